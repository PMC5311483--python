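"""The 36 early-coding-region sequence features.

The feature roster covers three blocks: nucleotide/codon composition (5
features), regularized amino-acid ratios for BLOSUM62-positive pairs that
differ in A/T load (7 features), and motif features (6 motifs x {sig1, pos1,
sig2, pos2} = 24 features). The schema is config-driven so an alternative
roster can be substituted; feature extraction is a pure function of
(sequence, config).

Ambiguous bases (N) contribute to no feature count; denominators shrink
accordingly. Internal stop codons translate to '*' and are excluded from
amino-acid counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .transcript_io import EARLY_LEN, EarlyRegion

MOTIF_SENTINEL_SIG = 0.0
MOTIF_SENTINEL_POS = -1.0

#: BLOSUM62-positive amino-acid pairs most distinct in A/T load of their codons.
DEFAULT_RATIO_PAIRS = (
    ("R", "K"), ("L", "I"), ("L", "M"), ("I", "V"),
    ("D", "E"), ("Q", "E"), ("S", "T"),
)

DEFAULT_N_MOTIFS = 6


@dataclass(frozen=True)
class FeatureConfig:
    ratio_pairs: tuple = DEFAULT_RATIO_PAIRS
    n_motifs: int = DEFAULT_N_MOTIFS
    pseudocount_mass: float = 20.0
    schema_version: str = "1.0"

    def feature_names(self) -> list[str]:
        names = [
            "adenine_content",
            "thymine_content",
            "longest_non_a_run",
            "at_free_codon_fraction",
            "at_minimal_codon_preference",
        ]
        names += [f"ratio_{a}_{b}" for a, b in self.ratio_pairs]
        for m in range(1, self.n_motifs + 1):
            names += [f"motif{m}_sig1", f"motif{m}_pos1", f"motif{m}_sig2", f"motif{m}_pos2"]
        return names


DEFAULT_CONFIG = FeatureConfig()
FEATURE_SCHEMA = DEFAULT_CONFIG.feature_names()
assert len(FEATURE_SCHEMA) == 36


@dataclass
class FeatureVector:
    transcript_id: str
    values: dict[str, float]
    schema_version: str = "1.0"

    def __post_init__(self) -> None:
        if len(self.values) != 36:
            raise ValueError(f"expected 36 features, got {len(self.values)}")

    def as_array(self, schema: list[str] | None = None):
        import numpy as np

        schema = schema or list(self.values)
        return np.array([self.values[k] for k in schema], dtype=float)


# ---------------------------------------------------------------------------
# Amino-acid background

class AaBackground(dict):
    """Proteome-wide amino-acid frequencies (20 entries summing to 1)."""

    def __init__(self, freqs: dict[str, float], source: str = "custom"):
        total = sum(freqs.values())
        if len(freqs) != 20:
            raise ValueError(f"need 20 amino-acid frequencies, got {len(freqs)}")
        if any(v <= 0 for v in freqs.values()):
            raise ValueError("all background frequencies must be > 0")
        super().__init__({aa: v / total for aa, v in freqs.items()})
        self.source = source

    @classmethod
    def bundled_human(cls) -> "AaBackground":
        """Approximate human proteome composition shipped with the package."""
        ref = importlib.resources.files("fiveimp.data") / "aa_frequencies_human.tsv"
        freqs: dict[str, float] = {}
        for line in ref.read_text().splitlines()[1:]:
            aa, f = line.split("\t")
            freqs[aa] = float(f)
        return cls(freqs, source="bundled human proteome (approximate)")


# ---------------------------------------------------------------------------
# Translation and the composition block

def translate_early(region: EarlyRegion | str) -> str:
    """Translate the 99-nt window to a 33-residue peptide.

    Position 1 is translated as written (non-AUG starts are not forced to
    Met); internal stops appear as '*'; codons containing N appear as 'X'.
    """
    seq = region.sequence if isinstance(region, EarlyRegion) else region
    if len(seq) != EARLY_LEN:
        raise ValueError(f"expected {EARLY_LEN}-nt region, got {len(seq)}")
    return str(Seq(seq).translate())


def regularized_aa_ratio(
    peptide: str, pair: tuple[str, str], background: AaBackground, mass: float = 20.0
) -> float:
    """(c_a + m*f_a) / (c_b + m*f_b): pseudo-counts distributed by background."""
    a, b = pair
    if a == b:
        raise ValueError("ratio pair must be two distinct amino acids")
    if mass <= 0:
        raise ValueError("pseudo-count mass must be > 0")
    ca, cb = peptide.count(a), peptide.count(b)
    return (ca + mass * background[a]) / (cb + mass * background[b])


_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)

# amino acid -> minimal (A+T) count among its codons
_MIN_AT: dict[str, int] = {}
for _codon, _aa in _CODON_TABLE.items():
    at = _codon.count("A") + _codon.count("T")
    _MIN_AT[_aa] = min(_MIN_AT.get(_aa, 3), at)


def longest_non_a_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = 0 if ch == "A" else cur + 1
        best = max(best, cur)
    return best


def composition_features(region: EarlyRegion | str) -> dict[str, float]:
    """Nucleotide- and codon-composition features of the 99-nt window.

    Contents are computed over unambiguous bases only; codons containing N
    are excluded from the codon-level fractions.
    """
    seq = region.sequence if isinstance(region, EarlyRegion) else region
    if len(seq) != EARLY_LEN:
        raise ValueError(f"expected {EARLY_LEN}-nt region, got {len(seq)}")
    n_unambig = len(seq) - seq.count("N")
    denom = n_unambig if n_unambig else 1
    codons = [seq[i : i + 3] for i in range(0, EARLY_LEN, 3)]
    clean = [c for c in codons if "N" not in c]
    cdenom = len(clean) if clean else 1
    at_free = sum(1 for c in clean if "A" not in c and "T" not in c)
    coding = [c for c in clean if c not in _STOPS]
    if coding:
        minimal = sum(
            1
            for c in coding
            if c.count("A") + c.count("T") == _MIN_AT[_CODON_TABLE[c]]
        )
        at_minimal = minimal / len(coding)
    else:
        at_minimal = 0.0
    return {
        "adenine_content": seq.count("A") / denom,
        "thymine_content": seq.count("T") / denom,
        "longest_non_a_run": float(longest_non_a_run(seq)),
        "at_free_codon_fraction": at_free / cdenom,
        "at_minimal_codon_preference": at_minimal,
    }


# ---------------------------------------------------------------------------
# Full vector assembly

def assemble_features(
    region: EarlyRegion,
    motif_models: list | None = None,
    enrichment_tables: list | None = None,
    background: AaBackground | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """All 36 features for one region, in schema order.

    Motif models/tables may be empty during bootstrap; absent motifs (or
    regions without a qualifying hit) receive the sentinel pair
    (significance 0, position -1).
    """
    from .motifs import motif_feature_values  # local import to avoid a cycle

    background = background or AaBackground.bundled_human()
    motif_models = motif_models or []
    enrichment_tables = enrichment_tables or []
    if len(motif_models) > config.n_motifs:
        raise ValueError(
            f"{len(motif_models)} motif models but schema has {config.n_motifs} slots"
        )

    values: dict[str, float] = {}
    values.update(composition_features(region))
    peptide = translate_early(region)
    counted = peptide.replace("*", "").replace("X", "")
    for a, b in config.ratio_pairs:
        values[f"ratio_{a}_{b}"] = regularized_aa_ratio(
            counted, (a, b), background, config.pseudocount_mass
        )
    for m in range(config.n_motifs):
        if m < len(motif_models):
            table = enrichment_tables[m] if m < len(enrichment_tables) else None
            sig1, pos1, sig2, pos2 = motif_feature_values(
                region, motif_models[m], table
            )
        else:
            sig1, pos1, sig2, pos2 = (
                MOTIF_SENTINEL_SIG, MOTIF_SENTINEL_POS,
                MOTIF_SENTINEL_SIG, MOTIF_SENTINEL_POS,
            )
        values[f"motif{m + 1}_sig1"] = sig1
        values[f"motif{m + 1}_pos1"] = pos1
        values[f"motif{m + 1}_sig2"] = sig2
        values[f"motif{m + 1}_pos2"] = pos2

    schema = config.feature_names()
    missing = [n for n in schema if n not in values]
    if missing:
        raise ValueError(f"feature schema mismatch; missing: {missing}")
    ordered = {n: float(values[n]) for n in schema}
    return FeatureVector(
        transcript_id=region.transcript_id,
        values=ordered,
        schema_version=config.schema_version,
    )


def features_frame(vectors: list[FeatureVector]):
    """Feature vectors as a DataFrame indexed by transcript_id."""
    import pandas as pd

    return pd.DataFrame(
        [v.values for v in vectors], index=[v.transcript_id for v in vectors]
    )
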