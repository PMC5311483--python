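"""Synthetic transcriptomes with known ground truth.

Generates a genome, transcript models, and peak/expression tables in which
the 5IM-defining signals are implanted with controllable strength: POS
(5UI-minus-like) transcripts lack 5'UTR junctions, keep their first coding
intron at or beyond 90 nt, and receive a CG-rich motif implant plus
synonymous adenine depletion in the early coding region. Intron placement
is simulated in genomic space by splitting exons, so downstream splicing
logic is exercised rather than bypassed.

Peptide sequences are preserved by the depletion recode (synonymous codons
only, tilted against adenine), so the implanted signal is an RNA-level
signal, as in the biological class being emulated.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.optimize import brentq

from .characterize import ExprRecord, PeakSet
from .transcript_io import EARLY_LEN, TranscriptModel

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = tuple(standard_dna_table.stop_codons)

_SYNONYMS: dict[str, list[str]] = {}
for _c, _aa in _CODON_TABLE.items():
    _SYNONYMS.setdefault(_aa, []).append(_c)


def load_codon_usage() -> dict[str, float]:
    """Bundled human-like codon usage as relative frequencies (all 64)."""
    ref = importlib.resources.files("fiveimp.data") / "codon_usage_human_like.tsv"
    usage = {}
    for line in ref.read_text().splitlines()[1:]:
        codon, f = line.split("\t")
        usage[codon] = float(f)
    total = sum(usage.values())
    return {c: v / total for c, v in usage.items()}


@dataclass
class SimParams:
    """Study-condition dials for the simulated transcriptome."""

    n_transcripts: int = 500
    pos_fraction: float = 0.71
    motif: str = "GCCGCCGCC"
    implant_prob: float = 0.8
    adenine_delta: float = 0.1
    #: first-coding-intron offset laws per transcript kind (inclusive ranges)
    intron_offset_law: dict = field(
        default_factory=lambda: {
            "pos": (90, 150), "neg_coding": (3, 87), "neg_utr": (30, 150)
        }
    )
    fivui_prob_neg: float = 0.7
    peak_odds: float = 4.0
    copula_rho: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("pos_fraction", self.pos_fraction),
                        ("implant_prob", self.implant_prob),
                        ("fivui_prob_neg", self.fivui_prob_neg)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must lie in (0, 1)")
        if self.peak_odds < 0:
            raise ValueError("peak_odds must be >= 0")
        if abs(self.copula_rho) > 1:
            raise ValueError("copula_rho must lie in [-1, 1]")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if set(self.motif.upper()) - set("ACGT"):
            raise ValueError("motif consensus must be over ACGT")


# ---------------------------------------------------------------------------
# Adenine-depleting synonymous recode

def _tilted_family(codons: list[str], usage: dict[str, float], theta: float) -> np.ndarray:
    w = np.array([usage[c] * math.exp(-theta * c.count("A")) for c in codons])
    return w / w.sum()


def _expected_a_per_nt(usage: dict[str, float], theta: float) -> float:
    """Expected per-nt adenine content of a codon drawn as: amino acid from
    usage-implied composition, codon from the theta-tilted synonym family."""
    sense = {c: f for c, f in usage.items() if c in _CODON_TABLE}
    total = sum(sense.values())
    aa_prob: dict[str, float] = {}
    for c, f in sense.items():
        aa_prob[_CODON_TABLE[c]] = aa_prob.get(_CODON_TABLE[c], 0.0) + f / total
    ea = 0.0
    for aa, p_aa in aa_prob.items():
        fam = _SYNONYMS[aa]
        probs = _tilted_family(fam, usage, theta)
        ea += p_aa * float(np.dot(probs, [c.count("A") for c in fam]))
    return ea / 3.0


def solve_adenine_tilt(delta: float, usage: dict[str, float] | None = None) -> float:
    """Tilt strength theta for a per-nt adenine depletion of ``delta``.

    Synonymous recoding has a ceiling: once every family sits on its
    minimum-adenine codon no further depletion is possible without changing
    the peptide. Requests beyond that ceiling saturate at the maximal tilt
    (the motif implant contributes additional depletion on top).
    """
    if delta == 0:
        return 0.0
    usage = usage or load_codon_usage()
    base = _expected_a_per_nt(usage, 0.0)
    theta_max = 50.0
    achievable = base - _expected_a_per_nt(usage, theta_max)
    if delta >= achievable:
        return theta_max
    return float(brentq(lambda t: base - _expected_a_per_nt(usage, t) - delta,
                        0.0, theta_max))


def recode_synonymous(seq: str, theta: float, rng: np.random.Generator,
                      usage: dict[str, float] | None = None,
                      skip_first_codon: bool = True) -> str:
    """Resample each codon from its theta-tilted synonym family.

    The encoded peptide is unchanged; stop codons and codons containing N
    are left as-is.
    """
    usage = usage or load_codon_usage()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if (i == 0 and skip_first_codon) or codon not in _CODON_TABLE:
            out.append(codon)
            continue
        fam = _SYNONYMS[_CODON_TABLE[codon]]
        probs = _tilted_family(fam, usage, theta)
        out.append(fam[int(rng.choice(len(fam), p=probs))])
    out.append(seq[len(seq) - len(seq) % 3 :])
    return "".join(out)


def implant_class_signal(
    regions: list[str], params: SimParams, rng: np.random.Generator,
    usage: dict[str, float] | None = None,
) -> tuple[list[str], list[dict]]:
    """Apply the POS-class signal to 99-nt early regions.

    Each region is synonymously recoded toward lower adenine content
    (target depletion ``adenine_delta`` per nt) and, with probability
    ``implant_prob``, receives the motif consensus at a uniform offset
    (start codon preserved). Returns the modified regions and per-region
    implant records.
    """
    usage = usage or load_codon_usage()
    # recoding covers codons 2-33 (96 of 99 nt); rescale the per-nt target
    theta = solve_adenine_tilt(params.adenine_delta * EARLY_LEN / (EARLY_LEN - 3), usage)
    motif = params.motif.upper()
    out, records = [], []
    for seq in regions:
        if len(seq) != EARLY_LEN:
            raise ValueError(f"expected {EARLY_LEN}-nt regions")
        new = recode_synonymous(seq, theta, rng, usage=usage)
        implanted = bool(rng.random() < params.implant_prob)
        offset = -1
        if implanted:
            offset = int(rng.integers(3, EARLY_LEN - len(motif) + 1))
            new = new[:offset] + motif + new[offset + len(motif) :]
        out.append(new)
        records.append({"implanted": implanted, "implant_offset": offset,
                        "theta": theta})
    return out, records


# ---------------------------------------------------------------------------
# Genome and transcript models

_SENSE_CODONS = [c for c in _CODON_TABLE]


def _random_codons(n: int, rng: np.random.Generator, usage: dict[str, float]) -> str:
    codons = _SENSE_CODONS
    probs = np.array([usage[c] for c in codons])
    probs = probs / probs.sum()
    idx = rng.choice(len(codons), size=n, p=probs)
    return "".join(codons[i] for i in idx)


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _random_stop(rng: np.random.Generator, usage: dict[str, float]) -> str:
    probs = np.array([usage[c] for c in _STOP_CODONS])
    probs = probs / probs.sum()
    return _STOP_CODONS[int(rng.choice(3, p=probs))]


def simulate_genome_and_models(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TranscriptModel], pd.DataFrame]:
    """Genome FASTA dict + transcript models + ground-truth table.

    Every transcript has >= 3 coding exons, CDS >= 480 nt, enough coding
    sequence downstream of the third exon for a control window, and a
    random strand. POS transcripts have no 5'UTR junction and a first
    coding intron at >= 90 nt; NEG transcripts carry a 5'UTR junction with
    probability ``fivui_prob_neg`` and otherwise an early coding intron.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    usage = load_codon_usage()
    theta = solve_adenine_tilt(
        params.adenine_delta * EARLY_LEN / (EARLY_LEN - 3), usage
    ) if params.adenine_delta else 0.0
    motif = params.motif.upper()
    law = params.intron_offset_law

    chroms: dict[str, list[str]] = {}
    cursor: dict[str, int] = {}
    per_chrom = 100
    models, truth_rows = [], []

    for i in range(params.n_transcripts):
        tid = f"TX{i:05d}"
        chrom = f"chrS{i // per_chrom + 1}"
        if chrom not in chroms:
            chroms[chrom] = []
            cursor[chrom] = 0
        is_pos = bool(rng.random() < params.pos_fraction)
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = int(rng.integers(50, 301))
        utr3_len = int(rng.integers(100, 301))

        # first-coding-intron offsets per class
        has_utr_junction = False
        if is_pos:
            o1 = int(rng.integers(law["pos"][0], law["pos"][1] + 1))
        else:
            has_utr_junction = bool(rng.random() < params.fivui_prob_neg)
            lo, hi = law["neg_utr"] if has_utr_junction else law["neg_coding"]
            o1 = int(rng.integers(lo, hi + 1))
        o2 = max(o1 + int(rng.integers(90, 141)), 100)
        o3 = o2 + int(rng.integers(90, 141))
        n_codons = int(rng.integers(max(160, (o3 + 110) // 3 + 1), 261))
        cds_len = 3 * n_codons  # includes the stop codon

        body = _random_codons(n_codons - 2, rng, usage)
        early = ("ATG" + body)[:EARLY_LEN]
        implanted, implant_offset = False, -1
        if is_pos:
            early = recode_synonymous(early, theta, rng, usage=usage)
            if rng.random() < params.implant_prob:
                implanted = True
                implant_offset = int(rng.integers(3, EARLY_LEN - len(motif) + 1))
                early = (early[:implant_offset] + motif
                         + early[implant_offset + len(motif) :])
        cds = early + ("ATG" + body)[EARLY_LEN : cds_len - 3] + _random_stop(rng, usage)
        mrna = _random_bases(utr5_len, rng) + cds + _random_bases(utr3_len, rng)

        # junctions in transcript coordinates
        juncs = []
        if has_utr_junction:
            juncs.append(int(rng.integers(10, utr5_len - 9)))
        c0 = utr5_len
        juncs += [c0 + o1, c0 + o2, c0 + o3]
        if rng.random() < 0.5:  # optional 3'UTR junction
            juncs.append(c0 + cds_len + int(rng.integers(10, utr3_len - 9)))
        juncs = sorted(juncs)

        intron_lens = [int(rng.integers(80, 501)) for _ in juncs]
        # assemble pre-mRNA with introns (GT...AG) at the junctions
        pieces, prev = [], 0
        for j, ilen in zip(juncs, intron_lens):
            pieces.append(mrna[prev:j])
            pieces.append("GT" + _random_bases(ilen - 4, rng) + "AG")
            prev = j
        pieces.append(mrna[prev:])
        pre = "".join(pieces)

        # exon intervals in pre-mRNA coordinates
        exon_bounds, acc_intron = [], 0
        starts_tx = [0] + juncs
        ends_tx = juncs + [len(mrna)]
        for s_t, e_t, k in zip(starts_tx, ends_tx, range(len(starts_tx))):
            offset = sum(intron_lens[:k])
            exon_bounds.append((s_t + offset, e_t + offset))
        cds_pre0 = c0 + sum(il for j, il in zip(juncs, intron_lens) if j <= c0)
        cds_pre1 = (c0 + cds_len) + sum(
            il for j, il in zip(juncs, intron_lens) if j < c0 + cds_len
        )

        g0 = cursor[chrom] + int(rng.integers(200, 501))
        L = len(pre)
        if strand == "+":
            block = pre
            exons = [(g0 + a, g0 + b) for a, b in exon_bounds]
            cds_start, cds_end = g0 + cds_pre0, g0 + cds_pre1
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            block = "".join(comp[b] for b in reversed(pre))
            exons = sorted((g0 + L - b, g0 + L - a) for a, b in exon_bounds)
            cds_start, cds_end = g0 + L - cds_pre1, g0 + L - cds_pre0
        pad = g0 - cursor[chrom]
        chroms[chrom].append(_random_bases(pad, rng) + block)
        cursor[chrom] = g0 + L

        models.append(
            TranscriptModel(
                transcript_id=tid, chrom=chrom, strand=strand, exons=exons,
                cds_start=cds_start, cds_end=cds_end, category="SSCR",
                source_line=f"simulated:{i}",
            )
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "sim_class": "POS" if is_pos else "NEG",
                "has_5ui": has_utr_junction,
                "first_coding_intron_offset": o1,
                "implanted": implanted,
                "implant_offset": implant_offset,
                "strand": strand,
                "category": "SSCR",
            }
        )

    genome = {c: "".join(parts) for c, parts in chroms.items()}
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    return genome, models, truth


# ---------------------------------------------------------------------------
# Peaks and expression

def simulate_peaks(
    models: list[TranscriptModel],
    called: dict[str, bool],
    peak_odds: float,
    rng: np.random.Generator,
    base_prob: float = 0.15,
    name: str = "sim_peaks",
) -> PeakSet:
    """Early-CDS peaks whose odds are multiplied for 5IM-called transcripts."""
    odds0 = base_prob / (1 - base_prob)
    rows = []
    for m in models:
        odds = odds0 * peak_odds if called.get(m.transcript_id, False) else odds0
        p = odds / (1 + odds)
        if rng.random() >= p:
            continue
        c0, _ = m.cds_tx_interval()
        tx_len = sum(e - s for s, e in m.exons)
        width = int(rng.integers(20, 41))
        start = c0 + int(rng.integers(0, EARLY_LEN - 20))
        end = min(start + width, tx_len)
        rows.append({"transcript_id": m.transcript_id, "start": start, "end": end})
    return PeakSet(
        name=name,
        peaks=pd.DataFrame(rows, columns=["transcript_id", "start", "end"]),
    )


def simulate_expression(
    transcript_ids: list[str],
    scores,
    copula_rho: float,
    rng: np.random.Generator,
    filter_fail_frac: float = 0.2,
) -> list[ExprRecord]:
    """Expression records with a target Spearman correlation to scores.

    A Gaussian copula couples the log2 pulldown/input ratio (and log2 TE)
    to the normal scores of the 5IMP ranks; the Pearson parameter is chosen
    so the measured Spearman correlation approximates ``copula_rho``. A
    ``filter_fail_frac`` fraction of records is constructed to fail the
    printed RPKM/read-count filters.
    """
    if abs(copula_rho) > 0.95:
        raise ValueError("|copula_rho| must be <= 0.95")
    from scipy.stats import norm

    s = np.asarray(pd.Series(scores)[transcript_ids] if hasattr(scores, "keys")
                   else scores, dtype=float)
    n = len(transcript_ids)
    ranks = pd.Series(s).rank(method="average").to_numpy()
    # normal scores via rank -> uniform -> probit
    z1 = norm.ppf((ranks - 0.5) / n)
    pearson = 2 * math.sin(math.pi * copula_rho / 6)
    eps = rng.standard_normal(n)
    z2 = pearson * z1 + math.sqrt(max(0.0, 1 - pearson**2)) * eps
    fails = rng.random(n) < filter_fail_frac
    records = []
    for i, tid in enumerate(transcript_ids):
        if fails[i]:
            rpkm_in = float(rng.uniform(0.1, 4.9))
            rpkm_pd = float(rng.uniform(0.1, 4.9))
            reads_in = reads_pd = 1000
        else:
            rpkm_in = float(6.0 + rng.gamma(2.0, 5.0))
            rpkm_pd = float(rpkm_in * 2 ** z2[i])
            reads_in = reads_pd = 1000
        records.append(
            ExprRecord(
                gene_id=tid, rpkm_input=rpkm_in, rpkm_pulldown=rpkm_pd,
                reads_input=reads_in, reads_pulldown=reads_pd,
                te=float(z2[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Writers

def write_genome_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_labels_tsv(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcategory\n")
        for m in models:
            fh.write(f"{m.transcript_id}\t{m.category}\n")


def expr_records_to_tsv(records: list[ExprRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def peaks_to_bed6(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, (_, pk) in enumerate(peaks.peaks.iterrows()):
            val = pk.get("value", 0) if hasattr(pk, "get") else 0
            fh.write(
                f"{pk['transcript_id']}\t{int(pk['start'])}\t{int(pk['end'])}\t"
                f"{peaks.name}_{i}\t{val}\t+\n"
            )
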