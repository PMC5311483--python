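"""Discriminative forward-strand motif discovery and PSSM hit features.

A single bundled Gibbs site-sampler stands in for external motif finders:
the feature interface downstream only needs position-specific scoring
matrices, and externally derived PSSMs (JASPAR-style matrix text or the
JSON motif store) can be dropped in. Scanning is forward-strand only, as
appropriate for RNA motifs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .transcript_io import EARLY_LEN, EarlyRegion

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SIG_CAP = 300.0  # cap on -log10(p)


@dataclass
class Pssm:
    """Column-probability matrix over ACGT with a log-odds view."""

    name: str
    matrix: np.ndarray  # shape (4, width), columns sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PSSM must be 4 x width with width >= 4")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PSSM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        p = (self.matrix + self.pseudocount) / (1 + 4 * self.pseudocount)
        q = self.background / self.background.sum()
        return np.log2(p / q[:, None])

    def information_content(self) -> float:
        """Total relative entropy (bits) of the matrix vs its background."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        q = self.background / self.background.sum()
        return float((p * np.log2(p / q[:, None])).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    @classmethod
    def from_sites(
        cls, sites: list[str], name: str = "motif",
        background=None, pseudocount: float = 0.5,
    ) -> "Pssm":
        width = len(sites[0])
        counts = np.full((4, width), pseudocount)
        for s in sites:
            for j, ch in enumerate(s):
                if ch in _BASE_INDEX:
                    counts[_BASE_INDEX[ch], j] += 1
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(name=name, matrix=counts / counts.sum(axis=0), background=bg)

    @classmethod
    def from_consensus(cls, consensus: str, name: str = "motif",
                       strength: float = 0.91) -> "Pssm":
        width = len(consensus)
        mat = np.full((4, width), (1 - strength) / 3)
        for j, ch in enumerate(consensus.upper()):
            mat[_BASE_INDEX[ch], j] = strength
        return cls(name=name, matrix=mat)

    @classmethod
    def from_matrix_text(cls, text: str, name: str = "motif") -> "Pssm":
        """Rows A/C/G/T of counts or probabilities, whitespace-separated."""
        rows = {}
        for line in text.strip().splitlines():
            parts = line.replace(":", " ").split()
            if parts and parts[0].upper() in _BASE_INDEX:
                rows[parts[0].upper()] = [float(x) for x in parts[1:]]
        if set(rows) != set(BASES):
            raise ValueError("matrix text must have rows A, C, G, T")
        mat = np.array([rows[b] for b in BASES], dtype=float)
        return cls(name=name, matrix=mat / mat.sum(axis=0))


@dataclass
class MotifHit:
    transcript_id: str
    offset: int
    score: float


@dataclass
class EnrichmentTable:
    """Fisher-exact enrichment p among 5UI- transcripts per score threshold.

    ``thresholds`` ascending; ``pvalues[i]`` is the one-sided enrichment p
    for "has a hit scoring >= thresholds[i]".
    """

    motif_name: str
    thresholds: np.ndarray
    pvalues: np.ndarray
    n_pos: int  # 5UI- transcripts in the labelled set
    n_neg: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if np.any((self.pvalues <= 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def min_threshold(self) -> float:
        return float(self.thresholds[0])

    def significance(self, score: float) -> float:
        """-log10 enrichment p at the largest threshold <= score (capped)."""
        idx = int(np.searchsorted(self.thresholds, score, side="right")) - 1
        if idx < 0:
            return 0.0
        return min(SIG_CAP, -math.log10(self.pvalues[idx]))


# ---------------------------------------------------------------------------
# Scanning

def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def scan_scores(seq: str, pssm: Pssm) -> np.ndarray:
    """Log-odds score at every valid forward-strand start (N scores 0)."""
    lo = pssm.log_odds()
    enc = _encode(seq)
    w = pssm.width
    n_starts = len(seq) - w + 1
    if n_starts <= 0:
        return np.empty(0)
    out = np.zeros(n_starts)
    for j in range(w):
        col = enc[j : j + n_starts]
        valid = col >= 0
        out[valid] += lo[col[valid], j]
    return out


def scan_hits(region: EarlyRegion | str, pssm: Pssm,
              min_score: float = -math.inf) -> list[MotifHit]:
    """Hits with score >= min_score, best first; ties broken leftmost."""
    seq = region.sequence if isinstance(region, EarlyRegion) else region
    tid = region.transcript_id if isinstance(region, EarlyRegion) else ""
    scores = scan_scores(seq, pssm)
    hits = [
        MotifHit(transcript_id=tid, offset=i, score=float(s))
        for i, s in enumerate(scores)
        if s >= min_score
    ]
    hits.sort(key=lambda h: (-h.score, h.offset))
    return hits


# ---------------------------------------------------------------------------
# Gibbs site sampler

def _sample_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    w = weights / weights.sum()
    return int(rng.choice(len(w), p=w))


def _window_onehot(s: np.ndarray, start: int, width: int) -> np.ndarray:
    out = np.zeros((4, width))
    window = s[start : start + width]
    valid = window >= 0
    out[window[valid], np.nonzero(valid)[0]] = 1.0
    return out


def _site_sampler_once(
    enc_seqs: list[np.ndarray], width: int, rng: np.random.Generator,
    background: np.ndarray, n_sweeps: int,
) -> tuple[np.ndarray, float]:
    """One restart of the classic one-site-per-sequence Gibbs sampler.

    Site counts are maintained incrementally: the held-out sequence's
    contribution is subtracted before resampling its site and added back
    after, so each iteration costs O(width), not O(n * width).
    """
    n = len(enc_seqs)
    starts = np.array(
        [rng.integers(0, len(s) - width + 1) for s in enc_seqs], dtype=np.int64
    )
    counts = np.full((4, width), 0.5)  # pseudo-counts
    for i, s in enumerate(enc_seqs):
        counts += _window_onehot(s, starts[i], width)

    for it in range(n_sweeps * n):
        hold = it % n
        s = enc_seqs[hold]
        counts -= _window_onehot(s, starts[hold], width)
        probs = counts / counts.sum(axis=0)
        lo = np.log(probs / background[:, None])
        n_starts = len(s) - width + 1
        scores = np.zeros(n_starts)
        for j in range(width):
            col = s[j : j + n_starts]
            valid = col >= 0
            scores[valid] += lo[col[valid], j]
        weights = np.exp(scores - scores.max())
        starts[hold] = _sample_index(weights, rng)
        counts += _window_onehot(s, starts[hold], width)

        # shift move once per sweep: realign all sites by +-1 if that raises
        # the information content (phase-locks periodic motifs)
        if (it + 1) % n == 0:
            q = background / background.sum()

            def _ic_of(cts: np.ndarray) -> float:
                pm = cts / cts.sum(axis=0)
                return float((pm * np.log2(np.clip(pm, 1e-12, 1) / q[:, None])).sum())

            for d in (-1, 1):
                shifted = starts + d
                if np.any(shifted < 0) or any(
                    shifted[i] + width > len(enc_seqs[i]) for i in range(n)
                ):
                    continue
                new_counts = np.full((4, width), 0.5)
                for i, si in enumerate(enc_seqs):
                    new_counts += _window_onehot(si, shifted[i], width)
                if _ic_of(new_counts) > _ic_of(counts):
                    starts, counts = shifted, new_counts

    matrix = counts / counts.sum(axis=0)
    q = background / background.sum()
    ic = float((matrix * np.log2(np.clip(matrix, 1e-12, 1) / q[:, None])).sum())
    return matrix, ic


def positional_background(regions: list) -> np.ndarray:
    """Average ACGT composition of the supplied regions (N ignored)."""
    counts = np.zeros(4)
    for r in regions:
        seq = r.sequence if isinstance(r, EarlyRegion) else r
        for b, i in _BASE_INDEX.items():
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def gibbs_discover(
    positive_regions: list,
    widths=(8, 9, 10),
    rng: np.random.Generator | None = None,
    n_restarts: int = 8,
    n_sweeps: int = 8,
    name: str = "motif",
) -> Pssm:
    """Best forward-strand motif across widths/restarts by information content.

    Classic site sampler: one site per sequence, one held-out sequence
    resampled per iteration, ``n_sweeps`` full passes per restart. Deterministic under a seeded generator. The
    log-odds background is the average composition of the training regions
    (early CDS is GC-skewed; a uniform background would inflate CG-rich
    scores).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if len(positive_regions) < 20:
        raise ValueError(
            f"need >= 20 positive regions for discovery, got {len(positive_regions)}"
        )
    widths = sorted(set(int(w) for w in widths))
    if any(w < 6 or w > 16 for w in widths):
        raise ValueError("motif widths must lie in [6, 16]")
    seqs = [
        (r.sequence if isinstance(r, EarlyRegion) else r) for r in positive_regions
    ]
    background = positional_background(positive_regions)
    enc_seqs = [_encode(s) for s in seqs]
    best = None
    for width in widths:
        for _ in range(n_restarts):
            matrix, ic = _site_sampler_once(enc_seqs, width, rng, background, n_sweeps)
            # compare by per-column information content so widths compete fairly
            key = ic / width
            if best is None or key > best[0]:
                best = (key, matrix)
    return Pssm(name=name, matrix=best[1], background=background)


# ---------------------------------------------------------------------------
# Enrichment significance

def hit_significance(
    all_hits: list[MotifHit],
    labels: dict[str, bool],
    motif_name: str = "motif",
    max_thresholds: int = 200,
) -> EnrichmentTable:
    """Fisher-exact enrichment of high-scoring hits among 5UI- transcripts.

    ``labels`` maps transcript_id -> True when the transcript is 5UI-.
    For each observed hit score s, the 2x2 table crosses "has a hit >= s"
    with the 5UI label; p is the one-sided (enrichment in 5UI-) Fisher p.
    """
    for h in all_hits:
        if h.transcript_id not in labels:
            raise KeyError(f"no 5UI label for transcript {h.transcript_id}")
    n_pos = sum(1 for v in labels.values() if v)
    n_neg = len(labels) - n_pos
    best: dict[str, float] = {}
    for h in all_hits:
        if h.transcript_id not in best or h.score > best[h.transcript_id]:
            best[h.transcript_id] = h.score
    scores = sorted({h.score for h in all_hits})
    if len(scores) > max_thresholds:
        idx = np.linspace(0, len(scores) - 1, max_thresholds).round().astype(int)
        scores = [scores[i] for i in sorted(set(idx))]
    thresholds, pvals = [], []
    best_items = list(best.items())
    for s in scores:
        with_hit_pos = sum(1 for t, sc in best_items if sc >= s and labels[t])
        with_hit_neg = sum(1 for t, sc in best_items if sc >= s and not labels[t])
        table = [
            [with_hit_pos, n_pos - with_hit_pos],
            [with_hit_neg, n_neg - with_hit_neg],
        ]
        _, p = fisher_exact(table, alternative="greater")
        thresholds.append(s)
        pvals.append(max(p, 1e-320))
    return EnrichmentTable(
        motif_name=motif_name,
        thresholds=np.array(thresholds),
        pvalues=np.array(pvals),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def motif_feature_values(
    region: EarlyRegion | str, pssm: Pssm, table: EnrichmentTable | None
) -> tuple[float, float, float, float]:
    """(sig1, pos1, sig2, pos2) for the two best motif instances.

    Instances are ranked by enrichment significance (ties -> leftmost
    offset); fewer than two qualifying hits yield sentinel pairs (0, -1).
    Positions are 0-based nucleotide offsets.
    """
    sentinel = (0.0, -1.0, 0.0, -1.0)
    if table is None:
        return sentinel
    hits = scan_hits(region, pssm, min_score=table.min_threshold)
    scored = [(table.significance(h.score), h.offset) for h in hits]
    scored = [(sig, off) for sig, off in scored if sig > 0]
    scored.sort(key=lambda t: (-t[0], t[1]))
    out = list(sentinel)
    if scored:
        out[0], out[1] = scored[0][0], float(scored[0][1])
    if len(scored) > 1:
        out[2], out[3] = scored[1][0], float(scored[1][1])
    return tuple(out)


# ---------------------------------------------------------------------------
# Motif store (JSON)

def save_motifs(path, pssms: list[Pssm],
                tables: list[EnrichmentTable] | None = None) -> None:
    payload = {"motifs": []}
    tables = tables or []
    for i, p in enumerate(pssms):
        entry = {
            "name": p.name,
            "matrix": p.matrix.tolist(),
            "background": p.background.tolist(),
            "pseudocount": p.pseudocount,
        }
        if i < len(tables) and tables[i] is not None:
            t = tables[i]
            entry["enrichment"] = {
                "thresholds": t.thresholds.tolist(),
                "pvalues": t.pvalues.tolist(),
                "n_pos": t.n_pos,
                "n_neg": t.n_neg,
            }
        payload["motifs"].append(entry)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_motifs(path) -> tuple[list[Pssm], list[EnrichmentTable | None]]:
    with open(path) as fh:
        payload = json.load(fh)
    pssms, tables = [], []
    for entry in payload["motifs"]:
        pssms.append(
            Pssm(
                name=entry["name"],
                matrix=np.array(entry["matrix"]),
                background=np.array(entry["background"]),
                pseudocount=entry["pseudocount"],
            )
        )
        enr = entry.get("enrichment")
        tables.append(
            EnrichmentTable(
                motif_name=entry["name"],
                thresholds=np.array(enr["thresholds"]),
                pvalues=np.array(enr["pvalues"]),
                n_pos=enr["n_pos"],
                n_neg=enr["n_neg"],
            )
            if enr
            else None
        )
    return pssms, tables
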