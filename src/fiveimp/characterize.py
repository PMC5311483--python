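"""Downstream association battery for 5IM calls.

Covers codon-optimality (tAI) profiles, target-set enrichment (Fisher +
Wilcoxon), rank correlations, translation-efficiency classes, the
ER-proximity expression filters and moving averages, EJC peak geometry,
and first-99-nt peak overlap. Statistical machinery (Fisher, Wilcoxon,
Spearman, Holm, BH) is delegated to scipy/statsmodels; odds ratios are the
sample cross-product (common stats packages differ on this, so it is
explicit here).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .folding import fold_energy_window  # noqa: F401  (battery re-export)
from .transcript_io import EARLY_LEN, TranscriptModel

N_PROFILE_CODONS = 32  # codons 2-33 of the 33-codon early region


@dataclass
class AssociationResult:
    name: str
    statistic: float
    effect: float
    effect_type: str  # odds_ratio | rho | median_diff | none
    p: float
    adjusted_p: float = float("nan")
    adjustment: str = "none"
    n: tuple = ()
    note: str = ""


@dataclass
class PeakSet:
    """Transcript-space intervals (0-based half-open) with optional centers."""

    name: str
    peaks: pd.DataFrame  # transcript_id, start, end [, weighted_center, value]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.peaks)
        required = {"transcript_id", "start", "end"}
        if not required <= set(df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        if len(df) and np.any(df["start"] >= df["end"]):
            raise ValueError("peak intervals must satisfy start < end")
        if "weighted_center" in df.columns and len(df):
            wc = df["weighted_center"].to_numpy(dtype=float)
            ok = np.isnan(wc) | ((wc >= df["start"]) & (wc < df["end"]))
            if not ok.all():
                raise ValueError("weighted_center must lie in [start, end)")
        self.peaks = df

    def centers(self) -> np.ndarray:
        """weighted_center where present, interval midpoint otherwise."""
        mid = (self.peaks["start"] + self.peaks["end"]) / 2.0
        if "weighted_center" in self.peaks.columns:
            wc = self.peaks["weighted_center"].to_numpy(dtype=float)
            return np.where(np.isnan(wc), mid, wc)
        return mid.to_numpy(dtype=float)

    @classmethod
    def from_bed6(cls, path, name: str | None = None) -> "PeakSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["transcript_id", "start", "end", "peak_name", "value", "strand"],
            usecols=range(6),
        )
        return cls(name=name or str(path), peaks=df[["transcript_id", "start", "end", "value"]])


@dataclass
class TaiTable:
    """tAI weight per sense codon, scaled so the maximum weight is 1."""

    weights: dict[str, float]
    source: str = "custom"

    def __post_init__(self) -> None:
        from Bio.Data.CodonTable import standard_dna_table

        sense = set(standard_dna_table.forward_table)
        missing = sense - set(self.weights)
        if missing:
            raise ValueError(f"tAI table missing {len(missing)} sense codons")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("tAI weights must be > 0")
        mx = max(self.weights.values())
        self.weights = {c: w / mx for c, w in self.weights.items()}

    @classmethod
    def from_tsv(cls, path, source: str | None = None) -> "TaiTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["codon"], df["weight"])), source=source or str(path))

    @classmethod
    def bundled_synthetic(cls) -> "TaiTable":
        """Synthetic representative table shipped with the package.

        The weights are derived from bundled codon-usage frequencies, not
        from measured tRNA gene copy numbers; they provide a realistic
        codon-optimality gradient for simulation and testing.
        """
        import importlib.resources

        ref = importlib.resources.files("fiveimp.data") / "tai_synthetic.tsv"
        rows = [l.split("\t") for l in ref.read_text().splitlines()[1:]]
        return cls({c: float(w) for c, w in rows}, source="bundled synthetic")


@dataclass
class ExprRecord:
    gene_id: str
    rpkm_input: float
    rpkm_pulldown: float
    reads_input: int
    reads_pulldown: int
    log2_ratio: float | None = None
    te: float | None = None


# ---------------------------------------------------------------------------
# Codon optimality

def tai_profile(region, table: TaiTable) -> tuple[np.ndarray, float]:
    """Per-codon tAI for codons 2-33 plus the median over defined positions.

    The start codon is excluded; stop codons have no weight (NaN).
    """
    seq = region.sequence if hasattr(region, "sequence") else region
    if len(seq) != EARLY_LEN:
        raise ValueError(f"expected {EARLY_LEN}-nt region")
    weights = np.full(N_PROFILE_CODONS, np.nan)
    for i in range(N_PROFILE_CODONS):
        codon = seq[3 * (i + 1) : 3 * (i + 2)]
        if codon in table.weights:
            weights[i] = table.weights[codon]
    median = float(np.nanmedian(weights)) if np.any(~np.isnan(weights)) else float("nan")
    return weights, median


def per_position_group_test(profiles_a: np.ndarray, profiles_b: np.ndarray) -> list[AssociationResult]:
    """Wilcoxon rank-sum per codon position, Holm-adjusted across positions."""
    A = np.asarray(profiles_a, dtype=float)
    B = np.asarray(profiles_b, dtype=float)
    if A.shape[0] < 10 or B.shape[0] < 10:
        raise ValueError("need >= 10 transcripts per group")
    results = []
    pvals = []
    for pos in range(A.shape[1]):
        a = A[:, pos][~np.isnan(A[:, pos])]
        b = B[:, pos][~np.isnan(B[:, pos])]
        if len(a) == 0 or len(b) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        results.append(
            AssociationResult(
                name=f"codon_{pos + 2}", statistic=float(stat),
                effect=float(np.nanmedian(a) - np.nanmedian(b)),
                effect_type="median_diff", p=float(p), n=(len(a), len(b)),
            )
        )
        pvals.append(p)
    adj = multipletests(pvals, method="holm")[1]
    for r, ap in zip(results, adj):
        r.adjusted_p, r.adjustment = float(ap), "holm"
    return results


# ---------------------------------------------------------------------------
# Association tests

def _cross_product_or(a: int, b: int, c: int, d: int) -> tuple[float, str]:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan"), "degenerate table"
    return (a * d) / (b * c), ""


def target_set_association(scores, is_target, is_5im) -> tuple[AssociationResult, AssociationResult]:
    """Fisher enrichment of 5IM among targets + Wilcoxon on scores by target.

    Returns (fisher_result, wilcoxon_result); the Wilcoxon result's effect
    is the median 5IMP-score difference (targets minus non-targets), which
    supports screens requiring both adjusted p < 0.05 and median
    difference > 1.
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(is_target, dtype=bool)
    f = np.asarray(is_5im, dtype=bool)
    a = int(np.sum(t & f))
    b = int(np.sum(t & ~f))
    c = int(np.sum(~t & f))
    d = int(np.sum(~t & ~f))
    or_, note = _cross_product_or(a, b, c, d)
    if min(a + b, c + d) == 0:
        fisher = AssociationResult(
            "fisher_5im_in_targets", float("nan"), float("nan"), "odds_ratio",
            1.0, n=(a, b, c, d), note="degenerate table",
        )
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        fisher = AssociationResult(
            "fisher_5im_in_targets", float("nan"), or_, "odds_ratio",
            float(p), n=(a, b, c, d), note=note,
        )
    in_t, out_t = scores[t], scores[~t]
    if len(in_t) == 0 or len(out_t) == 0:
        wilcoxon = AssociationResult(
            "wilcoxon_scores_by_target", float("nan"), float("nan"),
            "median_diff", 1.0, n=(len(in_t), len(out_t)), note="one group empty",
        )
    else:
        stat, p = stats.mannwhitneyu(in_t, out_t, alternative="two-sided")
        wilcoxon = AssociationResult(
            "wilcoxon_scores_by_target", float(stat),
            float(np.median(in_t) - np.median(out_t)), "median_diff",
            float(p), n=(len(in_t), len(out_t)),
        )
    return fisher, wilcoxon


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def score_quantity_correlation(scores, values, name: str = "spearman") -> AssociationResult:
    """Spearman rank correlation (average ranks for ties).

    Exact permutation p for n <= 8; t-approximation otherwise.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("scores and values must be paired")
    if len(x) < 10 and len(x) > 8:
        pass  # small but above the exact-enumeration cutoff; t-approx applies
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            name, float("nan"), float("nan"), "rho", 1.0, n=(len(x),),
            note="zero variance; correlation undefined",
        )
    rho, p = stats.spearmanr(x, y)
    if len(x) <= 8:
        p = _exact_spearman_p(x, y, rho)
    return AssociationResult(name, float(rho), float(rho), "rho", float(p), n=(len(x),))


def translation_efficiency_classes(te_values) -> np.ndarray:
    """HIGH/MID/LOW by one standard deviation around the mean (exclusive).

    Intended to be applied to log2-scale translation efficiencies.
    """
    v = np.asarray(te_values, dtype=float)
    mu, sd = v.mean(), v.std()
    out = np.full(v.shape, "MID", dtype=object)
    out[v < mu - sd] = "LOW"
    out[v > mu + sd] = "HIGH"
    return out


# ---------------------------------------------------------------------------
# ER-proximity expression handling

def er_filter_and_ratio(records: list[ExprRecord]) -> tuple[list[ExprRecord], int]:
    """Apply the expression filters and compute log2(pulldown / input).

    Keeps records with RPKM > 5 in either library AND >= 30 reads in either
    library; zero-denominator records are excluded from the ratio and
    tallied. Idempotent on its own output.
    """
    kept: list[ExprRecord] = []
    n_zero_denominator = 0
    for r in records:
        if not (r.rpkm_input > 5 or r.rpkm_pulldown > 5):
            continue
        if not (r.reads_input >= 30 or r.reads_pulldown >= 30):
            continue
        if r.rpkm_input == 0:
            n_zero_denominator += 1
            continue
        kept.append(
            ExprRecord(
                gene_id=r.gene_id, rpkm_input=r.rpkm_input,
                rpkm_pulldown=r.rpkm_pulldown, reads_input=r.reads_input,
                reads_pulldown=r.reads_pulldown,
                log2_ratio=math.log2(r.rpkm_pulldown / r.rpkm_input),
                te=r.te,
            )
        )
    return kept, n_zero_denominator


def moving_average_by_score(scores, values, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window means after sorting genes by score (step 1).

    Returns (window mean score, window mean value), n - bin_size + 1 points.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < bin_size:
        raise ValueError(f"need >= {bin_size} genes, got {len(x)}")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    kernel = np.ones(bin_size) / bin_size
    mean_x = np.convolve(xs, kernel, mode="valid")
    mean_y = np.convolve(ys, kernel, mode="valid")
    return mean_x, mean_y


# ---------------------------------------------------------------------------
# Peak geometry

CANONICAL_WINDOW = (15, 32)  # nt upstream of a junction, inclusive bounds


def project_peaks_to_transcript(peaks: PeakSet, model: TranscriptModel) -> PeakSet:
    """Project genomic-coordinate peaks onto one transcript's coordinates.

    Peaks spanning junctions are projected piecewise and merged; purely
    intronic peaks are dropped.
    """
    rows = []
    for _, pk in peaks.peaks.iterrows():
        if pk["transcript_id"] != model.transcript_id and pk["transcript_id"] != model.chrom:
            continue
        pieces = []
        for s, e in model.exons:
            lo, hi = max(s, int(pk["start"])), min(e, int(pk["end"]))
            if lo < hi:
                t0 = model._genomic_to_tx(lo if model.strand == "+" else hi - 1)
                t1 = model._genomic_to_tx(hi - 1 if model.strand == "+" else lo)
                pieces.append((min(t0, t1), max(t0, t1) + 1))
        if not pieces:
            continue
        start = min(p[0] for p in pieces)
        end = max(p[1] for p in pieces)
        rows.append({"transcript_id": model.transcript_id, "start": start, "end": end})
    return PeakSet(name=peaks.name, peaks=pd.DataFrame(rows, columns=["transcript_id", "start", "end"]))


@dataclass
class EjcClassification:
    transcript_id: str
    peak_labels: list[str]  # CANONICAL / NONCANONICAL per peak
    nc_count_first99: int
    group: str  # "0", "1", "2+"
    excluded: bool = False


def classify_ejc_peaks(peaks: PeakSet, model: TranscriptModel, rpkm: float) -> EjcClassification:
    """Canonical vs noncanonical EJC peak calls for one transcript.

    Canonical: the peak's (weighted) center lies 15-32 nt (inclusive)
    upstream of any exon-exon boundary. Noncanonical peaks overlapping the
    first 99 coding nt are counted and grouped 0 / 1 / 2+. Transcripts with
    RPKM <= 1 are excluded.
    """
    if rpkm <= 1:
        return EjcClassification(model.transcript_id, [], 0, "0", excluded=True)
    df = peaks.peaks[peaks.peaks["transcript_id"] == model.transcript_id]
    tx_len = sum(e - s for s, e in model.exons)
    boundaries = model.junctions_tx()
    c0, _ = model.cds_tx_interval()
    early = (c0, c0 + EARLY_LEN)
    sub = PeakSet(name=peaks.name, peaks=df)
    centers = sub.centers()
    labels = []
    nc_count = 0
    lo, hi = CANONICAL_WINDOW
    for (_, pk), center in zip(df.iterrows(), centers):
        if pk["start"] < 0 or pk["end"] > tx_len:
            raise ValueError(
                f"peak [{pk['start']}, {pk['end']}) outside transcript "
                f"{model.transcript_id} (length {tx_len})"
            )
        canonical = any(lo <= b - center <= hi for b in boundaries)
        labels.append("CANONICAL" if canonical else "NONCANONICAL")
        if not canonical and pk["start"] < early[1] and pk["end"] > early[0]:
            nc_count += 1
    group = "0" if nc_count == 0 else ("1" if nc_count == 1 else "2+")
    return EjcClassification(model.transcript_id, labels, nc_count, group)


def peak_overlap_first99(peaks: PeakSet, models: list[TranscriptModel]) -> dict[str, bool]:
    """True iff any peak intersects coding positions [0, 99) of the transcript."""
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for _, pk in peaks.peaks.iterrows():
        by_tx.setdefault(pk["transcript_id"], []).append((int(pk["start"]), int(pk["end"])))
    out = {}
    for m in models:
        c0, _ = m.cds_tx_interval()
        early = (c0, c0 + EARLY_LEN)
        out[m.transcript_id] = any(
            s < early[1] and e > early[0] for s, e in by_tx.get(m.transcript_id, [])
        )
    return out


# ---------------------------------------------------------------------------
# The battery

def characterization_battery(
    calls,
    target_sets: dict[str, dict[str, bool]] | None = None,
    quantitative_tables: dict[str, dict[str, float]] | None = None,
    in_depth: dict[str, list[str]] | None = None,
    rbp_screen: set[str] | None = None,
) -> pd.DataFrame:
    """Run the association battery against a set of 5IM calls.

    Each target set yields a Fisher enrichment and a Wilcoxon score test;
    each quantitative table a Spearman correlation. Top-level tests are
    Bonferroni-adjusted across the number of tested characteristics;
    characteristics listed under an ``in_depth`` category are instead
    BH-adjusted within their category. Sets named in ``rbp_screen`` get the
    screen verdict column (Bonferroni p < 0.05 and median score
    difference > 1).
    """
    target_sets = target_sets or {}
    quantitative_tables = quantitative_tables or {}
    if not target_sets and not quantitative_tables:
        raise ValueError("supply at least one annotation set or quantitative table")
    table = calls.table if hasattr(calls, "table") else calls
    ids = list(table.index)
    scores = table["score"].to_numpy(dtype=float)
    is_5im = table["is_5im"].to_numpy(dtype=bool)

    rows = []
    for name, targets in target_sets.items():
        t = np.array([bool(targets.get(i, False)) for i in ids])
        fisher, wilcoxon = target_set_association(scores, t, is_5im)
        rows.append({"characteristic": name, "test": "fisher", "statistic": fisher.statistic,
                     "effect": fisher.effect, "effect_type": fisher.effect_type,
                     "p": fisher.p, "n": fisher.n, "note": fisher.note})
        rows.append({"characteristic": name, "test": "wilcoxon", "statistic": wilcoxon.statistic,
                     "effect": wilcoxon.effect, "effect_type": wilcoxon.effect_type,
                     "p": wilcoxon.p, "n": wilcoxon.n, "note": wilcoxon.note})
    for name, values in quantitative_tables.items():
        pairs = [(scores[i], values[tid]) for i, tid in enumerate(ids) if tid in values]
        if len(pairs) < 10:
            raise ValueError(f"quantitative table {name!r} pairs with < 10 transcripts")
        xs, ys = zip(*pairs)
        r = score_quantity_correlation(xs, ys, name=name)
        rows.append({"characteristic": name, "test": "spearman", "statistic": r.statistic,
                     "effect": r.effect, "effect_type": r.effect_type,
                     "p": r.p, "n": r.n, "note": r.note})
    df = pd.DataFrame(rows)

    in_depth = in_depth or {}
    member_of = {c: cat for cat, chars in in_depth.items() for c in chars}
    df["category"] = df["characteristic"].map(lambda c: member_of.get(c, "top_level"))
    n_top = df.loc[df["category"] == "top_level", "characteristic"].nunique()
    adjusted = np.full(len(df), np.nan)
    method = np.full(len(df), "", dtype=object)
    top = df["category"] == "top_level"
    adjusted[top] = np.minimum(1.0, df.loc[top, "p"] * max(n_top, 1))
    method[top] = "bonferroni"
    for cat in in_depth:
        mask = (df["category"] == cat).to_numpy()
        if mask.any():
            adjusted[mask] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
            method[mask] = "qvalue"
    df["adjusted_p"] = adjusted
    df["adjustment"] = method

    if rbp_screen:
        verdict = []
        for _, row in df.iterrows():
            if row["characteristic"] in rbp_screen and row["test"] == "wilcoxon":
                verdict.append(bool(row["adjusted_p"] < 0.05 and row["effect"] > 1))
            else:
                verdict.append(None)
        df["rbp_screen_hit"] = verdict
    return df
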