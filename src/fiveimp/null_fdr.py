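"""Empirical-null FDR calling of 5IM transcripts.

Control-window 5IMP scores form the empirical null. Each evaluated
transcript gets an add-one empirical p-value, q-values via Storey's
pi0-smoothing estimator (or Benjamini-Hochberg), and a 5IM flag at a
target FDR. The add-one estimator p = (1 + #{null >= s}) / (N + 1) never
returns zero, so q-values cannot collapse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

MIN_NULL_FOR_CALLING = 100


@dataclass
class NullDistribution:
    scores: np.ndarray  # sorted ascending
    provenance: dict = field(default_factory=dict)
    calling_enabled: bool = True

    @property
    def n(self) -> int:
        return len(self.scores)

    def ecdf(self, x) -> np.ndarray | float:
        """Right-continuous empirical CDF of the null scores."""
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.searchsorted(self.scores, xs, side="right") / self.n
        return float(out[0]) if np.isscalar(x) else out


def fit_empirical_null(control_scores, provenance: dict | None = None) -> NullDistribution:
    scores = np.sort(np.asarray(control_scores, dtype=float))
    if scores.size == 0:
        raise ValueError("empty control score set")
    if np.any((scores < 0) | (scores > 10)):
        raise ValueError("5IMP scores must lie in [0, 10]")
    enabled = scores.size >= MIN_NULL_FOR_CALLING
    if not enabled:
        warnings.warn(
            f"only {scores.size} control scores (< {MIN_NULL_FOR_CALLING}); "
            "5IM calling disabled",
            stacklevel=2,
        )
    return NullDistribution(scores=scores, provenance=provenance or {},
                            calling_enabled=enabled)


def empirical_pvalue(null: NullDistribution, s) -> np.ndarray | float:
    """Add-one upper-tail p: (1 + #{null_i >= s}) / (N + 1)."""
    xs = np.atleast_1d(np.asarray(s, dtype=float))
    n_ge = null.n - np.searchsorted(null.scores, xs, side="left")
    p = (1.0 + n_ge) / (null.n + 1.0)
    return float(p[0]) if np.isscalar(s) else p


def _storey_pi0(p: np.ndarray) -> float:
    """pi0 via the lambda-grid cubic-smoother limit (qvalue-style)."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if np.all(pi0_lambda <= 0):
        return 1.0 / m
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return min(1.0, max(pi0, 1.0 / m))


def estimate_qvalues(pvals, method: str = "storey") -> np.ndarray:
    """q-values, monotone non-decreasing in p.

    ``storey``: pi0-scaled step-up with the cubic-smoother pi0 estimate;
    ``bh``: Benjamini-Hochberg (pi0 = 1).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown method {method!r}; expected 'storey' or 'bh'")
    pi0 = _storey_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # monotonize
    q = np.clip(q, 0, 1)
    out = np.empty_like(q)
    out[order] = q
    return out


@dataclass
class ImpCalls:
    table: pd.DataFrame  # transcript_id index: score, p, q, is_5im
    threshold_score: float | None
    target_fdr: float
    pi0: float | None = None

    @property
    def n_called(self) -> int:
        return int(self.table["is_5im"].sum())

    @property
    def fraction_called(self) -> float:
        return float(self.table["is_5im"].mean())

    def summary(self) -> dict:
        return {
            "target_fdr": self.target_fdr,
            "threshold_score": self.threshold_score,
            "n_called": self.n_called,
            "fraction_called": self.fraction_called,
            "pi0": self.pi0,
        }


def call_5im(
    scores,
    null: NullDistribution,
    target_fdr: float = 0.05,
    qvalue_method: str = "storey",
    score_threshold: float | None = None,
    model_version: str | None = None,
) -> ImpCalls:
    """Per-transcript empirical p, q, and the 5IM flag at a target FDR.

    ``scores`` is a mapping/Series of transcript_id -> 5IMP score. When
    ``score_threshold`` is given (e.g. a previously established operating
    point), calling is by score >= threshold instead of the q-value rule.
    Null and evaluated scores must come from the same trained ensemble:
    when both carry a model_version it is checked.
    """
    if not null.calling_enabled:
        raise ValueError(
            f"null has fewer than {MIN_NULL_FOR_CALLING} scores; calling disabled"
        )
    null_version = null.provenance.get("model_version")
    if model_version is not None and null_version is not None and model_version != null_version:
        raise ValueError(
            f"score/null model version mismatch: {model_version} vs {null_version}"
        )
    s = pd.Series(scores, dtype=float)
    if np.any((s < 0) | (s > 10)):
        raise ValueError("5IMP scores must lie in [0, 10]")
    p = empirical_pvalue(null, s.to_numpy())
    q = estimate_qvalues(p, method=qvalue_method)
    pi0 = _storey_pi0(np.asarray(p)) if qvalue_method == "storey" else None
    if score_threshold is not None:
        is_5im = s.to_numpy() >= score_threshold
    else:
        is_5im = q <= target_fdr
    table = pd.DataFrame(
        {"score": s.to_numpy(), "p": p, "q": q, "is_5im": is_5im}, index=s.index
    )
    table.index.name = "transcript_id"
    called = table.loc[table["is_5im"], "score"]
    threshold = float(called.min()) if len(called) else None
    if score_threshold is not None:
        threshold = float(score_threshold)
    return ImpCalls(table=table, threshold_score=threshold,
                    target_fdr=target_fdr, pi0=pi0)


def calls_to_tsv(calls: ImpCalls, path) -> None:
    calls.table.to_csv(path, sep="\t")
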