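"""The 5IMP ensemble: 10 balanced random-forest subclassifiers.

The positive class (POS) is 5UI- (no 5' UTR intron); each subclassifier is
a random forest trained on an independent balanced subsample of the
training set, and the 5IMP score of a transcript is the sum of the 10
subclassifier class-probability outputs, hence a value in [0, 10].
Cross-validation folds partition transcript *clusters* so near-duplicate
early regions never straddle a train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import GroupKFold

from .seq_features import FeatureVector
from .transcript_io import IntronContext

N_SUBCLASSIFIERS = 10
DEFAULT_EXCLUSION_NT = 90
DEFAULT_N_TREES = 500

POS, NEG = "POS", "NEG"  # POS = 5UI-, NEG = 5UI+


@dataclass
class LabeledExample:
    transcript_id: str
    cluster_id: str
    features: FeatureVector
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POS, NEG):
            raise ValueError(f"label must be POS or NEG, got {self.label!r}")


@dataclass
class Ensemble:
    forests: list
    schema: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.forests) != N_SUBCLASSIFIERS:
            raise ValueError(f"ensemble needs {N_SUBCLASSIFIERS} subclassifiers")

    def subclassifier_outputs(self, X: np.ndarray) -> np.ndarray:
        """(n_examples, 10) matrix of per-subclassifier POS probabilities."""
        outs = []
        for forest in self.forests:
            proba = forest.predict_proba(X)
            pos_col = list(forest.classes_).index(POS)
            outs.append(proba[:, pos_col])
        return np.column_stack(outs)

    def save(self, path) -> None:
        """Versioned archive: JSON-able metadata + serialized forests."""
        import joblib

        joblib.dump({"schema": self.schema, "metadata": self.metadata,
                     "forests": self.forests}, path)

    @classmethod
    def load(cls, path) -> "Ensemble":
        import joblib

        payload = joblib.load(path)
        return cls(forests=payload["forests"], schema=payload["schema"],
                   metadata=payload["metadata"])


@dataclass
class CvResult:
    scores: pd.DataFrame  # transcript_id, cluster_id, label, fold, score
    auc: float
    auprc: float
    roc_points: np.ndarray
    pr_points: np.ndarray
    baseline_auc: float = 0.5
    baseline_auprc: float = float("nan")


# ---------------------------------------------------------------------------

def build_training_set(
    examples: list[LabeledExample],
    contexts: dict[str, IntronContext],
    exclusion_nt: int = DEFAULT_EXCLUSION_NT,
    sscr_only_ids: set[str] | None = None,
) -> list[LabeledExample]:
    """Drop POS (5UI-) examples whose first coding intron is too early.

    A 5UI- transcript whose first coding intron falls inside the first
    ``exclusion_nt`` coding nucleotides behaves like a 5UI+ transcript and
    is removed; all 5UI+ examples are retained. When ``sscr_only_ids`` is
    given, the training set is additionally restricted to those transcripts
    (the SSCR-only training regime).
    """
    kept = []
    for ex in examples:
        if ex.transcript_id not in contexts:
            raise KeyError(f"no intron context for {ex.transcript_id}")
        if sscr_only_ids is not None and ex.transcript_id not in sscr_only_ids:
            continue
        if ex.label == POS:
            off = contexts[ex.transcript_id].first_coding_intron_offset
            if off is not None and off < exclusion_nt:
                continue
        kept.append(ex)
    return kept


def balanced_subsample(
    examples: list[LabeledExample], rng: np.random.Generator
) -> list[LabeledExample]:
    """Equal class sizes by sampling (without replacement) from the larger class."""
    pos = [e for e in examples if e.label == POS]
    neg = [e for e in examples if e.label == NEG]
    if not pos or not neg:
        raise ValueError("both classes must be non-empty for balancing")
    k = min(len(pos), len(neg))
    out = []
    for group in (pos, neg):
        if len(group) == k:
            out.extend(group)
        else:
            idx = rng.choice(len(group), size=k, replace=False)
            out.extend(group[i] for i in sorted(idx))
    return out


def _design_matrix(examples: list[LabeledExample], schema: list[str]):
    X = np.array([[e.features.values[f] for f in schema] for e in examples])
    y = np.array([e.label for e in examples])
    return X, y


def train_ensemble(
    examples: list[LabeledExample],
    rng: np.random.Generator,
    n_estimators: int = DEFAULT_N_TREES,
) -> Ensemble:
    """Train 10 random forests on independent balanced subsamples."""
    if not examples:
        raise ValueError("no training examples")
    schema = list(examples[0].features.values)
    forests = []
    sizes = []
    for _ in range(N_SUBCLASSIFIERS):
        sub = balanced_subsample(examples, rng)
        if len(sub) < 40:
            raise ValueError(
                f"only {len(sub)} examples after balancing; need >= 40"
            )
        X, y = _design_matrix(sub, schema)
        if np.all(X.std(axis=0) == 0):
            warnings.warn("all features have zero variance", stacklevel=2)
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X, y)
        forests.append(forest)
        sizes.append(len(sub))
    return Ensemble(
        forests=forests,
        schema=schema,
        metadata={
            "n_estimators": n_estimators,
            "subsample_sizes": sizes,
            "exclusion_nt": DEFAULT_EXCLUSION_NT,
        },
    )


def score_5imp(ensemble: Ensemble, features) -> np.ndarray | float:
    """5IMP score(s) in [0, 10]: sum of the 10 subclassifier outputs.

    ``features`` is a FeatureVector, a list of them, or a DataFrame whose
    columns cover the ensemble's schema.
    """
    single = isinstance(features, FeatureVector)
    if single:
        features = [features]
    if isinstance(features, pd.DataFrame):
        missing = [f for f in ensemble.schema if f not in features.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing: {missing}")
        X = features[ensemble.schema].to_numpy(dtype=float)
    else:
        for v in features:
            missing = [f for f in ensemble.schema if f not in v.values]
            if missing:
                raise ValueError(f"feature schema mismatch; missing: {missing}")
        X = np.array([[v.values[f] for f in ensemble.schema] for v in features])
    scores = ensemble.subclassifier_outputs(X).sum(axis=1)
    return float(scores[0]) if single else scores


def feature_importances(ensemble: Ensemble) -> pd.Series:
    """Mean impurity-based importance across the 10 subclassifiers."""
    imp = np.mean([f.feature_importances_ for f in ensemble.forests], axis=0)
    return pd.Series(imp, index=ensemble.schema).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Evaluation

def roc_pr(scores, labels) -> dict:
    """AUROC (rank statistic, ties averaged) and AUPRC (average precision).

    Also returns the naive-predictor baselines: AUC 0.5 and AUPRC equal to
    the positive-class prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (POS, 1, True) else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to evaluate")
    auc = float(roc_auc_score(y, scores))
    auprc = float(average_precision_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    prec, rec, _ = precision_recall_curve(y, scores)
    return {
        "auc": auc,
        "auprc": auprc,
        "roc_points": np.column_stack([fpr, tpr]),
        "pr_points": np.column_stack([rec, prec]),
        "baseline_auc": 0.5,
        "baseline_auprc": float(y.mean()),
    }


def cross_validate(
    examples: list[LabeledExample],
    k: int = 10,
    rng: np.random.Generator | None = None,
    n_estimators: int = DEFAULT_N_TREES,
    feature_rebuilder=None,
) -> CvResult:
    """Cluster-aware k-fold cross-validation with out-of-fold 5IMP scores.

    Folds partition clusters, never splitting one. When
    ``feature_rebuilder`` is given it is called per fold with the training
    transcript_ids and must return a function mapping an example to its
    feature dict rebuilt without held-out information (used to recompute
    motif enrichment features per fold).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    clusters = [e.cluster_id for e in examples]
    n_clusters = len(set(clusters))
    if n_clusters < k:
        raise ValueError(f"{n_clusters} clusters < {k} folds")
    schema = list(examples[0].features.values)
    # shuffle cluster identity mapping so fold composition depends on the rng
    uniq = sorted(set(clusters))
    perm = rng.permutation(len(uniq))
    cluster_rank = {c: int(perm[i]) for i, c in enumerate(uniq)}
    groups = np.array([cluster_rank[c] for c in clusters])

    rows = []
    splitter = GroupKFold(n_splits=k)
    X_idx = np.arange(len(examples))
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(X_idx, groups=groups, y=None)
    ):
        train = [examples[i] for i in train_idx]
        test = [examples[i] for i in test_idx]
        if feature_rebuilder is not None:
            remap = feature_rebuilder({e.transcript_id for e in train})
            train = [
                LabeledExample(e.transcript_id, e.cluster_id,
                               FeatureVector(e.transcript_id, remap(e)), e.label)
                for e in train
            ]
            test = [
                LabeledExample(e.transcript_id, e.cluster_id,
                               FeatureVector(e.transcript_id, remap(e)), e.label)
                for e in test
            ]
        ensemble = train_ensemble(train, rng, n_estimators=n_estimators)
        X_test, _ = _design_matrix(test, schema)
        fold_scores = ensemble.subclassifier_outputs(X_test).sum(axis=1)
        for e, s in zip(test, fold_scores):
            rows.append(
                {"transcript_id": e.transcript_id, "cluster_id": e.cluster_id,
                 "label": e.label, "fold": fold, "score": float(s)}
            )
    df = pd.DataFrame(rows)
    metrics = roc_pr(df["score"], df["label"])
    return CvResult(
        scores=df,
        auc=metrics["auc"],
        auprc=metrics["auprc"],
        roc_points=metrics["roc_points"],
        pr_points=metrics["pr_points"],
        baseline_auprc=metrics["baseline_auprc"],
    )
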