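"""End-to-end orchestration of the 5IM scoring pipeline.

The canonical order: simulate (or load) transcript models -> extract
evaluated 99-nt regions and intron contexts -> cluster by early-region
similarity -> discover motifs on a reserved cluster subset -> assemble the
36-feature vectors -> cluster-aware cross-validation of the balanced
ensemble -> train the final ensemble -> score downstream control windows
to form the empirical null -> call 5IM transcripts at a target FDR -> run
the association battery on simulated peak/expression tables.

Training transcripts are scored out-of-fold; every other transcript and
the control windows are scored by the final ensemble, mirroring the
train/apply split of the original protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from . import motifs as mf
from . import null_fdr as nf
from . import synthetic as syn
from . import transcript_io as tio
from .characterize import characterization_battery, er_filter_and_ratio, peak_overlap_first99
from .seq_features import DEFAULT_CONFIG, FeatureVector, assemble_features, AaBackground


@dataclass
class PipelineResult:
    params: syn.SimParams
    truth: pd.DataFrame
    regions: list
    contexts: dict
    clusters: list
    pssms: list
    cv: clf.CvResult | None
    ensemble: clf.Ensemble
    scores: pd.Series
    null: nf.NullDistribution
    calls: nf.ImpCalls
    battery: pd.DataFrame | None
    tables: dict = field(default_factory=dict)


def extract_dataset(models, genome, rng=None, with_controls: bool = True):
    """Evaluated regions, intron contexts, and (optionally) control windows."""
    regions, controls, contexts, skipped = [], [], {}, []
    for m in models:
        ok, reason = tio.assess_eligibility(m)
        if not ok:
            skipped.append((m.transcript_id, reason))
            continue
        regions.append(tio.extract_early_cds(m, genome))
        contexts[m.transcript_id] = tio.intron_context(m)
        if with_controls:
            ctrl = tio.sample_control_window(m, genome, rng)
            if ctrl is not None:
                controls.append(ctrl)
    return regions, controls, contexts, skipped


def discover_motifs(
    positive_regions, n_motifs: int, widths, rng, n_restarts: int = 4,
    n_sweeps: int = 8,
) -> list[mf.Pssm]:
    """Discover ``n_motifs`` PSSMs by iterative best-site masking."""
    seqs = [r.sequence if hasattr(r, "sequence") else r for r in positive_regions]
    pssms = []
    for k in range(n_motifs):
        pssm = mf.gibbs_discover(
            seqs, widths=widths, rng=rng, n_restarts=n_restarts,
            n_sweeps=n_sweeps, name=f"motif{k + 1}",
        )
        pssms.append(pssm)
        # mask the best instance in each sequence before the next round
        masked = []
        for s in seqs:
            hits = mf.scan_hits(s, pssm)
            if hits:
                o = hits[0].offset
                s = s[:o] + "N" * pssm.width + s[o + pssm.width :]
            masked.append(s)
        seqs = masked
    return pssms


def _base_feature_values(region, background, config):
    """Composition + ratio blocks (motif slots left to the caller)."""
    vec = assemble_features(region, [], [], background, config)
    return dict(vec.values)


def run_pipeline(
    params: syn.SimParams,
    n_estimators: int = 150,
    k_folds: int = 10,
    n_motifs: int = 2,
    motif_widths=(9,),
    reserve_fraction: float = 0.25,
    target_fdr: float = 0.05,
    run_cv: bool = True,
    run_battery: bool = True,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Simulate a transcriptome and run the full 5IM pipeline on it."""
    rng = rng or np.random.default_rng(params.seed)
    config = DEFAULT_CONFIG
    background = AaBackground.bundled_human()

    genome, models, truth = syn.simulate_genome_and_models(params, rng)
    regions, controls, contexts, skipped = extract_dataset(models, genome, rng)
    clusters = tio.cluster_early_regions(regions)
    cmap = tio.cluster_map(clusters)
    by_id = {r.transcript_id: r for r in regions}

    labels = {
        tid: (clf.POS if not ctx.has_5ui else clf.NEG)
        for tid, ctx in contexts.items()
    }

    # ---- reserved subset for motif discovery (whole clusters) -------------
    uniq_clusters = sorted({cmap[r.transcript_id] for r in regions})
    n_reserved = max(2, int(round(reserve_fraction * len(uniq_clusters))))
    reserved = set(
        np.array(uniq_clusters)[
            rng.choice(len(uniq_clusters), size=n_reserved, replace=False)
        ]
    )
    reserved_pos = [
        r for r in regions
        if cmap[r.transcript_id] in reserved
        and labels[r.transcript_id] == clf.POS
        and not r.high_ambiguity
        and (contexts[r.transcript_id].first_coding_intron_offset or 99) >= 90
    ]
    pssms = discover_motifs(reserved_pos, n_motifs, motif_widths, rng)

    # ---- hits cached once per motif ---------------------------------------
    working = [r for r in regions if cmap[r.transcript_id] not in reserved
               and not r.high_ambiguity]
    hits_per_motif = [
        [h for r in working for h in mf.scan_hits(r, p, min_score=0.0)]
        for p in pssms
    ]
    base_values = {
        r.transcript_id: _base_feature_values(r, background, config) for r in working
    }

    def tables_for(train_ids: set[str]) -> list[mf.EnrichmentTable]:
        sub_labels = {t: labels[t] == clf.POS for t in train_ids}
        out = []
        for p, hits in zip(pssms, hits_per_motif):
            sub = [h for h in hits if h.transcript_id in train_ids]
            out.append(
                mf.hit_significance(sub, sub_labels, motif_name=p.name)
                if sub else None
            )
        return out

    def values_with_tables(region, tables) -> dict[str, float]:
        vals = dict(base_values[region.transcript_id])
        for i in range(config.n_motifs):
            if i < len(pssms) and tables[i] is not None:
                s1, p1, s2, p2 = mf.motif_feature_values(region, pssms[i], tables[i])
            else:
                s1, p1, s2, p2 = 0.0, -1.0, 0.0, -1.0
            vals[f"motif{i + 1}_sig1"] = s1
            vals[f"motif{i + 1}_pos1"] = p1
            vals[f"motif{i + 1}_sig2"] = s2
            vals[f"motif{i + 1}_pos2"] = p2
        return vals

    # ---- training set ------------------------------------------------------
    all_ids = [r.transcript_id for r in working]
    full_tables = tables_for(set(all_ids))
    schema = config.feature_names()

    def make_example(r) -> clf.LabeledExample:
        vals = values_with_tables(r, full_tables)
        return clf.LabeledExample(
            transcript_id=r.transcript_id, cluster_id=cmap[r.transcript_id],
            features=FeatureVector(r.transcript_id, {n: vals[n] for n in schema}),
            label=labels[r.transcript_id],
        )

    examples = [make_example(r) for r in working]
    training = clf.build_training_set(examples, contexts)

    cv = None
    if run_cv:
        def rebuilder(train_ids: set[str]):
            tables = tables_for(train_ids)

            def remap(example: clf.LabeledExample) -> dict[str, float]:
                vals = values_with_tables(by_id[example.transcript_id], tables)
                return {n: vals[n] for n in schema}

            return remap

        cv = clf.cross_validate(
            training, k=k_folds, rng=rng, n_estimators=n_estimators,
            feature_rebuilder=rebuilder,
        )

    ensemble = clf.train_ensemble(training, rng, n_estimators=n_estimators)

    # ---- scores, null, calls ----------------------------------------------
    eval_vectors = [e.features for e in examples]
    eval_scores = clf.score_5imp(ensemble, eval_vectors)
    scores = pd.Series(eval_scores, index=[e.transcript_id for e in examples])
    if cv is not None:  # training transcripts keep their out-of-fold score
        oof = cv.scores.set_index("transcript_id")["score"]
        scores.loc[scores.index.intersection(oof.index)] = oof

    ctrl_working = [c for c in controls if c.transcript_id in base_values]
    ctrl_vectors = []
    for c in ctrl_working:
        vals = dict(_base_feature_values(c, background, config))
        for i in range(config.n_motifs):
            if i < len(pssms) and full_tables[i] is not None:
                s1, p1, s2, p2 = mf.motif_feature_values(c, pssms[i], full_tables[i])
            else:
                s1, p1, s2, p2 = 0.0, -1.0, 0.0, -1.0
            vals[f"motif{i + 1}_sig1"] = s1
            vals[f"motif{i + 1}_pos1"] = p1
            vals[f"motif{i + 1}_sig2"] = s2
            vals[f"motif{i + 1}_pos2"] = p2
        ctrl_vectors.append(FeatureVector(c.transcript_id, {n: vals[n] for n in schema}))
    ctrl_scores = clf.score_5imp(ensemble, ctrl_vectors)
    null = nf.fit_empirical_null(ctrl_scores, provenance={"model_version": "pipeline"})
    calls = nf.call_5im(scores, null, target_fdr=target_fdr,
                        model_version="pipeline")

    battery = None
    tables: dict = {}
    if run_battery:
        called = dict(calls.table["is_5im"])
        peak_set = syn.simulate_peaks(
            [m for m in models if m.transcript_id in called],
            called, params.peak_odds, rng,
        )
        overlap = peak_overlap_first99(
            peak_set, [m for m in models if m.transcript_id in called]
        )
        expr = syn.simulate_expression(
            list(scores.index), scores, params.copula_rho, rng
        )
        kept, _ = er_filter_and_ratio(expr)
        er_ratio = {r.gene_id: r.log2_ratio for r in kept}
        battery = characterization_battery(
            calls,
            target_sets={"early_cds_peak": overlap},
            quantitative_tables={"er_proximal_ratio": er_ratio},
        )
        tables = {"peaks": peak_set, "expression": expr}

    return PipelineResult(
        params=params, truth=truth, regions=regions, contexts=contexts,
        clusters=clusters, pssms=pssms, cv=cv, ensemble=ensemble,
        scores=scores, null=null, calls=calls, battery=battery, tables=tables,
    )
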