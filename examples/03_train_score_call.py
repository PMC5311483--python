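"""Train the balanced ensemble, cross-validate, and call 5IM transcripts.

Runs the full pipeline: motif discovery on a reserved cluster subset,
36-feature assembly, cluster-aware 10-fold cross-validation of the
10-subclassifier random-forest ensemble, control-window empirical null,
and FDR-based calling.
"""

from fiveimp import SimParams, run_pipeline

res = run_pipeline(SimParams(n_transcripts=600, seed=3),
                   n_estimators=100, k_folds=5, n_motifs=2)

print(f"out-of-fold AUROC  {res.cv.auc:.3f}  (naive baseline 0.500)")
print(f"out-of-fold AUPRC  {res.cv.auprc:.3f}  "
      f"(naive baseline = prevalence {res.cv.baseline_auprc:.3f})")
print(f"empirical null from {res.null.n} control windows")
s = res.calls.summary()
print(f"5IMP threshold at {s['target_fdr']:.0%} FDR: {s['threshold_score']:.2f}; "
      f"{s['fraction_called']:.1%} of transcripts called 5IM")
print("\nScores near 10 mean the early coding region looks like that of a "
      "transcript without 5'-proximal introns; calls are made where the "
      "control-window null makes such scores unlikely (q <= target FDR).")
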