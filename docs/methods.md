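# Methods

## Transcript geometry and eligibility

All coordinates are 0-based half-open internally. BED12 is read as-is,
genePred (UCSC tab dialect, optional leading bin column) is already
half-open, and GTF features (1-based inclusive) are converted on read; GTF
CDS/exon features are assembled per `transcript_id` via gffutils. Models
violating their invariants (unsorted/overlapping exons, CDS outside the
exon span, spliced CDS not a positive multiple of 3) are flagged with a
reason, never silently dropped.

A transcript is eligible for early-region analysis when it has at least
three coding exons (an exon counts as coding when it contains ≥ 1 coding
base), a spliced CDS of at least 99 nt, and a first-99-nt window straddling
at most two exons. The three-coding-exon rule exists so that every analyzed
transcript can also contribute a downstream control window; transcripts
with a CDS shorter than the fixed 99-nt feature window cannot be scored at
all.

Intron context is computed in transcript coordinates: `has_5ui` is true
when any exon–exon junction lies at or 5′ of the first coding base, and
`first_coding_intron_offset` counts the coding nucleotides strictly
upstream of the first junction inside the CDS (absent when the CDS lies in
one exon). Minus-strand sequence is reverse-complemented once, at
extraction; everything downstream is mRNA-sense.

Control windows are in-frame 99-nt windows whose first base lies at or
after the first coding base downstream of the third exon's last base,
chosen uniformly over the valid starts; transcripts with fewer than 99
such coding nucleotides contribute no control.

## Similarity clustering

Early regions are clustered single-linkage over pairs whose local
alignment is significant at E < 10⁻²⁵. Alignment uses Smith–Waterman
scores (+1 match, −3 mismatch, −5 gap open, −2 gap extend) via Biopython's
PairwiseAligner, with a blastn-style exact-word prefilter (default word
size 11) so the all-pairs cost stays near-linear on unrelated sequences;
as with word-seeded BLAST itself, a qualifying pair that shares no exact
word would be missed, which at these score parameters requires a
pathological mismatch-every-9th-base alignment. E-values use the
Karlin–Altschul form E = K·m·n·e^(−λS) with λ solved numerically from the
score system at uniform base composition and K = 0.711 (the tabulated
blastn value for +1/−3 scoring). The resulting partition is invariant to
input order; cluster representatives are the lexicographically smallest
member.

## The 36 features

The default schema (config-driven, replaceable) is:

| block | features | notes |
| --- | --- | --- |
| composition (5) | adenine_content, thymine_content, longest_non_a_run, at_free_codon_fraction, at_minimal_codon_preference | contents over unambiguous bases; codon fractions over N-free codons; ties in the min-(A+T) synonym count as minimal |
| regularized ratios (7) | R/K, L/I, L/M, I/V, D/E, Q/E, S/T | (c_a + m f_a)/(c_b + m f_b); pseudo-count mass m = 20 by default; background = bundled approximate human proteome frequencies, overridable |
| motif (24) | 6 motifs × {sig1, pos1, sig2, pos2} | significance = −log₁₀ Fisher enrichment p, capped at 300; positions are 0-based nucleotide offsets; sentinels (0, −1) when fewer than two qualifying instances |

Translation uses the standard code; position 1 is translated as written
(non-AUG starts are not forced to Met), internal stops become `*` and are
excluded (with `X` from N-containing codons) from amino-acid counts.
Feature extraction is a pure function of (sequence, config).

## Motif discovery and significance

One bundled Gibbs site sampler (one site per sequence, one held-out
sequence resampled per iteration, a ±1 site-shift move once per sweep to
phase-lock periodic motifs, information content as the restart-selection
objective) discovers forward-strand-only motifs; the iteration budget is
expressed in full sweeps over the sequence set so convergence does not
degrade with input size. The log-odds background is the average base
composition of the training regions rather than uniform, because early CDS
is GC-skewed and a uniform background would inflate CG-rich scores.
Externally derived PSSMs (JSON store or A/C/G/T matrix text) can be
substituted for discovery. Multiple motifs are found by masking each
sequence's best instance between rounds. All 99 − l + 1 valid starts are
scanned.

Instance significance comes from an enrichment table: for each observed
hit score s, a 2×2 Fisher exact test (one-sided, enrichment in 5UI⁻) of
"has a hit ≥ s" against the 5UI label. Inside cross-validation these
tables are rebuilt per fold from training transcripts only (the default);
a fixed-motif mode reuses tables built once on a reserved cluster subset.
Discovery itself always happens on the reserved subset, which is excluded
from training and evaluation.

## Ensemble, scoring, and evaluation

Ten random forests (default 500 trees each, √36 features per split,
unlimited depth; the pipeline and acceptance runs use 150 trees to keep
runtimes proportionate to the simulated problem sizes) are trained on
independent balanced subsamples (minority class passed through intact;
training requires ≥ 40 examples after balancing). A subclassifier's output
is its tree-vote POS fraction; the 5IMP score is the sum over the 10
subclassifiers, hence in [0, 10] and monotone in every subclassifier's
output.

Cross-validation partitions clusters across k = 10 folds (GroupKFold over
a seed-permuted cluster order) so near-duplicate regions never leak across
the split. AUROC is the rank statistic with tied ranks averaged; AUPRC is
average precision; both are computed by scikit-learn and verified against
brute-force pair-enumeration oracles in the tests. Naive baselines
(AUC 0.5, AUPRC = prevalence) are reported alongside every evaluation.

## Empirical null and FDR calling

Control-window scores from the same trained ensemble form the null
(provenance-checked via a model-version tag; < 100 controls disables
calling). Empirical p-values use the add-one estimator
p = (1 + #{null ≥ s})/(N + 1), which can never return 0. q-values use
Storey's estimator by default: π₀(λ) on the grid 0.05…0.95, a cubic
polynomial smoother evaluated at λ = 0.95 (clipped to [1/m, 1]), then the
π₀-scaled step-up with monotonization; Benjamini–Hochberg is available as
the alternative. A transcript is 5IM iff q ≤ the target FDR; the reported
threshold score is the smallest called score, and a fixed score threshold
can be supplied instead to reproduce a previously published operating
point. On a fully null score set, q-based calling at 5% FDR calls
essentially nothing — FDR control is not per-test calibration — so the
calibration checks in the tests assert the uniformity of the empirical
p-values and that the realized false-call rate stays at or below the
nominal target.

## Characterization battery

- Folding: the default backend is a simplified nearest-neighbor stacking
  DP over canonical pairs (GC/AU/GU; stack energy = −(strength_i +
  strength_j) with GC 1.7, AU 0.9, GU 0.5 kcal/mol; hairpin loop penalty
  4.5 + ln(size/3); helix-initiation penalty 1.0; minimum loop 3). It is a
  rank-order model, not a Turner-parameter implementation; any engine
  mapping a 35-nt window to ΔG ≤ 0 satisfies the contract, and an
  `RNAfold` subprocess backend is included. Windows must be exactly 35 nt;
  transcripts with shorter 5′UTRs are excluded upstream.
- tAI: per-codon weights over codons 2–33 (start codon excluded, stops
  undefined), median over defined positions. The bundled table is a
  synthetic representative (derived from codon-usage frequencies, max
  weight 1); real tables load from TSV.
- Tests: Fisher exact (two-sided; sample cross-product odds ratio, stated
  explicitly because packages differ), Wilcoxon rank-sum with the median
  score difference as effect, Spearman with average ranks (exact
  permutation p for n ≤ 8, where enumeration is feasible; t-approximation
  above), Holm across the 32 codon positions, Bonferroni across top-level
  characteristics and BH q-values within in-depth categories. The
  RBP-screen verdict requires Bonferroni p < 0.05 and median 5IMP
  difference > 1.
- Expression: records pass iff RPKM > 5 in either library and ≥ 30 reads
  in either; log₂(pulldown/input) with zero-denominator records excluded
  and tallied. TE classes are one standard deviation around the mean,
  exclusive bounds, intended for log2-scale efficiencies. Moving averages
  sort by score and slide a fixed-size window with step 1.
- Peak geometry: canonical EJC peaks have their (weighted, defaulting to
  midpoint) center 15–32 nt inclusive upstream of an exon–exon boundary;
  everything else is noncanonical, counted when overlapping coding
  positions [0, 99), grouped 0/1/2+; transcripts with RPKM ≤ 1 are
  excluded. Genomic peaks can be projected to transcript coordinates
  through the exon map (piecewise, merged).

## Synthetic data

The generator emulates the statistical structure the classifier and
battery assume, not the human genome: each transcript gets a 50–300 nt
5′UTR, a 480–780 nt CDS sampled from bundled human-like codon usage, a
100–300 nt 3′UTR, 4–6 exons with 80–500 nt introns (GT…AG), and a random
strand; introns are placed in genomic space by splitting exons so the
splicing logic is exercised, not bypassed. POS (5UI⁻-like) transcripts
have no 5′UTR junction and a first coding intron at 90–150 nt; NEG
transcripts carry a 5′UTR junction with probability 0.7 or an early coding
intron (3–87 nt) otherwise. Default dials are the strong study conditions:
71% POS, motif GCCGCCGCC implanted with probability 0.8, adenine depletion
0.1, peak odds 4, expression copula ρ 0.4.

The class signal is two-part: a synonymous recode of codons 2–33 toward
low-adenine synonyms (an exponential tilt on each family, with the tilt
strength solved so the expected per-nt depletion matches the dial) plus
the motif implant. Synonymous recoding has a hard ceiling (~0.082/nt under
the bundled usage, reached when every family sits on its minimum-adenine
codon); requests beyond it saturate at the ceiling, with the motif implant
contributing the remainder, so the measured class difference at the
default dial of 0.1 lands near 0.09. The dial is monotone throughout.
Because the recode is synonymous, the implanted signal is RNA-level only:
the amino-acid-ratio features carry no information in simulation, unlike
in real data where the class differs at the protein level too — passing
recovery tests therefore demonstrates the pipeline's mechanics, not the
real-data feature importance mix.

Peaks are Bernoulli early-CDS intervals whose odds are multiplied by the
dial for called transcripts; expression couples the log₂ pulldown/input
ratio (and log₂ TE) to the normal scores of the 5IMP ranks through a
Gaussian copula with the Pearson parameter chosen so the measured Spearman
correlation matches the dial, and a configurable fraction of records is
constructed to fail the printed filters.

## Numerical choices and problem sizes

Randomness flows from a single `numpy.random.Generator` per run; forests
receive integer seeds drawn from it, so whole-pipeline reruns at the same
seed are byte-identical. Ties in hit ranking break leftmost; ties in the
min-(A+T) synonym count count as minimal; empirical p-values live on the
add-one grid. The test suite and the acceptance script run the recovery
simulations at 2,000 transcripts with 150-tree subclassifiers and the
calibration checks at 20 seeds × 2,000 null scores — sizes chosen so each
property is measured with comfortable margins at desk scale.

## Known limitations

- The bundled amino-acid background, codon usage, and tAI tables are
  approximate or synthetic stand-ins; analyses of real transcriptomes
  should supply measured tables.
- The folding backend is a simplified stacking model suitable for ranking,
  not for absolute free energies.
- Word-seeded clustering inherits blastn's seed-miss blind spot.
- The generator does not model GC isochores, genome-scale length
  distributions, alternative isoforms beyond clustering, or protein-level
  class differences (see above).
- SignalP-style category labels are inputs, never predicted.
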