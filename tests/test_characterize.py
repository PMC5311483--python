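"""Folding windows, tAI profiles, association tests, filters, peak geometry."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fiveimp.characterize import (
    ExprRecord,
    PeakSet,
    TaiTable,
    characterization_battery,
    classify_ejc_peaks,
    er_filter_and_ratio,
    moving_average_by_score,
    peak_overlap_first99,
    per_position_group_test,
    score_quantity_correlation,
    tai_profile,
    target_set_association,
    translation_efficiency_classes,
)
from fiveimp.folding import NearestNeighborBackend, fold_energy_window

from conftest import make_toy_model, random_seq


# ---------------------------------------------------------------------------
# Folding

def test_poly_a_window_has_zero_energy():
    assert fold_energy_window("A" * 35) == 0.0


def test_gc_hairpin_strongly_negative():
    stem = "G" * 15
    window = stem + "AAAAA" + "C" * 15
    assert fold_energy_window(window) < -10


def test_wrong_window_length_rejected():
    with pytest.raises(ValueError, match="35"):
        fold_energy_window("A" * 34)


def test_backend_orders_structures_sensibly(rng):
    nn = NearestNeighborBackend()
    hairpin = "G" * 15 + "AAAAA" + "C" * 15
    random_w = random_seq(35, rng)
    assert nn.dg(hairpin) < nn.dg(random_w) <= 0.0


def test_hairpin_energy_regression_fixture():
    # frozen from a backend oracle run: GC stem stacks minus the loop penalty
    window = "G" * 15 + "AAAAA" + "C" * 15
    assert fold_energy_window(window) == pytest.approx(-43.2, abs=0.05)


# ---------------------------------------------------------------------------
# tAI profiles

def _uniform_table(w=0.5):
    from Bio.Data.CodonTable import standard_dna_table

    return TaiTable({c: w for c in standard_dna_table.forward_table})


def test_uniform_table_gives_flat_profile(rng):
    table = _uniform_table()
    weights, median = tai_profile(random_seq(96, rng) + "GGC", table)
    defined = weights[~np.isnan(weights)]
    assert np.all(defined == 1.0)  # weights rescaled so max = 1
    assert median == 1.0


def test_hand_toy_median():
    table = _uniform_table()
    table.weights["GCT"] = 0.2
    table.weights["GCC"] = 0.4
    table.weights["GCA"] = 0.6
    seq = "ATG" + "GCT" * 11 + "GCC" * 11 + "GCA" * 10
    weights, median = tai_profile(seq, table)
    assert median == pytest.approx(0.4)


def test_profile_matches_naive_lookup_oracle(rng):
    table = TaiTable.bundled_synthetic()
    seq = "ATG" + "".join(
        np.random.default_rng(0).choice(list(table.weights)) for _ in range(32)
    )
    weights, _ = tai_profile(seq, table)
    for i in range(32):
        codon = seq[3 * (i + 1) : 3 * (i + 2)]
        assert weights[i] == pytest.approx(table.weights[codon])


def test_stop_codons_have_no_weight():
    table = _uniform_table()
    seq = "ATG" + "TAA" + "GGC" * 31
    weights, median = tai_profile(seq, table)
    assert np.isnan(weights[0])
    assert median == 1.0


def holm_oracle(pvals):
    """Step-down enumeration of Holm-adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def test_identical_groups_all_adjusted_one(rng):
    profiles = rng.uniform(0.2, 1.0, size=(20, 32))
    results = per_position_group_test(profiles, profiles.copy())
    assert all(r.adjusted_p == 1.0 for r in results)


def test_shifted_group_all_positions_significant(rng):
    a = rng.uniform(0.3, 0.9, size=(200, 32))
    b = a + 0.2 + rng.normal(0, 0.02, size=(200, 32))
    results = per_position_group_test(a, b)
    assert all(r.adjusted_p < 0.05 for r in results)


def test_holm_adjustment_matches_oracle(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(30):
        p = rng.uniform(1e-6, 1, size=int(rng.integers(3, 40)))
        np.testing.assert_allclose(
            multipletests(p, method="holm")[1], holm_oracle(p), atol=1e-12
        )


# ---------------------------------------------------------------------------
# Target-set association

def test_balanced_table_gives_unit_or_and_p_one(rng):
    scores = rng.uniform(0, 10, 40)
    is_target = np.array([True] * 20 + [False] * 20)
    is_5im = np.array(([True] * 10 + [False] * 10) * 2)
    fisher, _ = target_set_association(scores, is_target, is_5im)
    assert fisher.effect == pytest.approx(1.0)
    assert fisher.p == pytest.approx(1.0)


def test_perfect_overlap_matches_hypergeometric_enumeration(rng):
    scores = rng.uniform(0, 10, 80)
    is_target = np.array([True] * 40 + [False] * 40)
    fisher, _ = target_set_association(scores, is_target, is_target.copy())
    # two-sided Fisher via point-probability rule, enumerated exhaustively
    def point_prob(a):
        return (math.comb(40, a) * math.comb(40, 40 - a)) / math.comb(80, 40)
    p_obs = point_prob(40)
    expected = sum(point_prob(a) for a in range(0, 41)
                   if point_prob(a) <= p_obs * (1 + 1e-12))
    assert fisher.p == pytest.approx(expected, rel=1e-6)


def test_random_targets_null_pvalues_valid(rng):
    """Null Fisher p-values are not anti-conservative across 500 replicates."""
    n = 200
    is_5im = np.array([True] * 60 + [False] * 140)
    ps = []
    for _ in range(500):
        targets = rng.permutation(np.array([True] * 50 + [False] * 150))
        fisher, _ = target_set_association(np.zeros(n) + rng.random(n),
                                           targets, is_5im)
        ps.append(fisher.p)
    ps = np.asarray(ps)
    assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
    for alpha in (0.05, 0.1, 0.2):
        se = math.sqrt(alpha * (1 - alpha) / len(ps))
        assert (ps <= alpha).mean() <= alpha + 3 * se


def test_wilcoxon_effect_is_median_difference(rng):
    scores = np.concatenate([rng.normal(7, 0.5, 50), rng.normal(4, 0.5, 50)])
    is_target = np.array([True] * 50 + [False] * 50)
    _, wilcoxon = target_set_association(scores, is_target,
                                         np.zeros(100, dtype=bool))
    assert wilcoxon.effect == pytest.approx(
        np.median(scores[:50]) - np.median(scores[50:])
    )
    assert wilcoxon.p < 1e-10


# ---------------------------------------------------------------------------
# Spearman correlation

def test_monotone_pairs_give_unit_rho():
    x = np.arange(20.0)
    assert score_quantity_correlation(x, x**3).effect == pytest.approx(1.0)
    assert score_quantity_correlation(x, -x).effect == pytest.approx(-1.0)


def test_tied_data_matches_rank_oracle(rng):
    x = np.round(rng.uniform(0, 5, 30), 0)
    y = np.round(rng.uniform(0, 5, 30), 0)
    r = score_quantity_correlation(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert r.effect == pytest.approx(oracle)


def test_small_n_exact_permutation_p():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([2.0, 1, 4, 3, 6, 5])
    r = score_quantity_correlation(x, y)
    rho = stats.spearmanr(x, y).statistic
    count = 0
    perms = list(itertools.permutations(range(6)))
    for perm in perms:
        rp = stats.spearmanr(x, y[list(perm)]).statistic
        count += abs(rp) >= abs(rho) - 1e-12
    assert r.p == pytest.approx(count / len(perms))


def test_zero_variance_flagged():
    r = score_quantity_correlation(np.ones(20), np.arange(20.0))
    assert math.isnan(r.effect) and "zero variance" in r.note


# ---------------------------------------------------------------------------
# TE classes and expression filters

def test_constant_te_all_mid():
    assert set(translation_efficiency_classes(np.ones(50))) == {"MID"}


def test_gaussian_tail_fractions(rng):
    v = rng.standard_normal(100_000)
    classes = translation_efficiency_classes(v)
    low = np.mean(classes == "LOW")
    high = np.mean(classes == "HIGH")
    assert low == pytest.approx(stats.norm.cdf(-1), abs=0.01)
    assert high == pytest.approx(stats.norm.sf(1), abs=0.01)


def test_extreme_outlier_lands_high():
    v = np.concatenate([np.random.default_rng(0).normal(0, 1, 99), [50.0]])
    assert translation_efficiency_classes(v)[-1] == "HIGH"


def _rec(gid, rpkm_in, rpkm_pd, reads_in, reads_pd):
    return ExprRecord(gid, rpkm_in, rpkm_pd, reads_in, reads_pd)


def test_er_filter_either_clauses():
    kept, _ = er_filter_and_ratio([_rec("a", 6.0, 0.5, 40, 10)])
    assert len(kept) == 1
    assert kept[0].log2_ratio == pytest.approx(math.log2(0.5 / 6.0))
    kept, _ = er_filter_and_ratio([_rec("b", 4.0, 4.5, 1000, 1000)])
    assert kept == []  # RPKM filter fires despite high reads


def test_er_filter_zero_denominator_tallied():
    kept, n_zero = er_filter_and_ratio([_rec("c", 0.0, 8.0, 40, 40)])
    assert kept == [] and n_zero == 1


def test_er_filter_idempotent(rng):
    records = [
        _rec(f"g{i}", float(rng.uniform(0, 20)), float(rng.uniform(0, 20)),
             int(rng.integers(0, 200)), int(rng.integers(0, 200)))
        for i in range(200)
    ]
    once, _ = er_filter_and_ratio(records)
    twice, n_zero = er_filter_and_ratio(once)
    assert n_zero == 0
    assert [(r.gene_id, r.log2_ratio) for r in twice] == [
        (r.gene_id, r.log2_ratio) for r in once
    ]


# ---------------------------------------------------------------------------
# Moving averages

def test_moving_average_flat_and_identity():
    scores = np.arange(250.0)
    mean_x, mean_y = moving_average_by_score(scores, np.ones(250), bin_size=100)
    assert len(mean_x) == 151
    assert np.allclose(mean_y, 1.0)
    _, ident = moving_average_by_score(scores, scores, bin_size=30)
    mx, _ = moving_average_by_score(scores, scores, bin_size=30)
    np.testing.assert_allclose(ident, mx)


def test_moving_average_commutes_with_affine(rng):
    scores = rng.uniform(0, 10, 300)
    values = rng.normal(size=300)
    _, base = moving_average_by_score(scores, values, 30)
    _, scaled = moving_average_by_score(scores, 3.0 * values + 2.0, 30)
    np.testing.assert_allclose(scaled, 3.0 * base + 2.0, atol=1e-9)


def test_moving_average_needs_enough_genes():
    with pytest.raises(ValueError):
        moving_average_by_score(np.arange(10.0), np.arange(10.0), 30)


# ---------------------------------------------------------------------------
# EJC peak geometry

def _ejc_model(rng):
    # plus strand, exons of 200/150/300 nt; CDS starts at transcript pos 100
    return make_toy_model(
        [(0, 200), (300, 450), (600, 900)], 100, 799, rng=rng
    )


def _peaks(rows):
    return PeakSet(name="ejc", peaks=pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "weighted_center"]
    ))


def test_canonical_window_inclusive_bounds(rng):
    model, _ = _ejc_model(rng)
    # junctions at transcript positions 200 and 350
    peaks = _peaks([
        ("tx1", 160, 190, 176.0),   # center 24 nt upstream of 200 -> canonical
        ("tx1", 150, 190, 168.0),   # 32 upstream -> canonical (inclusive)
        ("tx1", 170, 200, 185.0),   # 15 upstream -> canonical (inclusive)
        ("tx1", 140, 180, 160.0),   # 40 upstream -> noncanonical
        ("tx1", 185, 200, 186.0),   # 14 upstream -> noncanonical
    ])
    res = classify_ejc_peaks(peaks, model, rpkm=5.0)
    assert res.peak_labels == [
        "CANONICAL", "CANONICAL", "CANONICAL", "NONCANONICAL", "NONCANONICAL"
    ]


def test_noncanonical_count_in_first99_and_grouping(rng):
    model, _ = _ejc_model(rng)
    # CDS starts at tx 100; early coding region is [100, 199)
    peaks = _peaks([
        ("tx1", 100, 130, 110.0),  # nc, overlaps early region
        ("tx1", 150, 199, 160.0),  # nc, overlaps early region
        ("tx1", 400, 440, 420.0),  # nc, downstream
    ])
    res = classify_ejc_peaks(peaks, model, rpkm=2.0)
    assert res.nc_count_first99 == 2
    assert res.group == "2+"


def test_low_rpkm_transcript_excluded(rng):
    model, _ = _ejc_model(rng)
    res = classify_ejc_peaks(_peaks([("tx1", 100, 130, 110.0)]), model, rpkm=1.0)
    assert res.excluded


def test_peak_outside_transcript_rejected(rng):
    model, _ = _ejc_model(rng)
    with pytest.raises(ValueError, match="outside"):
        classify_ejc_peaks(_peaks([("tx1", 600, 700, 650.0)]), model, rpkm=5.0)


def test_classification_invariant_to_peak_order(rng):
    model, _ = _ejc_model(rng)
    rows = [("tx1", 160, 190, 176.0), ("tx1", 100, 130, 110.0),
            ("tx1", 150, 199, 160.0)]
    a = classify_ejc_peaks(_peaks(rows), model, rpkm=3.0)
    b = classify_ejc_peaks(_peaks(rows[::-1]), model, rpkm=3.0)
    assert sorted(a.peak_labels) == sorted(b.peak_labels)
    assert a.nc_count_first99 == b.nc_count_first99


# ---------------------------------------------------------------------------
# First-99 overlap

def test_overlap_boundary_half_open(rng):
    model, _ = make_toy_model([(0, 200), (300, 450), (600, 900)], 0, 699,
                              rng=rng)
    inside = PeakSet(name="p", peaks=pd.DataFrame(
        [("tx1", 98, 120)], columns=["transcript_id", "start", "end"]))
    outside = PeakSet(name="p", peaks=pd.DataFrame(
        [("tx1", 99, 120)], columns=["transcript_id", "start", "end"]))
    assert peak_overlap_first99(inside, [model])["tx1"]
    assert not peak_overlap_first99(outside, [model])["tx1"]


def test_overlap_matches_all_pairs_oracle(rng):
    models = []
    for i in range(20):
        m, _ = make_toy_model([(0, 200), (300, 450), (600, 900)], 30, 729,
                              tid=f"m{i}", rng=rng)
        models.append(m)
    rows = [
        (f"m{int(rng.integers(0, 20))}", int(s), int(s + rng.integers(5, 60)))
        for s in rng.integers(0, 700, size=300)
    ]
    peaks = PeakSet(name="p", peaks=pd.DataFrame(
        rows, columns=["transcript_id", "start", "end"]))
    got = peak_overlap_first99(peaks, models)
    for m in models:
        c0, _ = m.cds_tx_interval()
        expected = any(
            tid == m.transcript_id and s < c0 + 99 and e > c0
            for tid, s, e in rows
        )
        assert got[m.transcript_id] == expected


# ---------------------------------------------------------------------------
# Battery

def _calls_frame(rng, n=200):
    scores = rng.uniform(0, 10, n)
    df = pd.DataFrame(
        {"score": scores, "p": rng.uniform(0.001, 1, n),
         "q": rng.uniform(0.001, 1, n), "is_5im": scores > 7},
        index=[f"t{i}" for i in range(n)],
    )
    df.index.name = "transcript_id"
    return df


def test_single_test_bonferroni_identity(rng):
    calls = _calls_frame(rng)
    targets = {f"t{i}": bool(i % 3 == 0) for i in range(200)}
    out = characterization_battery(calls, target_sets={"set1": targets})
    fisher_row = out[out["test"] == "fisher"].iloc[0]
    # one characteristic -> Bonferroni multiplier is 1
    assert fisher_row["adjusted_p"] == pytest.approx(fisher_row["p"])


def test_family_wise_error_controlled(rng):
    """20 null characteristics, 100 replicates: FWER within the binomial bound."""
    n = 150
    errors = 0
    for rep in range(100):
        calls = _calls_frame(rng, n)
        target_sets = {
            f"s{j}": {f"t{i}": bool(v) for i, v in enumerate(rng.random(n) < 0.3)}
            for j in range(20)
        }
        out = characterization_battery(calls, target_sets=target_sets)
        errors += bool((out["adjusted_p"] < 0.05).any())
    # binomial(100, 0.05) upper 95% bound
    assert errors <= 10


def test_implanted_odds_ratio_detected(rng):
    """OR = 4 target sets at n = 2000 are detected after Bonferroni."""
    detected = 0
    n = 2000
    for rep in range(20):
        scores = rng.uniform(0, 10, n)
        is_5im = scores > 7
        p_t = np.where(is_5im, 0.4, 1 / (1 + (1 - 0.1) / (0.1 * 4)))
        base_odds = (0.4 / 0.6) / 4
        p_nontarget = base_odds / (1 + base_odds)
        targets = np.where(is_5im, rng.random(n) < 0.4,
                           rng.random(n) < p_nontarget)
        calls = pd.DataFrame({"score": scores, "is_5im": is_5im},
                             index=[f"t{i}" for i in range(n)])
        out = characterization_battery(
            calls, target_sets={"implant": dict(zip(calls.index, targets))}
        )
        fisher_row = out[out["test"] == "fisher"].iloc[0]
        detected += bool(fisher_row["adjusted_p"] < 0.05)
    assert detected >= 19


def test_battery_requires_input(rng):
    with pytest.raises(ValueError):
        characterization_battery(_calls_frame(rng))


def test_rbp_screen_rule(rng):
    n = 400
    scores = np.concatenate([rng.uniform(6, 10, 200), rng.uniform(0, 4, 200)])
    calls = pd.DataFrame({"score": scores, "is_5im": scores > 7},
                         index=[f"t{i}" for i in range(n)])
    targets = {f"t{i}": i < 200 for i in range(n)}  # targets have high scores
    out = characterization_battery(calls, target_sets={"rbp1": targets},
                                   rbp_screen={"rbp1"})
    row = out[(out["characteristic"] == "rbp1") & (out["test"] == "wilcoxon")].iloc[0]
    assert row["rbp_screen_hit"] is True or row["rbp_screen_hit"] == True  # noqa: E712
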