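"""Transcript geometry, region extraction, and clustering."""

import numpy as np
import pytest

from fiveimp import transcript_io as tio
from fiveimp.transcript_io import (
    EarlyRegion,
    alignment_evalue,
    assess_eligibility,
    cluster_early_regions,
    extract_early_cds,
    intron_context,
    read_transcript_models,
    sample_control_window,
    write_bed12,
)

from conftest import make_toy_model, oracle_spliced_cds, random_seq


# ---------------------------------------------------------------------------
# Readers

def test_bed12_three_blocks_maps_exons_and_cds(tmp_path):
    line = "chr1\t100\t800\ttxA\t0\t+\t150\t751\t0\t3\t100,100,100,\t0,300,600,"
    p = tmp_path / "m.bed"
    p.write_text(line + "\n")
    (m,) = read_transcript_models(p, "bed12")
    assert m.exons == [(100, 200), (400, 500), (700, 800)]
    assert (m.cds_start, m.cds_end) == (150, 751)
    assert m.valid


def test_bed12_zero_length_cds_flagged_not_dropped(tmp_path):
    line = "chr1\t0\t300\ttxB\t0\t+\t100\t100\t0\t1\t300,\t0,"
    p = tmp_path / "m.bed"
    p.write_text(line + "\n")
    (m,) = read_transcript_models(p, "bed12")
    assert not m.valid
    assert "no CDS" in m.invalid_reason


def test_malformed_line_error_names_line_number(tmp_path):
    p = tmp_path / "m.bed"
    p.write_text("chr1\t100\t800\ttxA\t0\t+\t150\t750\t0\t3\t100,100,100,\t0,300,600,\n"
                 "chr1\tnot_an_int\t800\ttxB\n")
    with pytest.raises(ValueError, match="line 2"):
        read_transcript_models(p, "bed12")


def test_genepred_minus_strand_matches_base_walk_oracle(tmp_path, rng):
    fields = ["txC", "chr2", "-", "100", "800", "150", "750", "3",
              "100,400,700,", "200,500,800,"]
    p = tmp_path / "m.gp"
    p.write_text("\t".join(fields) + "\n")
    (m,) = read_transcript_models(p, "genepred")
    assert m.exons == [(100, 200), (400, 500), (700, 800)]
    genome = {"chr2": random_seq(900, rng)}
    # spliced CDS equals the naive walk, reverse-complemented for minus strand
    c0, c1 = m.cds_tx_interval()
    spliced = m.spliced_sequence(genome)[c0:c1]
    assert spliced == oracle_spliced_cds(genome, m)


def test_gtf_reader_assembles_cds_per_transcript(tmp_path):
    attrs = 'gene_id "g1"; transcript_id "txG";'
    lines = [
        f"chr3\tsrc\texon\t101\t200\t.\t+\t.\t{attrs}",
        f"chr3\tsrc\texon\t301\t400\t.\t+\t.\t{attrs}",
        f"chr3\tsrc\texon\t501\t700\t.\t+\t.\t{attrs}",
        f"chr3\tsrc\tCDS\t151\t200\t.\t+\t0\t{attrs}",
        f"chr3\tsrc\tCDS\t301\t400\t.\t+\t1\t{attrs}",
        f"chr3\tsrc\tCDS\t501\t550\t.\t+\t2\t{attrs}",
    ]
    p = tmp_path / "m.gtf"
    p.write_text("\n".join(lines) + "\n")
    (m,) = read_transcript_models(p, "gtf")
    assert m.exons == [(100, 200), (300, 400), (500, 700)]
    assert (m.cds_start, m.cds_end) == (150, 550)
    assert m.spliced_cds_length() == 200  # flagged: not a multiple of 3
    assert not m.valid


def test_bed12_roundtrip_preserves_geometry(tmp_path):
    from fiveimp.synthetic import SimParams, simulate_genome_and_models

    _, models, _ = simulate_genome_and_models(SimParams(n_transcripts=20, seed=3))
    p = tmp_path / "rt.bed"
    write_bed12(models, p)
    back = read_transcript_models(p, "bed12")
    for a, b in zip(models, back):
        assert a.transcript_id == b.transcript_id
        assert a.exons == b.exons
        assert (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end)
        assert a.strand == b.strand


# ---------------------------------------------------------------------------
# Eligibility and intron context

def test_two_coding_exons_ineligible():
    m, _ = make_toy_model([(0, 100), (200, 300)], 10, 251)
    ok, reason = assess_eligibility(m)
    assert not ok and "fewer than three coding exons" in reason


def test_straddle_two_exons_is_eligible():
    # 4 coding exons; first 99 coding nt inside exons 1-2
    m, _ = make_toy_model([(0, 100), (200, 300), (400, 500), (600, 700)], 40, 643)
    ok, reason = assess_eligibility(m)
    assert ok, reason


def test_straddle_three_exons_ineligible():
    # 30 + 30 coding nt in exons 1-2 puts base 99 into exon 3
    m, _ = make_toy_model([(0, 100), (200, 230), (400, 500), (600, 700)], 70, 647)
    ok, reason = assess_eligibility(m)
    assert not ok and "straddle" in reason


def test_short_cds_ineligible():
    m, _ = make_toy_model([(0, 50), (100, 150), (200, 250)], 10, 206)
    ok, reason = assess_eligibility(m)
    assert not ok and "shorter than 99" in reason


def test_intron_context_5utr_junction():
    # junction 10 nt upstream of the start codon -> 5UI present
    m, _ = make_toy_model([(0, 40), (100, 400), (500, 800)], 110, 711)
    ctx = intron_context(m)
    assert ctx.has_5ui
    assert ctx.first_coding_intron_offset == 290  # junction at tx 340, AUG at tx 50


def test_intron_context_single_coding_exon_offset_absent():
    m, _ = make_toy_model([(0, 300), (400, 500)], 10, 250)
    ctx = intron_context(m)
    assert not ctx.has_5ui
    assert ctx.first_coding_intron_offset is None


def test_intron_context_offset_base_walk_case():
    # AUG at transcript position 50, junctions at tx 120 and 300, CDS 400 nt
    m, _ = make_toy_model([(0, 120), (200, 380), (500, 800)], 50, 650)
    assert m.spliced_cds_length() == 400
    ctx = intron_context(m)
    assert not ctx.has_5ui
    assert ctx.first_coding_intron_offset == 70


# ---------------------------------------------------------------------------
# Early-region extraction

def test_extract_early_cds_matches_manual_splice(rng):
    # CDS split 60 + 39+ across exons 1-2
    m, genome = make_toy_model(
        [(0, 100), (200, 260), (300, 400)], 40, 363, rng=rng
    )
    region = extract_early_cds(m, genome)
    manual = genome["chr1"][40:100] + genome["chr1"][200:239]
    assert region.sequence == manual
    assert region.kind == "EVALUATED" and region.window_offset == 0


def test_extract_early_cds_minus_strand_matches_oracle(rng):
    m, genome = make_toy_model(
        [(0, 100), (200, 260), (300, 400)], 37, 360, strand="-", rng=rng
    )
    region = extract_early_cds(m, genome)
    assert region.sequence == oracle_spliced_cds(genome, m)[:99]


def test_extract_early_cds_deterministic(rng):
    m, genome = make_toy_model([(0, 100), (200, 260), (300, 400)], 40, 363, rng=rng)
    assert extract_early_cds(m, genome).sequence == extract_early_cds(m, genome).sequence


def test_extract_all_simulated_models_match_oracle(small_sim):
    for m in small_sim["models"][:40]:
        ok, _ = assess_eligibility(m)
        if not ok:
            continue
        region = extract_early_cds(m, small_sim["genome"])
        assert region.sequence == oracle_spliced_cds(small_sim["genome"], m)[:99]


def test_missing_contig_raises(rng):
    m, _ = make_toy_model([(0, 100), (200, 260), (300, 400)], 40, 363, rng=rng)
    with pytest.raises(KeyError, match="contig"):
        extract_early_cds(m, {"other": "ACGT"})


# ---------------------------------------------------------------------------
# Control windows

def test_control_window_none_when_tail_too_short(rng):
    # only 80 coding nt downstream of exon 3
    m, genome = make_toy_model(
        [(0, 100), (200, 310), (400, 521), (600, 680)], 0, 680, rng=rng
    )
    assert m.spliced_cds_length() % 3 == 0
    assert sample_control_window(m, genome, np.random.default_rng(0)) is None


def test_control_window_in_frame_and_deterministic(rng):
    exons = [(0, 100), (200, 310), (400, 520), (600, 900)]
    m, genome = make_toy_model(exons, 0, 900, rng=rng)
    w1 = sample_control_window(m, genome, np.random.default_rng(5))
    w2 = sample_control_window(m, genome, np.random.default_rng(5))
    assert w1.window_offset % 3 == 0
    assert w1.kind == "CONTROL"
    assert (w1.window_offset, w1.sequence) == (w2.window_offset, w2.sequence)


def test_control_window_covers_all_valid_starts(rng):
    exons = [(0, 100), (200, 310), (400, 520), (600, 900)]
    m, genome = make_toy_model(exons, 0, 900, rng=rng)
    valid = set(tio.control_window_offsets(m))
    assert valid == set(range(330, 532, 3))  # offsets 330..531 step 3
    g = np.random.default_rng(11)
    seen = {sample_control_window(m, genome, g).window_offset for _ in range(1000)}
    assert seen == valid


# ---------------------------------------------------------------------------
# Clustering

def _region(tid, seq):
    return EarlyRegion(transcript_id=tid, sequence=seq, kind="EVALUATED",
                       window_offset=0, n_exons_straddled=1)


def test_identical_regions_cluster_together(rng):
    s = random_seq(99, rng)
    clusters = cluster_early_regions([_region("a", s), _region("b", s)])
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["a", "b"]


def test_random_regions_are_singletons(rng):
    regions = [_region(f"t{i}", random_seq(99, rng)) for i in range(60)]
    clusters = cluster_early_regions(regions)
    assert len(clusters) == 60


def test_random_pair_alignment_scores_far_from_threshold(rng):
    """Smith-Waterman score distribution oracle on random 99-mer pairs."""
    aligner = tio._make_aligner()
    scores = [
        aligner.score(random_seq(99, rng), random_seq(99, rng)) for _ in range(200)
    ]
    # every random pair's E-value is astronomically above the 1e-25 threshold
    assert min(alignment_evalue(s) for s in scores) > 1e-3


def test_single_linkage_transitivity(rng):
    a = random_seq(99, rng)
    b = a[:50] + random_seq(49, rng)   # shares 50-nt block with a
    c = random_seq(50, rng) + b[50:]   # shares 49-nt block with b, not a
    clusters = cluster_early_regions([_region("a", a), _region("b", b), _region("c", c)])
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["a", "b", "c"]


def test_clustering_invariant_to_input_order(rng):
    seqs = [random_seq(99, rng) for _ in range(20)]
    dup = seqs[3]
    regions = [_region(f"t{i}", s) for i, s in enumerate(seqs)] + [_region("dup", dup)]
    part1 = {frozenset(c.member_ids) for c in cluster_early_regions(regions)}
    part2 = {frozenset(c.member_ids) for c in cluster_early_regions(regions[::-1])}
    assert part1 == part2
    assert frozenset({"t3", "dup"}) in part1


# ---------------------------------------------------------------------------
# Region invariants

def test_region_rejects_bad_length_and_alphabet():
    with pytest.raises(ValueError, match="length"):
        _region("x", "ACGT")
    with pytest.raises(ValueError, match="invalid characters"):
        _region("x", "X" * 99)


def test_high_ambiguity_flag():
    seq = "N" * 11 + "ACG" * 29 + "A"
    assert _region("x", seq).high_ambiguity
    seq2 = "N" * 9 + "ACG" * 30
    assert not _region("x", seq2).high_ambiguity


def test_regions_tsv_roundtrip(tmp_path, rng):
    regions = [_region(f"t{i}", random_seq(99, rng)) for i in range(5)]
    p = tmp_path / "regions.tsv"
    tio.regions_to_tsv(regions, p)
    back = tio.regions_from_tsv(p)
    assert [(r.transcript_id, r.sequence) for r in back] == [
        (r.transcript_id, r.sequence) for r in regions
    ]
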