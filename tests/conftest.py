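"""Shared fixtures: toy genomes/models and independent coordinate oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fiveimp.transcript_io import TranscriptModel

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def oracle_spliced_cds(genome: dict[str, str], model: TranscriptModel) -> str:
    """Independent base-by-base walk of the coding sequence.

    Collects every exonic genomic position inside the CDS span one base at
    a time, then orients to mRNA sense. Deliberately naive: no interval
    arithmetic shared with the package implementation.
    """
    chrom = genome[model.chrom]
    bases = []
    for s, e in model.exons:
        for g in range(s, e):
            if model.cds_start <= g < model.cds_end:
                bases.append(chrom[g])
    seq = "".join(bases)
    return revcomp(seq) if model.strand == "-" else seq


def oracle_spliced_transcript(genome: dict[str, str], model: TranscriptModel) -> str:
    chrom = genome[model.chrom]
    seq = "".join(chrom[g] for s, e in model.exons for g in range(s, e))
    return revcomp(seq) if model.strand == "-" else seq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_model(
    exons, cds_start, cds_end, strand="+", chrom="chr1", tid="tx1",
    category="OTHER", genome_len=None, rng=None,
):
    """A TranscriptModel plus a random genome dict covering its span."""
    rng = rng or np.random.default_rng(0)
    end = genome_len or (max(e for _, e in exons) + 10)
    genome = {chrom: random_seq(end, rng)}
    model = TranscriptModel(
        transcript_id=tid, chrom=chrom, strand=strand, exons=list(exons),
        cds_start=cds_start, cds_end=cds_end, category=category,
    )
    return model, genome


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated transcriptome shared across tests (read-only)."""
    from fiveimp.pipeline import extract_dataset
    from fiveimp.synthetic import SimParams, simulate_genome_and_models

    params = SimParams(n_transcripts=120, seed=7)
    genome, models, truth = simulate_genome_and_models(params)
    regions, controls, contexts, skipped = extract_dataset(
        models, genome, np.random.default_rng(7)
    )
    return {
        "params": params, "genome": genome, "models": models, "truth": truth,
        "regions": regions, "controls": controls, "contexts": contexts,
        "skipped": skipped,
    }
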