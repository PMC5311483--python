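"""Transcript models, early-coding-region extraction, and similarity clustering.

All genomic coordinates are 0-based, half-open internally.  BED12 is accepted
as-is; genePred (UCSC tab dialect) is already 0-based half-open; GTF is
converted on read.  All sequence handling downstream of extraction is
mRNA-sense: minus-strand slices are reverse-complemented at extraction time,
never later.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Seq import reverse_complement

EARLY_LEN = 99

CATEGORIES = ("SSCR", "MSCR", "SIGNALP_POS", "OTHER")

_VALID_BASES = frozenset("ACGTN")


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS geometry on a genome plus a category label.

    ``exons`` are genomic intervals sorted by start; ``cds_start``/``cds_end``
    delimit the translated span in genomic coordinates irrespective of strand.
    Invalid models are flagged (``valid=False`` with ``invalid_reason``), not
    dropped, so callers can report them.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    category: str = "OTHER"
    source_line: str = ""
    valid: bool = True
    invalid_reason: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.transcript_id}: unknown category {self.category!r}")
        self._validate()

    def _validate(self) -> None:
        if not self.valid:
            return
        ex = self.exons
        if not ex:
            self._flag("no exons")
            return
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if s1 < e0:
                self._flag("exons unsorted or overlapping")
                return
        if any(s >= e for s, e in ex):
            self._flag("empty exon")
            return
        if self.cds_start >= self.cds_end:
            self._flag("no CDS")
            return
        if self.cds_start < ex[0][0] or self.cds_end > ex[-1][1]:
            self._flag("CDS outside exons")
            return
        n = self.spliced_cds_length()
        if n <= 0 or n % 3 != 0:
            self._flag(f"spliced CDS length {n} not a positive multiple of 3")

    def _flag(self, reason: str) -> None:
        self.valid = False
        self.invalid_reason = reason

    # -- transcript-coordinate geometry -------------------------------------

    def exon_lengths_tx(self) -> list[int]:
        """Exon lengths in transcript (5'->3') order."""
        lens = [e - s for s, e in self.exons]
        return lens[::-1] if self.strand == "-" else lens

    def junctions_tx(self) -> list[int]:
        """Exon-exon junction positions in transcript coordinates.

        A junction at position j means j transcript bases precede it (the
        first base of the downstream exon is at transcript position j).
        """
        lens = self.exon_lengths_tx()
        out, acc = [], 0
        for ln in lens[:-1]:
            acc += ln
            out.append(acc)
        return out

    def _genomic_to_tx(self, gpos: int) -> int:
        """Transcript coordinate of the exonic genomic position ``gpos``."""
        acc = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= gpos < e:
                    return acc + (gpos - s)
                acc += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= gpos < e:
                    return acc + (e - 1 - gpos)
                acc += e - s
        raise ValueError(f"{self.transcript_id}: position {gpos} not exonic")

    def cds_tx_interval(self) -> tuple[int, int]:
        """CDS as a half-open interval in transcript coordinates."""
        if self.strand == "+":
            t0 = self._genomic_to_tx(self.cds_start)
            t1 = self._genomic_to_tx(self.cds_end - 1) + 1
        else:
            t0 = self._genomic_to_tx(self.cds_end - 1)
            t1 = self._genomic_to_tx(self.cds_start) + 1
        return t0, t1

    def spliced_cds_length(self) -> int:
        total = 0
        for s, e in self.exons:
            total += max(0, min(e, self.cds_end) - max(s, self.cds_start))
        return total

    def n_coding_exons(self) -> int:
        """Exons containing at least one coding base."""
        return sum(
            1 for s, e in self.exons if min(e, self.cds_end) - max(s, self.cds_start) > 0
        )

    def spliced_sequence(self, genome) -> str:
        """mRNA-sense spliced transcript sequence."""
        parts = [fetch_sequence(genome, self.chrom, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq

    def tx_window_exons(self, t_start: int, t_end: int) -> int:
        """Number of exons straddled by transcript interval [t_start, t_end)."""
        juncs = self.junctions_tx()
        return 1 + sum(1 for j in juncs if t_start < j < t_end)


@dataclass
class IntronContext:
    """Where introns fall relative to the start codon, in transcript space."""

    has_5ui: bool
    first_coding_intron_offset: int | None
    n_coding_exons: int


@dataclass
class EarlyRegion:
    """A 99-nt in-frame coding window (evaluated or downstream control)."""

    transcript_id: str
    sequence: str
    kind: str  # EVALUATED or CONTROL
    window_offset: int
    n_exons_straddled: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != EARLY_LEN:
            raise ValueError(
                f"{self.transcript_id}: region length {len(self.sequence)} != {EARLY_LEN}"
            )
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"{self.transcript_id}: invalid characters {bad}")
        if self.kind not in ("EVALUATED", "CONTROL"):
            raise ValueError(f"kind must be EVALUATED or CONTROL, got {self.kind!r}")
        if self.window_offset % 3 != 0 or self.window_offset < 0:
            raise ValueError(f"window_offset {self.window_offset} not a multiple of 3")
        if self.kind == "EVALUATED" and self.n_exons_straddled > 2:
            raise ValueError("evaluated region straddles more than 2 exons")

    @property
    def n_fraction(self) -> float:
        return self.sequence.count("N") / EARLY_LEN

    @property
    def high_ambiguity(self) -> bool:
        """Regions with N at >10% of positions are excluded from training."""
        return self.n_fraction > 0.10


@dataclass
class TranscriptCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("empty cluster")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative not a member")


# ---------------------------------------------------------------------------
# Genome access

def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a genome store (pyfaidx.Fasta or mapping)."""
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise KeyError(f"contig {chrom!r} not in genome")
        return str(genome[chrom][start:end]).upper()
    try:
        rec = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} not in genome") from exc
    return str(rec[start:end]).upper()


# ---------------------------------------------------------------------------
# Readers / writers

def read_category_labels(path) -> dict[str, str]:
    """TSV of (transcript_id, category); unknown categories rejected."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
            if parts[0] == "transcript_id":  # header
                continue
            if parts[1] not in CATEGORIES:
                raise ValueError(f"{path}:{i}: unknown category {parts[1]!r}")
            labels[parts[0]] = parts[1]
    return labels


def _parse_bed12_line(line: str, lineno: int, labels: Mapping[str, str]) -> TranscriptModel:
    f = line.split("\t")
    if len(f) < 12:
        raise ValueError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED12 field ({exc})") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"line {lineno}: blockCount does not match block lists")
    exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
    return TranscriptModel(
        transcript_id=name,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=thick_start,
        cds_end=thick_end,
        category=labels.get(name, "OTHER"),
        source_line=f"line {lineno}",
    )


def _parse_genepred_line(line: str, lineno: int, labels: Mapping[str, str]) -> TranscriptModel:
    f = line.split("\t")
    # optional leading bin column (UCSC database dumps)
    if len(f) >= 11 and f[0].isdigit() and f[2] in ("+", "-"):
        f = f[1:]
    if len(f) < 10:
        raise ValueError(f"line {lineno}: genePred needs >=10 fields, got {len(f)}")
    try:
        name, chrom, strand = f[0], f[1], f[2]
        cds_start, cds_end = int(f[5]), int(f[6])
        starts = [int(x) for x in f[8].rstrip(",").split(",")]
        ends = [int(x) for x in f[9].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed genePred field ({exc})") from exc
    if len(starts) != len(ends):
        raise ValueError(f"line {lineno}: exonStarts/exonEnds length mismatch")
    return TranscriptModel(
        transcript_id=name,
        chrom=chrom,
        strand=strand,
        exons=list(zip(starts, ends)),
        cds_start=cds_start,
        cds_end=cds_end,
        category=labels.get(name, "OTHER"),
        source_line=f"line {lineno}",
    )


def _read_gtf(path, labels: Mapping[str, str]) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValueError(f"GTF feature without transcript_id: {feat}")
        rec = per_tx.setdefault(
            tid, {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        interval = (feat.start - 1, feat.end)  # 1-based inclusive -> half-open
        rec[{"exon": "exons", "CDS": "cds"}[feat.featuretype]].append(interval)
    models = []
    for tid, rec in per_tx.items():
        exons = sorted(rec["exons"])
        if not rec["cds"]:
            m = TranscriptModel(tid, rec["chrom"], rec["strand"] or "+", exons, 0, 0,
                                labels.get(tid, "OTHER"), source_line="gtf")
            m.valid, m.invalid_reason = False, "no CDS"
            models.append(m)
            continue
        cds_start = min(s for s, _ in rec["cds"])
        cds_end = max(e for _, e in rec["cds"])
        models.append(
            TranscriptModel(tid, rec["chrom"], rec["strand"] or "+", exons,
                            cds_start, cds_end, labels.get(tid, "OTHER"),
                            source_line="gtf")
        )
    return models


def read_transcript_models(path, format: str, labels=None) -> list[TranscriptModel]:
    """Read transcript models from BED12, genePred, or GTF.

    ``labels`` maps transcript_id -> category (or is a path to such a TSV);
    transcripts missing from it get category OTHER.
    """
    if labels is None:
        labels = {}
    elif not isinstance(labels, Mapping):
        labels = read_category_labels(labels)
    if format == "gtf":
        return _read_gtf(path, labels)
    parsers = {"bed12": _parse_bed12_line, "genepred": _parse_genepred_line}
    if format not in parsers:
        raise ValueError(f"unknown format {format!r}; expected bed12, genepred, or gtf")
    parse = parsers[format]
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            models.append(parse(line, lineno, labels))
    return models


def write_bed12(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - start) for s, _ in m.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, start, end, m.transcript_id, 0, m.strand,
                        m.cds_start, m.cds_end, 0, len(m.exons), sizes, starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Eligibility, intron context, region extraction

def assess_eligibility(model: TranscriptModel) -> tuple[bool, str]:
    """Apply the early-region eligibility rules.

    Ineligible if the transcript has fewer than three coding exons, if the
    spliced CDS is shorter than the 99-nt window, or if the first 99 coding
    nt straddle more than two exons.
    """
    if not model.valid:
        return False, f"invalid model: {model.invalid_reason}"
    if model.n_coding_exons() < 3:
        return False, "fewer than three coding exons"
    if model.spliced_cds_length() < EARLY_LEN:
        return False, "spliced CDS shorter than 99 nt"
    c0, _ = model.cds_tx_interval()
    if model.tx_window_exons(c0, c0 + EARLY_LEN) > 2:
        return False, "first 99 coding nt straddle more than two exons"
    return True, ""


def intron_context(model: TranscriptModel) -> IntronContext:
    """Locate the first intron relative to the start codon.

    has_5ui: at least one junction at or upstream of the first coding base.
    first_coding_intron_offset: coding nt strictly upstream of the first
    junction inside the CDS; absent when the CDS lies in a single exon.
    """
    c0, c1 = model.cds_tx_interval()
    juncs = model.junctions_tx()
    has_5ui = any(j <= c0 for j in juncs)
    coding_juncs = [j for j in juncs if c0 < j < c1]
    offset = min(coding_juncs) - c0 if coding_juncs else None
    return IntronContext(
        has_5ui=has_5ui,
        first_coding_intron_offset=offset,
        n_coding_exons=model.n_coding_exons(),
    )


def extract_early_cds(model: TranscriptModel, genome) -> EarlyRegion:
    """The first 99 coding nt as an mRNA-sense EVALUATED region."""
    eligible, reason = assess_eligibility(model)
    if not eligible:
        raise ValueError(f"{model.transcript_id}: ineligible ({reason})")
    c0, _ = model.cds_tx_interval()
    seq = model.spliced_sequence(genome)[c0 : c0 + EARLY_LEN]
    return EarlyRegion(
        transcript_id=model.transcript_id,
        sequence=seq,
        kind="EVALUATED",
        window_offset=0,
        n_exons_straddled=model.tx_window_exons(c0, c0 + EARLY_LEN),
    )


def control_window_offsets(model: TranscriptModel) -> list[int]:
    """All valid in-frame control-window offsets (nt from CDS start).

    Windows start at or after the first coding base downstream of the third
    exon's last base and must fit entirely inside the CDS.
    """
    c0, c1 = model.cds_tx_interval()
    juncs = model.junctions_tx()
    if len(juncs) < 3:
        return []
    j3 = juncs[2]  # transcript position after the last base of exon 3
    min_start = max(c0, j3)
    first_off = min_start - c0
    first_off += (-first_off) % 3  # round up to in-frame
    max_off = (c1 - c0) - EARLY_LEN
    return list(range(first_off, max_off + 1, 3)) if first_off <= max_off else []


def sample_control_window(model: TranscriptModel, genome, rng: np.random.Generator):
    """One uniformly chosen in-frame 99-nt control window, or None.

    Returns None when fewer than 99 coding nt remain downstream of the third
    exon. The caller inherits the evaluated transcript's 5UI label/cluster.
    """
    offsets = control_window_offsets(model)
    if not offsets:
        return None
    off = int(rng.choice(offsets))
    c0, _ = model.cds_tx_interval()
    seq = model.spliced_sequence(genome)[c0 + off : c0 + off + EARLY_LEN]
    return EarlyRegion(
        transcript_id=model.transcript_id,
        sequence=seq,
        kind="CONTROL",
        window_offset=off,
        n_exons_straddled=model.tx_window_exons(c0 + off, c0 + off + EARLY_LEN),
    )


# ---------------------------------------------------------------------------
# Similarity clustering (seeded Smith-Waterman + Karlin-Altschul E-value)

SW_MATCH, SW_MISMATCH = 1.0, -3.0
SW_GAP_OPEN, SW_GAP_EXTEND = -5.0, -2.0
KA_K = 0.711  # tabulated for the +1/-3 nucleotide score system


def _solve_lambda(match: float, mismatch: float, p_match: float = 0.25) -> float:
    """Karlin-Altschul lambda: E[exp(lambda * s)] = 1 under the null."""
    lo, hi = 1e-6, 10.0
    f = lambda lam: p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


KA_LAMBDA = _solve_lambda(SW_MATCH, SW_MISMATCH)


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = SW_MATCH
    a.mismatch_score = SW_MISMATCH
    a.open_gap_score = SW_GAP_OPEN
    a.extend_gap_score = SW_GAP_EXTEND
    return a


def alignment_evalue(score: float, m: int = EARLY_LEN, n: int = EARLY_LEN) -> float:
    """Karlin-Altschul expected number of alignments scoring >= score."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def cluster_early_regions(
    regions: list[EarlyRegion],
    evalue_threshold: float = 1e-25,
    word_size: int = 11,
) -> list[TranscriptCluster]:
    """Single-linkage clusters over local-alignment similarity.

    Candidate pairs must share an exact ``word_size``-mer (blastn-style
    seeding); candidates are Smith-Waterman aligned and linked when the
    Karlin-Altschul E-value of the score is below ``evalue_threshold``.
    The partition is invariant to input order.
    """
    ids = [r.transcript_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript_ids among regions")
    order = sorted(range(len(regions)), key=lambda i: ids[i])
    seqs = [regions[i].sequence for i in order]
    sorted_ids = [ids[i] for i in order]
    n = len(seqs)

    # word -> indices seeding
    index: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        for k in range(EARLY_LEN - word_size + 1):
            w = s[k : k + word_size]
            if "N" in w:
                continue
            index.setdefault(w, []).append(i)
    candidates = set()
    for hits in index.values():
        uniq = sorted(set(hits))
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                candidates.add((uniq[a], uniq[b]))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    aligner = _make_aligner()
    for a, b in sorted(candidates):
        if find(a) == find(b):
            continue
        score = aligner.score(seqs[a], seqs[b])
        if alignment_evalue(score) < evalue_threshold:
            union(a, b)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(sorted_ids[i])
    clusters = []
    for members in groups.values():
        rep = min(members)
        clusters.append(
            TranscriptCluster(cluster_id=f"cluster_{rep}", member_ids=sorted(members),
                              representative_id=rep)
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


# ---------------------------------------------------------------------------
# Tabular output

def regions_to_tsv(regions: list[EarlyRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tkind\twindow_offset\tn_exons_straddled\tsequence\n")
        for r in regions:
            fh.write(
                f"{r.transcript_id}\t{r.kind}\t{r.window_offset}\t"
                f"{r.n_exons_straddled}\t{r.sequence}\n"
            )


def regions_from_tsv(path) -> list[EarlyRegion]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                EarlyRegion(
                    transcript_id=f[cols["transcript_id"]],
                    sequence=f[cols["sequence"]],
                    kind=f[cols["kind"]],
                    window_offset=int(f[cols["window_offset"]]),
                    n_exons_straddled=int(f[cols["n_exons_straddled"]]),
                )
            )
    return out


def clusters_to_tsv(clusters: list[TranscriptCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\ttranscript_id\n")
        for c in clusters:
            for m in c.member_ids:
                fh.write(f"{c.cluster_id}\t{m}\n")


def cluster_map(clusters: list[TranscriptCluster]) -> dict[str, str]:
    return {m: c.cluster_id for c in clusters for m in c.member_ids}
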