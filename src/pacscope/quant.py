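"""Processing of 3'-end sequencing reads into region-class counts.

The pipeline stage mirrors how 3'-end libraries are quantified in practice:

1. poly(A)-tail detection on raw reads (:func:`trim_polya`) — a read must
   carry at least 25 A's at its 3' terminus to be treated as evidence of a
   cleavage site;
2. the 3'-most aligned base of each read defines its candidate poly(A) site
   (:func:`read_three_prime_site`);
3. sites whose downstream genomic 20-mer contains more than 12 A on the
   transcript sense strand are discarded as internal-priming artifacts
   (:func:`internal_priming_filter`);
4. surviving sites are clustered single-linkage within a small gap
   (:func:`cluster_sites`), absorbing cleavage heterogeneity;
5. sites/clusters are counted, sense-stranded, into the four region classes
   (:func:`count_by_feature`), discarding assignments ambiguous between
   genes within one class.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import RegionSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PacRead:
    """One aligned 3'-end read."""

    chrom: str
    strand: str
    start: int  # aligned span, 0-based half-open
    end: int
    a_count: int  # length of the detected poly(A) tail in the raw read
    sample: str

    def __post_init__(self) -> None:
        if self.a_count < 0:
            raise ValueError("a_count must be >= 0")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid aligned span")


@dataclass
class PacSite:
    """A candidate cleavage position (3'-most aligned base) with support."""

    chrom: str
    strand: str
    pos: int
    support: dict[str, int] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class PacCluster:
    """Single-linkage cluster of nearby sites; one countable poly(A) site."""

    chrom: str
    strand: str
    representative: int
    members: list[int]
    count: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.count.values())


@dataclass
class FeatureCounts:
    """gene x region_class x sample count tensor plus library sizes."""

    counts: dict[tuple[str, str], dict[str, int]]  # (gene, class) -> sample -> n
    library_sizes: dict[str, int]
    ambiguous: dict[str, int] = field(default_factory=dict)  # per region class
    unassigned: dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        """Counts as a pandas DataFrame indexed by (gene, region_class)."""
        import pandas as pd

        if not self.counts:
            return pd.DataFrame()
        df = pd.DataFrame.from_dict(self.counts, orient="index").fillna(0).astype(int)
        df.index = pd.MultiIndex.from_tuples(df.index, names=["gene", "region_class"])
        return df.sort_index()


def trim_polya(
    read_seq: str, min_a: int = 25, max_mismatch: int = 2
) -> tuple[str, int, bool]:
    """Detect and strip a 3' poly(A) tail.

    The tail is the longest suffix ending at the read's 3' terminus that
    contains at most ``max_mismatch`` non-A characters, then trimmed on its
    5' side so it starts with an A (a tail cannot open on a mismatch).

    Returns ``(insert, a_count, passes)`` where ``a_count`` is the number of
    A's in the tail and ``passes`` requires ``a_count >= min_a``. Reads whose
    tail consumes the whole read (empty insert) still pass the A-count rule;
    callers discard them before alignment.
    """
    if not read_seq:
        raise ValueError("empty read sequence")
    n = len(read_seq)
    mismatches = 0
    i = n  # tail start index
    while i > 0:
        if read_seq[i - 1] != "A":
            if mismatches == max_mismatch:
                break
            mismatches += 1
        i -= 1
    while i < n and read_seq[i] != "A":
        i += 1
    tail = read_seq[i:]
    a_count = tail.count("A")
    return read_seq[:i], a_count, a_count >= min_a


def read_three_prime_site(read: PacRead) -> PacSite:
    """Site at the 3'-most aligned base: ``end - 1`` on ``+``, ``start`` on ``-``."""
    pos = read.end - 1 if read.strand == "+" else read.start
    return PacSite(read.chrom, read.strand, pos, {read.sample: 1})


def collapse_reads_to_sites(reads: Iterable[PacRead]) -> list[PacSite]:
    """Aggregate per-read 3' ends into unique sites with per-sample support."""
    sites: dict[tuple[str, str, int], PacSite] = {}
    for read in reads:
        pos = read.end - 1 if read.strand == "+" else read.start
        key = (read.chrom, read.strand, pos)
        site = sites.get(key)
        if site is None:
            site = PacSite(read.chrom, read.strand, pos, {})
            sites[key] = site
        site.support[read.sample] = site.support.get(read.sample, 0) + 1
    return sorted(sites.values(), key=lambda s: (s.chrom, s.strand, s.pos))


def internal_priming_filter(
    site: PacSite,
    genome,
    window_nt: int = 20,
    max_a: int = 12,
) -> bool:
    """Keep a site unless its downstream genomic window is A-rich.

    Counts A on the transcript sense strand in the ``window_nt`` bases
    immediately 3' of ``pos``. For ``-`` strand sites this scans the
    reference toward decreasing coordinates, counting T on the ``+`` strand.
    Windows truncated by the chromosome end are scanned as-is.

    ``genome`` is any mapping-style FASTA access (e.g. ``pyfaidx.Fasta``)
    yielding sliceable per-chromosome sequence.
    """
    chrom_seq = genome[site.chrom]
    clen = len(chrom_seq)
    if site.strand == "+":
        lo, hi = site.pos + 1, min(site.pos + 1 + window_nt, clen)
        if hi - lo < window_nt:
            logger.debug("truncated internal-priming window at %s:%d", site.chrom, site.pos)
        window = str(chrom_seq[lo:hi]).upper()
        n_a = window.count("A")
    else:
        lo, hi = max(site.pos - window_nt, 0), site.pos
        if hi - lo < window_nt:
            logger.debug("truncated internal-priming window at %s:%d", site.chrom, site.pos)
        window = str(chrom_seq[lo:hi]).upper()
        n_a = window.count("T")  # sense-strand A
    return n_a <= max_a


def filter_internal_priming(
    sites: Sequence[PacSite],
    genome,
    window_nt: int = 20,
    max_a: int = 12,
) -> list[PacSite]:
    kept = [s for s in sites if internal_priming_filter(s, genome, window_nt, max_a)]
    n_removed = len(sites) - len(kept)
    if n_removed:
        logger.info("internal-priming filter removed %d/%d sites", n_removed, len(sites))
    return kept


def cluster_sites(sites: Sequence[PacSite], max_gap: int = 25) -> list[PacCluster]:
    """Single-linkage clustering of sites on one chrom+strand within
    ``max_gap``; representative = highest-support member position, ties
    broken toward the most distal position in transcription direction."""
    by_key: dict[tuple[str, str], list[PacSite]] = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s)

    clusters: list[PacCluster] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda s: s.pos)
        block: list[PacSite] = []
        for site in group:
            if block and site.pos - block[-1].pos > max_gap:
                clusters.append(_finish_cluster(chrom, strand, block))
                block = []
            block.append(site)
        if block:
            clusters.append(_finish_cluster(chrom, strand, block))
    return clusters


def _finish_cluster(chrom: str, strand: str, block: list[PacSite]) -> PacCluster:
    # distal = larger coordinate on +, smaller on -
    distal_sign = 1 if strand == "+" else -1
    rep = max(block, key=lambda s: (s.total_support, distal_sign * s.pos)).pos
    count: dict[str, int] = {}
    for s in block:
        for sample, n in s.support.items():
            count[sample] = count.get(sample, 0) + n
    return PacCluster(chrom, strand, rep, [s.pos for s in block], count)


class _RegionIndex:
    """Sorted-interval lookup: position -> gene ids, per (chrom, strand)."""

    def __init__(self, rs: RegionSet):
        by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for gid, iv in rs.all_intervals():
            by_key.setdefault((iv.chrom, iv.strand), []).append(
                (iv.start, iv.end, gid)
            )
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._rows: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        self._max_len: dict[tuple[str, str], int] = {}
        for key, rows in by_key.items():
            rows.sort()
            self._rows[key] = rows
            self._starts[key] = [r[0] for r in rows]
            self._max_len[key] = max(r[1] - r[0] for r in rows)

    def genes_at(self, chrom: str, strand: str, pos: int) -> list[str]:
        key = (chrom, strand)
        rows = self._rows.get(key)
        if not rows:
            return []
        starts = self._starts[key]
        hi = bisect_right(starts, pos)
        lo = bisect_right(starts, pos - self._max_len[key])
        return [gid for s, e, gid in rows[max(lo - 1, 0):hi] if s <= pos < e]


def count_by_feature(
    sites_or_clusters: Sequence[PacSite] | Sequence[PacCluster],
    regions: Mapping[str, RegionSet],
    sense_stranded: bool = True,
) -> FeatureCounts:
    """Assign sites/clusters to genes per region class by position.

    Each region class is counted independently (the classes come from
    separate BED quantifications). Within one class a position landing in
    intervals of more than one gene is discarded as ambiguous. Antisense
    hits never count when ``sense_stranded``.
    """
    indexes = {cls: _RegionIndex(rs) for cls, rs in regions.items()}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    library_sizes: dict[str, int] = {}
    ambiguous = {cls: 0 for cls in regions}
    unassigned = {cls: 0 for cls in regions}

    items = list(sites_or_clusters)
    for item in items:
        support = item.count if isinstance(item, PacCluster) else item.support
        pos = item.representative if isinstance(item, PacCluster) else item.pos
        for sample, n in support.items():
            library_sizes[sample] = library_sizes.get(sample, 0) + n
        for cls, index in indexes.items():
            if sense_stranded:
                gids = index.genes_at(item.chrom, item.strand, pos)
            else:
                gids = index.genes_at(item.chrom, "+", pos) + index.genes_at(
                    item.chrom, "-", pos
                )
            if len(gids) == 1:
                bucket = counts.setdefault((gids[0], cls), {})
                for sample, n in support.items():
                    bucket[sample] = bucket.get(sample, 0) + n
            elif len(gids) > 1:
                ambiguous[cls] += 1
            else:
                unassigned[cls] += 1

    for cls, n in ambiguous.items():
        if n:
            logger.info("%d ambiguous assignments discarded in %s", n, cls)
    return FeatureCounts(counts, library_sizes, ambiguous, unassigned)


def scan_pas_hexamer(seq: str, motifs: Iterable[str] = ("AATAAA",)) -> list[int]:
    """All 0-based start positions of exact motif matches; overlaps allowed."""
    seq = seq.upper()
    hits: list[int] = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append(start)
            start = seq.find(motif, start + 1)
    return sorted(set(hits))


def read_three_prime_bed(path, sample: str | None = None) -> list[PacSite]:
    """Read a 3'-end BED (chrom, pos, pos+1, sample, support, strand) into
    sites. If ``sample`` is given it overrides the name column."""
    sites: dict[tuple[str, str, int], PacSite] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            smp = sample or name
            key = (chrom, strand, int(start))
            site = sites.get(key)
            if site is None:
                site = PacSite(chrom, strand, int(start), {})
                sites[key] = site
            site.support[smp] = site.support.get(smp, 0) + int(score)
    return sorted(sites.values(), key=lambda s: (s.chrom, s.strand, s.pos))


def read_sites_from_sam(path, sample: str, min_a: int = 25) -> list[PacSite]:
    """Collapse aligned single-end reads in a SAM/BAM into 3'-end sites.

    The poly(A) length is taken from the ``ZA`` integer tag when present
    (written by the simulator and by tail-trimming preprocessors); reads
    lacking the tag are assumed pre-filtered. Soft-clipped bases are
    ignored: the aligned span defines the 3'-most base.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            a_count = aln.get_tag("ZA") if aln.has_tag("ZA") else min_a
            if a_count < min_a:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(
                PacRead(
                    aln.reference_name,
                    strand,
                    aln.reference_start,
                    aln.reference_end,
                    a_count,
                    sample,
                )
            )
    return collapse_reads_to_sites(reads)
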