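"""Gene annotation loading and construction of the four region classes.

The genome is partitioned, per gene, into four stranded interval classes:

``utr3``
    The union of annotated 3' UTR features across a gene's transcripts, each
    feature extended a fixed distance (default 300 nt) in the direction of
    transcription to capture cleavage sites just past the annotated UTR end.
``cds``
    The union of annotated coding-sequence features.
``intron``
    The gene span minus the gene's CDS and extended 3' UTR intervals. By
    construction 5' UTR exonic bases fall in this class.
``downstream10k``
    A fixed window (default 10 kb) starting at the gene's strand-aware 3'
    end, minus all same-strand exons and all extended 3' UTRs of any gene
    (own or neighboring), capturing intergenic poly(A) sites downstream of
    the annotated transcription unit.

Coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted on load. Chromosome lengths for clipping come from a FASTA index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .intervals import Interval, merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

REGION_CLASSES = ("utr3", "cds", "intron", "downstream10k")

DEFAULT_BIOTYPES = frozenset({"protein_coding"})
DEFAULT_EXCLUDED_TAGS = frozenset({"retained_intron"})


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass
class Gene:
    gene_id: str
    span: Interval
    biotype: str


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    tags: frozenset[str]
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    """Filtered genes and transcripts in a unified coordinate model."""

    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


@dataclass
class RegionSet:
    """Per-gene disjoint, sorted intervals of one region class."""

    region_class: str
    regions: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    def all_intervals(self) -> Iterable[tuple[str, Interval]]:
        for gid, ivs in self.regions.items():
            for iv in ivs:
                yield gid, iv


def _parse_attributes(attr_field: str) -> dict[str, list[str]]:
    """Parse GTF attribute column; repeated keys (e.g. ``tag``) accumulate."""
    attrs: dict[str, list[str]] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs.setdefault(key, []).append(value.strip().strip('"'))
    return attrs


def load_annotation(
    gtf_path: str | Path,
    biotypes: Iterable[str] = DEFAULT_BIOTYPES,
    excluded_tags: Iterable[str] = DEFAULT_EXCLUDED_TAGS,
) -> GenomeAnnotation:
    """Load an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Only genes whose biotype is in ``biotypes`` are kept; transcripts
    carrying any tag in ``excluded_tags`` (default ``retained_intron``) are
    dropped. 1-based inclusive GTF coordinates become 0-based half-open.
    """
    biotypes = set(biotypes)
    excluded_tags = set(excluded_tags)
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    feature_rows: list[tuple[str, str, Interval]] = []  # (feature, tx_id, iv)

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: bad strand {strand!r}"
                )
            attrs = _parse_attributes(attr)
            try:
                iv = Interval(chrom, start, end, strand)
            except ValueError as exc:
                raise GtfParseError(f"{gtf_path}: line {lineno}: {exc}") from exc

            if feature == "gene":
                gid = _single(attrs, "gene_id", gtf_path, lineno)
                biotype = _first(attrs, ("gene_biotype", "gene_type"), "")
                genes[gid] = Gene(gid, iv, biotype)
            elif feature == "transcript":
                tid = _single(attrs, "transcript_id", gtf_path, lineno)
                gid = _single(attrs, "gene_id", gtf_path, lineno)
                tags = frozenset(attrs.get("tag", []))
                # Ensembl also flags retained_intron as transcript_biotype
                tbio = _first(attrs, ("transcript_biotype", "transcript_type"), "")
                if tbio:
                    tags = tags | {tbio}
                transcripts[tid] = Transcript(tid, gid, tags)
            elif feature in ("exon", "CDS", "three_prime_utr"):
                tid = _single(attrs, "transcript_id", gtf_path, lineno)
                feature_rows.append((feature, tid, iv))

    for feature, tid, iv in feature_rows:
        tx = transcripts.get(tid)
        if tx is None:
            raise GtfParseError(
                f"{gtf_path}: feature references unknown transcript {tid!r}"
            )
        if feature == "exon":
            tx.exons.append(iv)
        elif feature == "CDS":
            tx.cds.append(iv)
        else:
            tx.utr3.append(iv)

    for tx in transcripts.values():
        if tx.gene_id not in genes:
            raise GtfParseError(
                f"{gtf_path}: transcript {tx.transcript_id} references "
                f"unknown gene {tx.gene_id!r}"
            )

    keep_genes = {g.gene_id for g in genes.values() if g.biotype in biotypes}
    kept_tx = {
        tid: tx
        for tid, tx in transcripts.items()
        if tx.gene_id in keep_genes and not (tx.tags & excluded_tags)
    }
    kept_genes = {gid: g for gid, g in genes.items() if gid in keep_genes}
    n_drop = len(transcripts) - len(kept_tx)
    if n_drop:
        logger.info("dropped %d transcripts by biotype/tag filters", n_drop)
    return GenomeAnnotation(kept_genes, kept_tx)


def _single(attrs: Mapping[str, list[str]], key: str, path, lineno: int) -> str:
    vals = attrs.get(key)
    if not vals:
        raise GtfParseError(f"{path}: line {lineno}: missing attribute {key!r}")
    return vals[0]


def _first(attrs: Mapping[str, list[str]], keys: Iterable[str], default: str) -> str:
    for key in keys:
        if key in attrs:
            return attrs[key][0]
    return default


def _extend_3prime(iv: Interval, extension_nt: int, chrom_len: int | None) -> Interval:
    """Extend an interval in the transcription direction, clipped to bounds."""
    if iv.strand == "+":
        end = iv.end + extension_nt
        if chrom_len is not None and end > chrom_len:
            logger.debug("clipping extension past end of %s", iv.chrom)
            end = chrom_len
        return Interval(iv.chrom, iv.start, end, iv.strand)
    start = iv.start - extension_nt
    if start < 0:
        logger.debug("clipping extension past start of %s", iv.chrom)
        start = 0
    return Interval(iv.chrom, start, iv.end, iv.strand)


def build_utr3_regions(
    ann: GenomeAnnotation,
    extension_nt: int = 300,
    chrom_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Per gene, union of 3' UTR features each extended ``extension_nt`` nt
    in the 3' direction. Genes without annotated 3' UTRs are absent."""
    regions: dict[str, list[Interval]] = {}
    for tx in ann.transcripts.values():
        if not tx.utr3:
            continue
        clen = chrom_lengths.get(tx.utr3[0].chrom) if chrom_lengths else None
        extended = [_extend_3prime(iv, extension_nt, clen) for iv in tx.utr3]
        regions.setdefault(tx.gene_id, []).extend(extended)
    return RegionSet("utr3", {g: merge_intervals(ivs) for g, ivs in regions.items()})


def build_cds_regions(ann: GenomeAnnotation) -> RegionSet:
    """Per gene, merged union of CDS features across transcripts."""
    regions: dict[str, list[Interval]] = {}
    for tx in ann.transcripts.values():
        if tx.cds:
            regions.setdefault(tx.gene_id, []).extend(tx.cds)
    return RegionSet("cds", {g: merge_intervals(ivs) for g, ivs in regions.items()})


def build_intron_regions(ann: GenomeAnnotation, utr3: RegionSet) -> RegionSet:
    """Per gene: gene span minus merged CDS minus the gene's extended 3' UTR.

    5' UTR exon bases remain in this class by construction.
    """
    cds = build_cds_regions(ann)
    regions: dict[str, list[Interval]] = {}
    for gid, gene in ann.genes.items():
        remaining = [gene.span]
        for sub in (cds.regions.get(gid, []), utr3.regions.get(gid, [])):
            clipped = _clip_to(sub, gene.span)
            if clipped:
                remaining = subtract_intervals(remaining, merge_intervals(clipped))
            if not remaining:
                break
        if remaining:
            regions[gid] = remaining
    return RegionSet("intron", regions)


def _clip_to(intervals: Iterable[Interval], bound: Interval) -> list[Interval]:
    out = []
    for iv in intervals:
        s, e = max(iv.start, bound.start), min(iv.end, bound.end)
        if s < e:
            out.append(Interval(iv.chrom, s, e, iv.strand))
    return out


def build_downstream_regions(
    ann: GenomeAnnotation,
    utr3: RegionSet,
    window_nt: int = 10000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Per gene, a ``window_nt`` window appended to the gene's strand-aware
    3' end, minus all same-strand exons and all extended 3' UTRs of any
    gene, clipped to chromosome bounds."""
    # index same-strand exons and extended UTRs by (chrom, strand)
    blockers: dict[tuple[str, str], list[Interval]] = {}
    for tx in ann.transcripts.values():
        for iv in tx.exons:
            blockers.setdefault((iv.chrom, iv.strand), []).append(iv)
    for _gid, iv in utr3.all_intervals():
        blockers.setdefault((iv.chrom, iv.strand), []).append(iv)
    merged_blockers = {key: merge_intervals(ivs) for key, ivs in blockers.items()}

    regions: dict[str, list[Interval]] = {}
    for gid, gene in ann.genes.items():
        span = gene.span
        clen = chrom_lengths.get(span.chrom) if chrom_lengths else None
        if span.strand == "+":
            start, end = span.end, span.end + window_nt
            if clen is not None and end > clen:
                logger.debug("clipping downstream window of %s", gid)
                end = clen
        else:
            start, end = span.start - window_nt, span.start
            if start < 0:
                logger.debug("clipping downstream window of %s", gid)
                start = 0
        if start >= end:
            continue
        window = [Interval(span.chrom, start, end, span.strand)]
        blocks = merged_blockers.get((span.chrom, span.strand), [])
        overlapping = [b for b in blocks if b.start < end and b.end > start]
        if overlapping:
            clipped = _clip_to(overlapping, window[0])
            if clipped:
                window = subtract_intervals(window, clipped)
        if window:
            regions[gid] = window
    return RegionSet("downstream10k", regions)


def build_all_regions(
    ann: GenomeAnnotation,
    extension_nt: int = 300,
    window_nt: int = 10000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, RegionSet]:
    """Build the four region classes with the standard dependency order."""
    utr3 = build_utr3_regions(ann, extension_nt, chrom_lengths)
    return {
        "utr3": utr3,
        "cds": build_cds_regions(ann),
        "intron": build_intron_regions(ann, utr3),
        "downstream10k": build_downstream_regions(
            ann, utr3, window_nt, chrom_lengths
        ),
    }


def write_regions_bed(rs: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED6: name = ``gene_id|region_class``."""
    rows = [
        (iv.chrom, iv.start, iv.end, f"{gid}|{rs.region_class}", 0, iv.strand)
        for gid, iv in rs.all_intervals()
    ]
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write(f"# pacscope regions: {rs.region_class}\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_regions_bed(path: str | Path) -> RegionSet:
    """Read a BED6 written by :func:`write_regions_bed` (lossless round-trip)."""
    regions: dict[str, list[Interval]] = {}
    region_class = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "pacscope regions:" in line:
                    region_class = line.rsplit(":", 1)[1].strip()
                continue
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            gid, _, rcls = name.rpartition("|")
            if region_class is None:
                region_class = rcls
            elif rcls != region_class:
                raise ValueError(f"{path}: mixed region classes in one BED")
            regions.setdefault(gid, []).append(
                Interval(chrom, int(start), int(end), strand)
            )
    if region_class is None:
        raise ValueError(f"{path}: empty region BED with no class annotation")
    for gid in regions:
        regions[gid].sort(key=lambda iv: iv.start)
    return RegionSet(region_class, regions)


def chrom_lengths_from_fasta(fasta_path: str | Path) -> dict[str, int]:
    """Chromosome lengths via the FASTA index (built if absent)."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path)) as fa:
        return {name: len(fa[name]) for name in fa.keys()}
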