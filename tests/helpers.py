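"""Independent brute-force oracles used by the test suite.

These reimplement the textual rules directly (per-base boolean masks,
per-read linear scans, literal step-up enumeration), never calling the
code paths they check.
"""

from __future__ import annotations

import numpy as np

from pacscope.annotation import GenomeAnnotation


def gene_bounds(ann: GenomeAnnotation, chrom_len: int, extension_nt: int, window_nt: int):
    """Per-gene window [lo, hi) wide enough to hold all four region classes."""
    pad = window_nt + extension_nt
    out = {}
    for gid, gene in ann.genes.items():
        out[gid] = (max(gene.span.start - pad, 0), min(gene.span.end + pad, chrom_len))
    return out


def perbase_region_masks(
    ann: GenomeAnnotation,
    chrom_len: int,
    extension_nt: int = 300,
    window_nt: int = 10000,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-gene base masks (over the gene's local window) for the four
    region classes, applying the textual rules base by base.

    Returns ``{region_class: {gene_id: bool mask}}``; masks are indexed
    relative to :func:`gene_bounds`. Single-chromosome annotations only.
    """
    bounds = gene_bounds(ann, chrom_len, extension_nt, window_nt)

    # global same-strand exon and extended-3'UTR masks over the chromosome
    exon_mask = {"+": np.zeros(chrom_len, bool), "-": np.zeros(chrom_len, bool)}
    utr3_ext_global = {"+": np.zeros(chrom_len, bool), "-": np.zeros(chrom_len, bool)}

    def ext(iv):
        if iv.strand == "+":
            return iv.start, min(iv.end + extension_nt, chrom_len)
        return max(iv.start - extension_nt, 0), iv.end

    for tx in ann.transcripts.values():
        for iv in tx.exons:
            exon_mask[iv.strand][iv.start : iv.end] = True
        for iv in tx.utr3:
            s, e = ext(iv)
            utr3_ext_global[iv.strand][s:e] = True

    utr3, cds, intron, down = {}, {}, {}, {}
    for gid, gene in ann.genes.items():
        lo, hi = bounds[gid]
        n = hi - lo
        strand = gene.span.strand
        u = np.zeros(n, bool)
        c = np.zeros(n, bool)
        for tx in ann.transcripts_of(gid):
            for iv in tx.utr3:
                s, e = ext(iv)
                u[s - lo : e - lo] = True
            for iv in tx.cds:
                c[iv.start - lo : iv.end - lo] = True
        span = np.zeros(n, bool)
        span[gene.span.start - lo : gene.span.end - lo] = True
        if u.any():
            utr3[gid] = u
        if c.any():
            cds[gid] = c
        intr = span & ~c & ~u
        if intr.any():
            intron[gid] = intr
        if strand == "+":
            ws, we = gene.span.end, min(gene.span.end + window_nt, chrom_len)
        else:
            ws, we = max(gene.span.start - window_nt, 0), gene.span.start
        w = np.zeros(n, bool)
        w[ws - lo : we - lo] = True
        w &= ~exon_mask[strand][lo:hi] & ~utr3_ext_global[strand][lo:hi]
        if w.any():
            down[gid] = w
    return {"utr3": utr3, "cds": cds, "intron": intron, "downstream10k": down}


def regionset_masks(rs, bounds) -> dict[str, np.ndarray]:
    """Convert a RegionSet into per-gene local-window boolean masks."""
    out = {}
    for gid, ivs in rs.regions.items():
        lo, hi = bounds[gid]
        m = np.zeros(hi - lo, bool)
        for iv in ivs:
            m[iv.start - lo : iv.end - lo] = True
        out[gid] = m
    return out


def naive_feature_counts(sites, regions):
    """Per-site linear scan over every interval of every region class,
    applying the strand-match and single-gene rules literally.

    Returns ``{(gene, region_class): {sample: count}}`` mirroring
    FeatureCounts.counts.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for site in sites:
        for cls, rs in regions.items():
            hits = []
            for gid, ivs in rs.regions.items():
                for iv in ivs:
                    if (
                        iv.chrom == site.chrom
                        and iv.strand == site.strand
                        and iv.start <= site.pos < iv.end
                    ):
                        hits.append(gid)
                        break
            if len(hits) == 1:
                bucket = counts.setdefault((hits[0], cls), {})
                for sample, n in site.support.items():
                    bucket[sample] = bucket.get(sample, 0) + n
    return counts


def brute_force_bh(p):
    """Step-up rule applied literally: the adjusted value of the i-th
    smallest p is the running minimum of p_(j) * m / j over j >= i."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return adj


def random_toy_gtf(rng: np.random.Generator, n_genes: int = 12) -> tuple[str, int]:
    """A randomized single-chromosome GTF with varying gene geometry,
    strands and occasional close same/opposite-strand neighbors.

    Returns (gtf text, chromosome length).
    """
    lines = []
    pos = int(rng.integers(200, 800))
    for i in range(n_genes):
        gid = f"RT{i:03d}"
        tid = gid + ".t1"
        strand = "+" if rng.random() < 0.5 else "-"
        exon1 = int(rng.integers(150, 600))
        intron = int(rng.integers(100, 1500))
        cds2 = int(rng.integers(90, 400))
        utr3 = int(rng.integers(100, 900))
        glen = exon1 + intron + cds2 + utr3
        gstart, gend = pos, pos + glen
        gattr = f'gene_id "{gid}"; gene_biotype "protein_coding";'
        tattr = f'gene_id "{gid}"; transcript_id "{tid}";'

        def row(feat, s, e):
            return f"chr1\ttoy\t{feat}\t{s + 1}\t{e}\t.\t{strand}\t.\t{tattr}"

        lines.append(f"chr1\ttoy\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t{gattr}")
        lines.append(row("transcript", gstart, gend))
        if strand == "+":
            e1 = (gstart, gstart + exon1)
            e2 = (gstart + exon1 + intron, gend)
            c2 = (e2[0], e2[0] + cds2)
            u3 = (c2[1], gend)
        else:
            e1 = (gend - exon1, gend)
            e2 = (gstart, gstart + utr3 + cds2)
            c2 = (gstart + utr3, e2[1])
            u3 = (gstart, gstart + utr3)
        for s, e in (e1, e2):
            lines.append(row("exon", s, e))
        for s, e in (e1, c2):
            lines.append(row("CDS", s, e))
        lines.append(row("three_prime_utr", u3[0], u3[1]))
        # sometimes the next gene sits close enough to intrude on the
        # 10 kb downstream window of this one
        gap = int(rng.integers(200, 4000)) if rng.random() < 0.5 else int(
            rng.integers(11000, 14000)
        )
        pos = gend + gap
    return "\n".join(lines) + "\n", pos + 12000
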