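"""Self-contained synthetic data with known ground truth.

The generator emulates the structure of a knockdown 3'-end-sequencing study:
three cell-line contrasts, each with 3 replicates of a control shRNA and
3 replicates each of two knockdown shRNAs, stranded single-end 3'-end reads
carrying poly(A) tails, and paired gene-level RNA-seq counts whose
expression effects are coupled to the poly(A)-site usage shifts.

Each synthetic gene has an annotated 3' UTR poly(A) site and an intergenic
site ~2 kb past the gene end (a subset also gets an intronic site). A
canonical AATAAA hexamer is planted ~21 nt upstream of every true site.
"Intended QI" genes shift usage from the 3' UTR site to the downstream site
upon knockdown and lose expression; all other genes are null. Internal-
priming decoy positions with >12 A in the downstream genomic 20-mer are
planted away from true sites, and decoy reads are emitted at a configured
rate — they carry genuine-looking >=25-A tails, so only the genomic filter
can remove them.

Every 20-nt window of the background sequence (outside decoy masks) is
forced to contain at most 12 A and at most 12 T, so true sites can never
trip the internal-priming filter, on either strand, even after cleavage
jitter. All randomness flows from labeled substreams of one master seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import CountMatrix
from .integrate import GeneSet
from .quant import PacSite

CHROM = "chrS1"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Labeled RNG substream: regenerating one artifact leaves others alone."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(label.encode())])


@dataclass
class SimulationConfig:
    """The stated world of the simulation; defaults mirror the emulated
    study design (3 replicates x (control + 2 knockdown shRNAs) per cell
    line, 3 cell lines)."""

    seed: int = 0
    n_genes: int = 120
    contrasts: tuple[str, ...] = ("lineA", "lineB", "lineC")
    n_replicates: int = 3
    # gene geometry (nt)
    margin: int = 500
    utr3_len: int = 500
    cds2_len: int = 300
    intron_len: int = 800
    exon1_len: int = 400
    downstream_window: int = 10000
    downstream_site_offset: int = 2000
    decoy_offset: int = 6000
    # fractions of genes by intended behavior
    qi_fraction: float = 0.3
    intron_site_fraction: float = 0.25
    # usage fractions (see _gene_pi)
    qi_utr3_control: float = 0.8
    qi_utr3_kd: float = 0.2
    # expression effects (log2)
    qi_expression_lfc: float = -1.0
    # sequencing
    pac_depth: float = 1000.0  # mean 3'-end reads per gene per sample
    pac_dispersion: float = 0.05
    rnaseq_mean: float = 500.0
    rnaseq_dispersion: float = 0.04  # BCV 0.2, typical for cell-line replicates
    jitter_sd: float = 3.0
    jitter_max: int = 10
    decoy_rate: float = 0.05  # decoy reads per gene, relative to depth
    tail_min_a: int = 25
    tail_extra_mean: float = 10.0  # Poisson excess over the minimum
    read_insert_len: int = 50
    # decay assay
    decay_times: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    decay_t0: float = 6.0
    decay_ct_noise_sd: float = 0.1
    curve_slope: float = -3.321928094887362  # perfect doubling per cycle
    curve_intercept: float = 20.0
    # cohort
    cohort_samples: int = 500
    cohort_rho: float = 0.6
    cohort_background_genes: int = 100

    @property
    def gene_len(self) -> int:
        return self.exon1_len + self.intron_len + self.cds2_len + self.utr3_len

    @property
    def slot_len(self) -> int:
        return 2 * self.margin + self.gene_len + self.downstream_window

    @property
    def chrom_len(self) -> int:
        return self.n_genes * self.slot_len + self.margin

    def conditions(self) -> dict[str, str]:
        """sample -> condition map for one contrast (ctrl vs pooled kd)."""
        design: dict[str, str] = {}
        for shrna, cond in (("ctrl", "control"), ("kd1", "knockdown"), ("kd2", "knockdown")):
            for rep in range(1, self.n_replicates + 1):
                design[f"{shrna}_rep{rep}"] = cond
        return design


@dataclass
class SiteTruth:
    site_class: str  # utr3 | intron | downstream10k
    pos: int  # 0-based cleavage position (3'-most base)
    hexamer_start: int


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    start: int
    end: int
    intended_qi: bool
    sites: list[SiteTruth]
    decoy_pos: int
    pi_control: dict[str, float]
    pi_knockdown: dict[str, float]
    expression_lfc: float
    decay_k: float = float("nan")

    def expected_pac_score(self, region: str) -> float:
        """log2(pi_kd,region/pi_ctrl,region) - log2(pi_kd,utr3/pi_ctrl,utr3);
        depends only on usage fractions, never on expression."""
        if region not in self.pi_control or "utr3" not in self.pi_control:
            return float("nan")
        return float(
            np.log2(self.pi_knockdown[region] / self.pi_control[region])
            - np.log2(self.pi_knockdown["utr3"] / self.pi_control["utr3"])
        )

    @property
    def intended_quadrant(self) -> str:
        score = self.expected_pac_score("downstream10k")
        if np.isnan(score) or score == 0 or self.expression_lfc == 0:
            return "unclassified"
        if self.expression_lfc < 0:
            return "QI" if score > 0 else "QIV"
        return "QII" if score > 0 else "QIII"


@dataclass
class TruthManifest:
    config: SimulationConfig
    genes: list[GeneTruth]

    def qi_genes(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.genes if g.intended_qi)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "strand": g.strand,
                    "start": g.start,
                    "end": g.end,
                    "intended_qi": g.intended_qi,
                    "expression_lfc": g.expression_lfc,
                    "expected_pac_score_ds": g.expected_pac_score("downstream10k"),
                    "intended_quadrant": g.intended_quadrant,
                    "decay_k": g.decay_k,
                }
            )
        return pd.DataFrame(rows).set_index("gene_id")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "genes": [asdict(g) for g in self.genes],
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _gene_pi(cfg: SimulationConfig, qi: bool, has_intron_site: bool) -> tuple[dict, dict]:
    """Per-condition usage fractions over a gene's sites (sum to 1)."""
    pi_intron = 0.1 if has_intron_site else 0.0
    # split the non-intron mass in the configured utr3:downstream proportions
    ctrl = {
        "utr3": cfg.qi_utr3_control * (1 - pi_intron),
        "downstream10k": (1 - cfg.qi_utr3_control) * (1 - pi_intron),
    }
    if has_intron_site:
        ctrl["intron"] = pi_intron
    if qi:
        kd = {
            "utr3": cfg.qi_utr3_kd * (1 - pi_intron),
            "downstream10k": (1 - cfg.qi_utr3_kd) * (1 - pi_intron),
        }
        if has_intron_site:
            kd["intron"] = pi_intron
    else:
        kd = dict(ctrl)
    return ctrl, kd


def _enforce_bounded_runs(
    seq: np.ndarray, protect: np.ndarray, rng: np.random.Generator,
    window: int = 20, max_count: int = 12,
) -> None:
    """Cap A and T counts in every ``window``-mer at ``max_count``,
    flipping unprotected offenders to C/G in place."""
    for base_code, repl in ((0, 1), (3, 2)):  # A->C, T->G
        for _ in range(50):
            is_b = (seq == base_code).astype(np.int32)
            csum = np.concatenate([[0], np.cumsum(is_b)])
            counts = csum[window:] - csum[:-window]
            bad_starts = np.flatnonzero(counts > max_count)
            if bad_starts.size == 0:
                break
            # patch one offender per bad window (leftmost unprotected)
            patched = set()
            for s in bad_starts:
                for off in rng.permutation(window):
                    j = s + off
                    if seq[j] == base_code and not protect[j] and j not in patched:
                        seq[j] = repl
                        patched.add(j)
                        break


def simulate_annotation(cfg: SimulationConfig):
    """Generate (genome sequence dict, GTF text, truth manifest).

    Genes alternate strands and occupy non-overlapping slots wide enough
    that downstream windows never touch a neighboring gene.
    """
    rng = rng_for(cfg.seed, "annotation")
    seq = rng.choice(4, size=cfg.chrom_len, p=[0.22, 0.28, 0.28, 0.22]).astype(np.uint8)
    protect = np.zeros(cfg.chrom_len, dtype=bool)

    n_qi = int(round(cfg.qi_fraction * cfg.n_genes))
    qi_flags = np.zeros(cfg.n_genes, dtype=bool)
    qi_flags[rng.choice(cfg.n_genes, size=n_qi, replace=False)] = True
    intron_flags = rng.random(cfg.n_genes) < cfg.intron_site_fraction

    hex_codes = np.array([0, 0, 3, 0, 0, 0], dtype=np.uint8)  # AATAAA
    hex_rc = np.array([3, 3, 3, 0, 3, 3], dtype=np.uint8)  # TTTATT

    genes: list[GeneTruth] = []
    for i in range(cfg.n_genes):
        gid = f"SYNG{i:04d}"
        slot = i * cfg.slot_len
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            gstart = slot + cfg.margin
            gend = gstart + cfg.gene_len
            utr3_site = gend - 50 - 1
            intron_mid = gstart + cfg.exon1_len + cfg.intron_len // 2
            ds_site = gend + cfg.downstream_site_offset
            decoy = gend + cfg.decoy_offset
        else:
            gstart = slot + cfg.margin + cfg.downstream_window
            gend = gstart + cfg.gene_len
            utr3_site = gstart + 50  # utr3 occupies the low-coordinate end
            intron_mid = gend - cfg.exon1_len - cfg.intron_len // 2
            ds_site = gstart - cfg.downstream_site_offset
            decoy = gstart - cfg.decoy_offset

        sites = [SiteTruth("utr3", utr3_site, -1), SiteTruth("downstream10k", ds_site, -1)]
        if intron_flags[i]:
            sites.append(SiteTruth("intron", intron_mid, -1))

        for st in sites:
            if strand == "+":
                hs = st.pos - 26
                seq[hs : hs + 6] = hex_codes
            else:
                hs = st.pos + 21
                seq[hs : hs + 6] = hex_rc
            protect[hs : hs + 6] = True
            st.hexamer_start = hs

        pi_c, pi_k = _gene_pi(cfg, bool(qi_flags[i]), bool(intron_flags[i]))
        genes.append(
            GeneTruth(
                gene_id=gid,
                strand=strand,
                start=gstart,
                end=gend,
                intended_qi=bool(qi_flags[i]),
                sites=sites,
                decoy_pos=decoy,
                pi_control=pi_c,
                pi_knockdown=pi_k,
                expression_lfc=cfg.qi_expression_lfc if qi_flags[i] else 0.0,
            )
        )

    _enforce_bounded_runs(seq, protect, rng)

    # decoy windows planted last: 14 sense-strand As in the 20-mer downstream
    decoy_window = np.array([0] * 14 + [1, 2, 1, 2, 1, 2], dtype=np.uint8)
    for g in genes:
        w = rng.permutation(decoy_window)
        if g.strand == "+":
            lo = g.decoy_pos + 1
            seq[lo : lo + 20] = w
        else:
            lo = g.decoy_pos - 20
            seq[lo : lo + 20] = 3 - w[::-1]  # complement, reversed

    genome = {CHROM: _BASES[seq].tobytes().decode("ascii")}
    gtf = _annotation_gtf(cfg, genes)
    return genome, gtf, TruthManifest(cfg, genes)


def _annotation_gtf(cfg: SimulationConfig, genes: Sequence[GeneTruth]) -> str:
    """Ensembl-dialect GTF for the synthetic genes (1-based inclusive)."""
    lines = ["#!pacscope synthetic annotation"]

    def row(feature, start, end, strand, attrs):
        return "\t".join(
            [CHROM, "pacscope_sim", feature, str(start + 1), str(end), ".", strand, ".", attrs]
        )

    for g in genes:
        gattr = f'gene_id "{g.gene_id}"; gene_biotype "protein_coding";'
        tid = g.gene_id + ".t1"
        tattr = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; transcript_biotype "protein_coding";'
        lines.append(row("gene", g.start, g.end, g.strand, gattr))
        lines.append(row("transcript", g.start, g.end, g.strand, tattr))
        if g.strand == "+":
            exon1 = (g.start, g.start + cfg.exon1_len)
            exon2 = (g.start + cfg.exon1_len + cfg.intron_len, g.end)
            cds2 = (exon2[0], exon2[0] + cfg.cds2_len)
            utr3 = (cds2[1], g.end)
            cds1 = exon1
        else:
            exon1 = (g.end - cfg.exon1_len, g.end)
            exon2 = (g.start, g.start + cfg.utr3_len + cfg.cds2_len)
            cds2 = (g.start + cfg.utr3_len, exon2[1])
            utr3 = (g.start, g.start + cfg.utr3_len)
            cds1 = exon1
        for s, e in (exon1, exon2):
            lines.append(row("exon", s, e, g.strand, tattr))
        for s, e in (cds1, cds2):
            lines.append(row("CDS", s, e, g.strand, tattr))
        lines.append(row("three_prime_utr", utr3[0], utr3[1], g.strand, tattr))
    return "\n".join(lines) + "\n"


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 3'-end read simulation


def _truncated_jitter(rng, n: int, sd: float, jmax: int) -> np.ndarray:
    j = np.rint(rng.normal(0.0, sd, size=n)).astype(np.int64)
    return np.clip(j, -jmax, jmax)


def simulate_pac_reads(
    cfg: SimulationConfig,
    truth: TruthManifest,
    contrast: str,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-sample 3'-end read positions for one contrast.

    Returns ``{sample: {"pos", "strand", "is_decoy"}}`` arrays. Gene totals
    are NB-distributed around the configured depth (scaled by the gene's
    expression fold change in knockdown samples), sites drawn multinomially
    from the per-condition usage fractions, cleavage positions jittered by
    a truncated Gaussian. Decoy (internal-priming) reads are emitted at the
    configured per-gene rate at the planted decoy positions.
    """
    rng = rng_for(cfg.seed, f"pac:{contrast}")
    design = cfg.conditions()
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample, condition in design.items():
        pos_parts: list[np.ndarray] = []
        strand_parts: list[np.ndarray] = []
        decoy_parts: list[np.ndarray] = []
        for g in truth.genes:
            kd = condition == "knockdown"
            mean = cfg.pac_depth * (2.0 ** g.expression_lfc if kd else 1.0)
            n_total = _nb_draw(rng, mean, cfg.pac_dispersion)
            pi = g.pi_knockdown if kd else g.pi_control
            classes = [s.site_class for s in g.sites]
            probs = np.array([pi[c] for c in classes])
            probs = probs / probs.sum()
            counts = rng.multinomial(n_total, probs)
            for st, n in zip(g.sites, counts):
                if n == 0:
                    continue
                jit = _truncated_jitter(rng, n, cfg.jitter_sd, cfg.jitter_max)
                pos_parts.append(st.pos + jit)
                strand_parts.append(np.full(n, 0 if g.strand == "+" else 1, dtype=np.int8))
                decoy_parts.append(np.zeros(n, dtype=bool))
            n_decoy = rng.poisson(cfg.pac_depth * cfg.decoy_rate)
            if n_decoy:
                pos_parts.append(np.full(n_decoy, g.decoy_pos, dtype=np.int64))
                strand_parts.append(np.full(n_decoy, 0 if g.strand == "+" else 1, dtype=np.int8))
                decoy_parts.append(np.ones(n_decoy, dtype=bool))
        out[sample] = {
            "pos": np.concatenate(pos_parts),
            "strand": np.concatenate(strand_parts),
            "is_decoy": np.concatenate(decoy_parts),
        }
    return out


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """One NB(mean, dispersion) draw; dispersion 0 degenerates to Poisson."""
    if dispersion <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def reads_to_sites(reads: Mapping[str, Mapping[str, np.ndarray]]) -> list[PacSite]:
    """Collapse per-sample read position arrays into PacSites with support."""
    sites: dict[tuple[str, int], PacSite] = {}
    for sample, arrs in reads.items():
        for strand_code in (0, 1):
            strand = "+" if strand_code == 0 else "-"
            mask = arrs["strand"] == strand_code
            pos, counts = np.unique(arrs["pos"][mask], return_counts=True)
            for p, n in zip(pos, counts):
                key = (strand, int(p))
                site = sites.get(key)
                if site is None:
                    site = PacSite(CHROM, strand, int(p), {})
                    sites[key] = site
                site.support[sample] = site.support.get(sample, 0) + int(n)
    return sorted(sites.values(), key=lambda s: (s.strand, s.pos))


def write_reads_bed(reads: Mapping[str, Mapping[str, np.ndarray]], path: str | Path) -> None:
    """3'-end BED: one line per unique (sample, pos, strand), score = support."""
    with open(path, "w") as fh:
        for sample in sorted(reads):
            arrs = reads[sample]
            for strand_code, strand in ((0, "+"), (1, "-")):
                mask = arrs["strand"] == strand_code
                pos, counts = np.unique(arrs["pos"][mask], return_counts=True)
                for p, n in zip(pos, counts):
                    fh.write(f"{CHROM}\t{p}\t{p + 1}\t{sample}\t{n}\t{strand}\n")


def simulate_raw_reads(
    cfg: SimulationConfig,
    truth: TruthManifest,
    genome: Mapping[str, str],
    n_reads_per_gene: int = 5,
) -> list[tuple[str, str, int]]:
    """Raw (unaligned) reads: genomic insert + poly(A) tail.

    Returns ``(name, sequence, a_count)`` tuples; every true read carries at
    least ``tail_min_a`` A's. Used for FASTQ emission and tail-trimming
    round trips.
    """
    rng = rng_for(cfg.seed, "rawreads")
    seq = genome[CHROM]
    comp = str.maketrans("ACGT", "TGCA")
    out = []
    for g in truth.genes:
        for k in range(n_reads_per_gene):
            st = g.sites[int(rng.integers(len(g.sites)))]
            tail_len = cfg.tail_min_a + int(rng.poisson(cfg.tail_extra_mean))
            if g.strand == "+":
                insert = seq[max(st.pos + 1 - cfg.read_insert_len, 0) : st.pos + 1]
            else:
                frag = seq[st.pos : st.pos + cfg.read_insert_len]
                insert = frag.translate(comp)[::-1]
            out.append((f"{g.gene_id}_r{k}", insert + "A" * tail_len, tail_len))
    return out


def write_fastq(raw_reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, read_seq, _ in raw_reads:
            fh.write(f"@{name}\n{read_seq}\n+\n{'I' * len(read_seq)}\n")


def write_sam(
    reads: Mapping[str, Mapping[str, np.ndarray]],
    genome: Mapping[str, str],
    path: str | Path,
    read_len: int = 50,
) -> None:
    """Minimal aligned SAM for simulated 3'-end reads (one sample per file
    is encoded in the read names; the ZA tag carries the poly(A) length)."""
    clen = len(genome[CHROM])
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{clen}\n")
        i = 0
        for sample in sorted(reads):
            arrs = reads[sample]
            for p, s in zip(arrs["pos"], arrs["strand"]):
                if s == 0:
                    start = max(int(p) - read_len + 1, 0)
                    flag = 0
                else:
                    start = int(p)
                    flag = 16
                span = min(read_len, clen - start)
                fh.write(
                    f"{sample}.{i}\t{flag}\t{CHROM}\t{start + 1}\t60\t{span}M\t*\t0\t0\t"
                    f"{'N' * span}\t*\tZA:i:30\n"
                )
                i += 1


# ---------------------------------------------------------------------------
# RNA-seq, decay, cohort


def simulate_rnaseq(
    cfg: SimulationConfig, truth: TruthManifest, contrast: str
) -> CountMatrix:
    """Gene-level NB counts for one contrast (9 samples: 3 ctrl + 6 kd)."""
    rng = rng_for(cfg.seed, f"rnaseq:{contrast}")
    design = cfg.conditions()
    data = {}
    for sample, condition in design.items():
        kd = condition == "knockdown"
        col = []
        for g in truth.genes:
            mean = cfg.rnaseq_mean * (2.0 ** g.expression_lfc if kd else 1.0)
            col.append(_nb_draw(rng, mean, cfg.rnaseq_dispersion))
        data[sample] = col
    counts = pd.DataFrame(data, index=[g.gene_id for g in truth.genes])
    return CountMatrix(counts, design)


def simulate_decay(
    cfg: SimulationConfig,
    n_genes: int = 20,
    noise_sd: float | None = None,
    truth: TruthManifest | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Ct tables for a transcription-shutoff time course plus the truth K.

    Percent remaining follows ``100 * exp(-K (t - t0))`` at the configured
    time points, converted to Ct through the configured standard curve with
    Gaussian Ct noise. When a :class:`TruthManifest` is given, the course
    uses its gene ids and the drawn decay constants are recorded on it.
    """
    rng = rng_for(cfg.seed, "decay")
    if noise_sd is None:
        noise_sd = cfg.decay_ct_noise_sd
    if truth is not None:
        gene_ids = [g.gene_id for g in truth.genes][:n_genes]
        n_genes = len(gene_ids)
    else:
        gene_ids = [f"DECG{i:03d}" for i in range(n_genes)]
    ks = np.exp(rng.normal(np.log(np.log(2) / 6.0), 0.4, size=n_genes))
    if truth is not None:
        for g, k in zip(truth.genes, ks):
            g.decay_k = float(k)
    rows = []
    for gene, k in zip(gene_ids, ks):
        for t in cfg.decay_times:
            pct = 100.0 * np.exp(-k * (t - cfg.decay_t0))
            ct = cfg.curve_intercept + cfg.curve_slope * np.log10(pct / 100.0)
            ct += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"gene": gene, "time_h": t, "ct": ct})
    table = pd.DataFrame(rows)
    truth_k = pd.Series(ks, index=gene_ids, name="K")
    return table, truth_k


def simulate_cohort(
    cfg: SimulationConfig,
    gs: GeneSet,
    driver_gene: str = "CPSF1",
    rho: float | None = None,
) -> pd.DataFrame:
    """Cohort expression matrix: set genes correlate with the driver at
    ``rho``; background genes are independent standard normals."""
    rng = rng_for(cfg.seed, "cohort")
    if rho is None:
        rho = cfg.cohort_rho
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    if len(gs.members) < 2:
        raise ValueError("cohort simulation needs a gene set with >= 2 genes")
    n = cfg.cohort_samples
    samples = [f"PT{j:04d}" for j in range(n)]
    driver = rng.normal(size=n)
    rows = {driver_gene: driver}
    for gene in sorted(gs.members):
        noise = rng.normal(size=n)
        rows[gene] = rho * driver + np.sqrt(1.0 - rho**2) * noise
    for j in range(cfg.cohort_background_genes):
        rows[f"BGG{j:04d}"] = rng.normal(size=n)
    return pd.DataFrame(rows, index=samples).T
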