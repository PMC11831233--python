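"""Pipeline orchestration: partition -> quantify -> diff -> integrate.

Two entry points:

* :func:`run_simulation_study` — the fully in-memory end-to-end run on
  synthetic data, used by tests and the acceptance script: simulate the
  genome/annotation, generate 3'-end reads for every contrast, filter,
  count, test, score and derive the lengthened-and-down (QI) gene set, then
  compare against the simulation truth.
* :func:`run_pipeline` — the file-based run driven by a
  :class:`PipelineConfig`, writing per-stage outputs with provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import differential as diff
from . import integrate
from .annotation import (
    build_all_regions,
    chrom_lengths_from_fasta,
    load_annotation,
    write_regions_bed,
)
from .quant import (
    cluster_sites,
    count_by_feature,
    filter_internal_priming,
    read_three_prime_bed,
)
from .simulate import (
    SimulationConfig,
    TruthManifest,
    reads_to_sites,
    simulate_annotation,
    simulate_pac_reads,
    simulate_rnaseq,
)

logger = logging.getLogger(__name__)

#: every stage threshold with its default; these are the literal values the
#: analysis is defined with and the defaults of every CLI flag.
DEFAULT_PARAMETERS = {
    "extension_nt": 300,
    "window_nt": 10000,
    "min_a": 25,
    "ip_window": 20,
    "ip_max_a": 12,
    "cluster_gap": 25,
    "min_cpm": 2.0,
    "min_reads": 5,
    "padj_max": 0.1,
    "min_frac_change": 0.10,
    "pac_min": 0.5,
    "lfc_max": -0.25,
    "min_contrasts": 2,
}


@dataclass
class PipelineConfig:
    gtf: str = ""
    fasta: str = ""
    reads_bed: dict[str, str] = field(default_factory=dict)  # sample -> path
    rna_counts: str = ""
    design: dict[str, str] = field(default_factory=dict)  # sample -> condition
    out_dir: str = "pacscope_out"
    seed: int = 0
    parameters: dict = field(default_factory=lambda: dict(DEFAULT_PARAMETERS))


class ConfigError(ValueError):
    """Aggregated configuration violations."""


def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    """Check file existence, parameter sanity and design consistency.

    Raises :class:`ConfigError` listing every violation at once.
    """
    problems: list[str] = []
    for label, path in (("gtf", cfg.gtf), ("fasta", cfg.fasta)):
        if not path:
            problems.append(f"{label}: path not set")
        elif not Path(path).exists():
            problems.append(f"{label}: file not found: {path}")
    for sample, path in cfg.reads_bed.items():
        if not Path(path).exists():
            problems.append(f"reads[{sample}]: file not found: {path}")
        if sample not in cfg.design:
            problems.append(f"design: sample {sample!r} has no condition")
    for sample in cfg.design:
        if cfg.reads_bed and sample not in cfg.reads_bed:
            problems.append(f"design: sample {sample!r} has no reads file")

    p = {**DEFAULT_PARAMETERS, **cfg.parameters}
    for key in ("extension_nt", "window_nt", "min_a", "ip_window", "cluster_gap",
                "min_reads", "min_contrasts"):
        if p[key] <= 0:
            problems.append(f"parameter {key} must be positive, got {p[key]}")
    if p["ip_max_a"] < 0 or p["ip_max_a"] > p["ip_window"]:
        problems.append("parameter ip_max_a must lie in [0, ip_window]")
    if not 0 < p["padj_max"] <= 1:
        problems.append("parameter padj_max must lie in (0, 1]")
    if not 0 <= p["min_frac_change"] <= 1:
        problems.append("parameter min_frac_change must lie in [0, 1]")
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    cfg.parameters = p
    return cfg


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pacscope config={cfg_hash}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based run; returns a summary dict (also written as JSON)."""
    cfg = validate_config(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(cfg)
    provenance = {"config": asdict(cfg), "config_hash": cfg_hash, "stages": {}}
    p = cfg.parameters

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        provenance["stages"][name] = {"status": "running"}

        def done(**extra):
            provenance["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
                **extra,
            }
            logger.info("stage %s finished", name)

        return done

    try:
        done = stage("partition")
        ann = load_annotation(cfg.gtf)
        chrom_lengths = chrom_lengths_from_fasta(cfg.fasta)
        regions = build_all_regions(
            ann, p["extension_nt"], p["window_nt"], chrom_lengths
        )
        for cls, rs in regions.items():
            write_regions_bed(rs, out_dir / f"regions_{cls}.bed")
        done(n_genes=len(ann.genes))

        summary = {"config_hash": cfg_hash, "n_genes": len(ann.genes)}
        if cfg.reads_bed:
            done = stage("quantify")
            from pyfaidx import Fasta

            sites = []
            for sample, path in sorted(cfg.reads_bed.items()):
                sites.extend(read_three_prime_bed(path, sample))
            with Fasta(cfg.fasta) as genome:
                kept = filter_internal_priming(
                    sites, genome, p["ip_window"], p["ip_max_a"]
                )
            clusters = cluster_sites(kept, p["cluster_gap"])
            fc = count_by_feature(clusters, regions)
            counts = fc.to_frame().reindex(columns=sorted(cfg.design), fill_value=0)
            _write_table(counts, out_dir / "feature_counts.tsv", cfg_hash)
            done(n_sites=len(sites), n_kept=len(kept), n_clusters=len(clusters))

            done = stage("diff")
            cm = diff.CountMatrix(
                counts, cfg.design, pd.Series(fc.library_sizes, dtype=float)
            )
            keep = diff.filter_expressed(
                diff.cpm_normalize(cm), cfg.design, p["min_cpm"]
            ).intersection(diff.filter_min_reads(cm, p["min_reads"]))
            sub = diff.CountMatrix(
                cm.counts.loc[keep], cfg.design, cm.library_sizes
            )
            pac_diff = diff.diff_test(sub)
            _write_table(pac_diff, out_dir / "pac_diff.tsv", cfg_hash)
            summary["n_pac_units_tested"] = len(pac_diff)
            done(n_units=len(pac_diff))

        provenance["status"] = "ok"
        summary["status"] = "ok"
    except Exception as exc:
        provenance["status"] = "failed"
        failed = [k for k, v in provenance["stages"].items() if v.get("status") == "running"]
        provenance["failed_stage"] = failed[0] if failed else None
        provenance["error"] = str(exc)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
        raise
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


# ---------------------------------------------------------------------------
# in-memory end-to-end study on synthetic data


@dataclass
class ContrastResult:
    contrast: str
    pac_diff: pd.DataFrame  # (gene, region_class) units
    rna_diff: pd.DataFrame  # gene units
    score_table: pd.DataFrame  # pac_score / lfc_expr / quadrant


@dataclass
class StudyResult:
    truth: TruthManifest
    contrasts: list[ContrastResult]
    qi_geneset: integrate.GeneSet

    def qi_recovery(self) -> dict:
        """Recovery of intended-QI genes and false-inclusion rate."""
        truth_qi = self.truth.qi_genes()
        called = set(self.qi_geneset.members)
        negatives = {g.gene_id for g in self.truth.genes} - truth_qi
        recovered = len(called & truth_qi) / len(truth_qi) if truth_qi else float("nan")
        false_incl = len(called - truth_qi) / len(negatives) if negatives else 0.0
        return {
            "n_truth_qi": len(truth_qi),
            "n_called": len(called),
            "recovery": recovered,
            "false_inclusion": false_incl,
        }


def run_contrast(
    cfg: SimulationConfig,
    truth: TruthManifest,
    genome,
    regions,
    contrast: str,
    parameters: dict | None = None,
) -> ContrastResult:
    """Simulate and analyze one contrast end to end (in memory)."""
    p = {**DEFAULT_PARAMETERS, **(parameters or {})}
    design = cfg.conditions()
    reads = simulate_pac_reads(cfg, truth, contrast)
    sites = reads_to_sites(reads)
    kept = filter_internal_priming(sites, genome, p["ip_window"], p["ip_max_a"])
    clusters = cluster_sites(kept, p["cluster_gap"])
    fc = count_by_feature(clusters, regions)
    counts = fc.to_frame().reindex(columns=list(design), fill_value=0)
    cm = diff.CountMatrix(counts, design, pd.Series(fc.library_sizes, dtype=float))
    keep = diff.filter_expressed(
        diff.cpm_normalize(cm), design, p["min_cpm"]
    ).intersection(diff.filter_min_reads(cm, p["min_reads"]))
    pac_diff = diff.diff_test(
        diff.CountMatrix(cm.counts.loc[keep], design, cm.library_sizes),
        treated="knockdown",
        control="control",
    )

    rna_cm = simulate_rnaseq(cfg, truth, contrast)
    rna_keep = diff.filter_expressed(diff.cpm_normalize(rna_cm), design, p["min_cpm"])
    rna_diff = diff.diff_test(
        diff.CountMatrix(rna_cm.counts.loc[rna_keep], design, rna_cm.library_sizes),
        treated="knockdown",
        control="control",
    )
    score_table = integrate.build_pac_score_table(pac_diff, rna_diff, "downstream10k")
    return ContrastResult(contrast, pac_diff, rna_diff, score_table)


def run_simulation_study(
    cfg: SimulationConfig, parameters: dict | None = None
) -> StudyResult:
    """Full synthetic study across all contrasts plus QI gene-set derivation."""
    p = {**DEFAULT_PARAMETERS, **(parameters or {})}
    genome, gtf_text, truth = simulate_annotation(cfg)
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(gtf_text)
        gtf_path = fh.name
    try:
        ann = load_annotation(gtf_path)
    finally:
        Path(gtf_path).unlink()
    chrom_lengths = {name: len(seq) for name, seq in genome.items()}
    regions = build_all_regions(ann, p["extension_nt"], p["window_nt"], chrom_lengths)

    results = [
        run_contrast(cfg, truth, genome, regions, contrast, p)
        for contrast in cfg.contrasts
    ]
    qi = integrate.derive_qi_geneset(
        [r.score_table for r in results],
        pac_min=p["pac_min"],
        lfc_max=p["lfc_max"],
        min_contrasts=p["min_contrasts"],
    )
    return StudyResult(truth, results, qi)
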