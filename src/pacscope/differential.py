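"""Normalization, expression filters, differential testing and APA calls.

The differential test is a deliberately simple stand-in for a quasi-likelihood
negative-binomial GLM fit: per unit, group means are estimated from
library-size-normalized counts, a method-of-moments NB dispersion (floored at
zero, the Poisson limit) supplies the delta-method variance of the log mean
difference, and the Wald statistic is referred to a t distribution with
``n1 + n2 - 2`` degrees of freedom as a small-sample correction. It is
calibration-checked, not value-matched, against the original software's test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer counts (units x samples) with a sample -> condition design."""

    counts: pd.DataFrame
    design: dict[str, str]  # sample -> condition
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design)
        if missing:
            raise ValueError(f"samples without condition in design: {sorted(missing)}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for smp in self.counts.columns:
            seen.setdefault(self.design[smp], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]


def cpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts * 1e6 / library_size`` per sample."""
    if (cm.library_sizes <= 0).any():
        bad = cm.library_sizes[cm.library_sizes <= 0].index.tolist()
        raise ValueError(f"zero/negative library size for samples {bad}")
    return cm.counts * 1e6 / cm.library_sizes


def filter_expressed(
    cpm: pd.DataFrame, design: dict[str, str], min_cpm: float = 2.0
) -> pd.Index:
    """Units whose condition-mean cpm exceeds ``min_cpm`` in every condition."""
    if cpm.empty:
        return cpm.index
    cond = pd.Series({s: design[s] for s in cpm.columns})
    means = cpm.T.groupby(cond).mean().T
    keep = (means > min_cpm).all(axis=1)
    return cpm.index[keep]


def filter_min_reads(cm: CountMatrix, min_reads: int = 5) -> pd.Index:
    """Units with at least ``min_reads`` total counts in >= 1 condition."""
    cond = pd.Series({s: cm.design[s] for s in cm.counts.columns})
    totals = cm.counts.T.groupby(cond).sum().T
    keep = (totals >= min_reads).any(axis=1)
    return cm.counts.index[keep]


def diff_test(
    cm: CountMatrix,
    treated: str | None = None,
    control: str | None = None,
    prior_cpm: float = 0.5,
) -> pd.DataFrame:
    """Per-unit log2FC (treated vs control) and NB Wald p-values.

    log2FC uses condition-mean cpm with a ``prior_cpm`` pseudo-count. The
    Wald statistic tests equality of NB means with a per-unit
    method-of-moments dispersion (pooled across the two groups, floored at
    0); with fewer than 2 replicates in either group the p-value is NaN but
    the log2FC is still reported.

    Returns a DataFrame with columns ``log2fc``, ``p``, ``padj``,
    ``cpm_control``, ``cpm_treated``.
    """
    conditions = cm.conditions
    if len(conditions) < 2:
        raise ValueError("diff_test needs two conditions")
    if control is None:
        control = conditions[0]
    if treated is None:
        treated = next(c for c in conditions if c != control)

    cpm = cpm_normalize(cm)
    ctrl_samples = cm.samples_of(control)
    trt_samples = cm.samples_of(treated)
    if not ctrl_samples or not trt_samples:
        raise ValueError(f"conditions {control!r}/{treated!r} not in design")

    cpm_c = cpm[ctrl_samples].mean(axis=1)
    cpm_t = cpm[trt_samples].mean(axis=1)
    log2fc = np.log2((cpm_t + prior_cpm) / (cpm_c + prior_cpm))

    # Work on counts rescaled to the mean library size so the NB moment
    # machinery sees a common scale (exact when library sizes are equal).
    scale = cm.library_sizes.mean() / cm.library_sizes
    y = cm.counts * scale
    yc = y[ctrl_samples].to_numpy(float)
    yt = y[trt_samples].to_numpy(float)
    n_c, n_t = yc.shape[1], yt.shape[1]

    if n_c < 2 or n_t < 2:
        logger.warning("fewer than 2 replicates per condition: p-values NaN")
        p = np.full(len(cpm_c), np.nan)
    else:
        mu_c = yc.mean(axis=1)
        mu_t = yt.mean(axis=1)
        var_c = yc.var(axis=1, ddof=1)
        var_t = yt.var(axis=1, ddof=1)
        # pooled method-of-moments dispersion: var = mu + alpha mu^2
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (var_c - mu_c) + (var_t - mu_t)
            den = mu_c**2 + mu_t**2
            alpha = np.where(den > 0, num / den, 0.0)
        alpha = np.maximum(alpha, 0.0)  # Poisson limit floor
        mu_c_s = np.maximum(mu_c, 0.5)
        mu_t_s = np.maximum(mu_t, 0.5)
        # delta method: var(log mean) ~ (1/mu + alpha) / n
        se2 = (1.0 / mu_c_s + alpha) / n_c + (1.0 / mu_t_s + alpha) / n_t
        wald = (np.log(mu_t_s) - np.log(mu_c_s)) / np.sqrt(se2)
        df = n_c + n_t - 2
        p = 2.0 * stats.t.sf(np.abs(wald), df)
        p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "cpm_control": cpm_c,
            "cpm_treated": cpm_t,
        },
        index=cm.counts.index,
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1.

    NaN entries (untestable units) propagate as NaN and do not enter the
    correction.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        from statsmodels.stats.multitest import multipletests

        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


@dataclass
class ApaCall:
    gene: str
    direction: str  # "lengthening" | "shortening"
    n_clusters: int
    best_padj: float
    max_frac_change: float


def usage_fractions(
    cluster_counts: pd.DataFrame, design: dict[str, str]
) -> pd.DataFrame:
    """Per-condition usage fraction of each cluster within its gene.

    ``cluster_counts`` is indexed by (gene, cluster position) with samples
    as columns. Fractions per gene and condition sum to 1; genes with a
    zero total in any condition are dropped (usage undefined) with a log
    message.
    """
    cond = pd.Series({s: design[s] for s in cluster_counts.columns})
    by_cond = cluster_counts.T.groupby(cond).sum().T
    gene_totals = by_cond.groupby(level=0).sum()
    bad = gene_totals.index[(gene_totals == 0).any(axis=1)]
    if len(bad):
        logger.info("dropping %d genes with zero totals in a condition", len(bad))
        by_cond = by_cond.drop(index=bad, level=0)
        gene_totals = gene_totals.drop(index=bad)
    frac = by_cond / gene_totals.reindex(by_cond.index.get_level_values(0)).values
    return frac


def call_apa(
    pac_diff: pd.DataFrame,
    padj_max: float = 0.1,
    min_frac_change: float = 0.10,
    min_pacs: int = 2,
) -> list[ApaCall]:
    """Per-gene APA calls from a cluster-level differential table.

    ``pac_diff`` must be indexed by (gene, cluster position) and carry
    columns ``padj``, ``usage_control``, ``usage_treated``, ``strand``. A
    gene is called when it has at least ``min_pacs`` clusters and at least
    one cluster with ``padj < padj_max`` whose absolute usage change is at
    least ``min_frac_change``. Direction follows the most distal qualifying
    cluster: lengthening if it gains usage, shortening if it loses it.
    """
    calls: list[ApaCall] = []
    for gene, sub in pac_diff.groupby(level=0, sort=True):
        if len(sub) < min_pacs:
            continue
        dusage = sub["usage_treated"] - sub["usage_control"]
        qual = (sub["padj"] < padj_max) & (dusage.abs() >= min_frac_change)
        if not qual.any():
            continue
        qsub = sub[qual]
        strand = qsub["strand"].iloc[0]
        positions = qsub.index.get_level_values(1).to_numpy()
        distal_idx = positions.argmax() if strand == "+" else positions.argmin()
        change = dusage[qual].iloc[distal_idx]
        direction = "lengthening" if change > 0 else "shortening"
        calls.append(
            ApaCall(
                gene=gene,
                direction=direction,
                n_clusters=len(sub),
                best_padj=float(sub["padj"].min()),
                max_frac_change=float(dusage.abs().max()),
            )
        )
    return calls
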