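"""Gene-set signature scoring in cohort expression matrices.

A signature score for a sample is the unweighted mean of per-gene Z-scores
(standardized across samples) over the genes of a set. Scores are compared
to a driver gene's Z-score by Pearson correlation (reported R) with the
p-value from a Spearman rank test, and between sample groups by an unpaired
two-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .integrate import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class SignatureScore:
    scores: pd.Series  # per sample
    set_name: str
    n_used: int
    n_missing: int


def zscore_by_gene(em: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene (row) across samples with sample (n-1) sd.

    Genes with zero variance are dropped with a warning.
    """
    if em.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    if em.index.duplicated().any():
        raise ValueError("duplicated gene ids in expression matrix")
    sd = em.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant genes from Z matrix", int(constant.sum()))
        em = em.loc[~constant]
        sd = sd.loc[~constant]
    return em.sub(em.mean(axis=1), axis=0).div(sd, axis=0)


def signature_score(z: pd.DataFrame, gs: GeneSet) -> SignatureScore:
    """Per-sample mean Z over set genes present in the matrix."""
    present = [g for g in sorted(gs.members) if g in z.index]
    if not present:
        raise ValueError(f"no genes of set {gs.name!r} present in matrix")
    missing = len(gs.members) - len(present)
    if missing:
        logger.info("%d/%d set genes missing from matrix", missing, len(gs.members))
    return SignatureScore(
        scores=z.loc[present].mean(axis=0),
        set_name=gs.name,
        n_used=len(present),
        n_missing=missing,
    )


def correlate_scores(x, y) -> tuple[float, float, float]:
    """Pearson r (headline R) plus Spearman rho and its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    pearson_r = stats.pearsonr(x, y).statistic
    sp = stats.spearmanr(x, y)
    return float(pearson_r), float(sp.statistic), float(sp.pvalue)


def compare_groups(
    scores: pd.Series, groups: pd.Series, equal_var: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test between the two labels in ``groups``.

    Welch's test by default; ``equal_var=True`` for the pooled-variance
    Student test. Returns ``(t, p)`` with t oriented as first label minus
    second (label order = order of first appearance).
    """
    groups = groups.reindex(scores.index)
    labels = list(dict.fromkeys(groups.dropna()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    a = scores[groups == labels[0]]
    b = scores[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes-in-rows TSV expression matrix with a header of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)
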