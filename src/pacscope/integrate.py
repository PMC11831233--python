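"""Integration of 3'-end (PAC) and RNA-seq differential results.

The PAC-score for a gene and a non-UTR region class is the difference of
log2 fold changes of 3'-end read counts::

    pac_score = log2FC(region) - log2FC(annotated 3' UTR)

A positive score means poly(A)-site usage shifted toward the region (e.g.
the 10-kb downstream window) relative to the annotated 3' UTR; transcription
-level fold changes cancel in the subtraction. Genes are then classified
into quadrants against the RNA-seq expression log2FC:

    QI   expression down, score up      (lengthening with loss of mRNA)
    QII  expression up,   score up
    QIII expression up,   score down
    QIV  expression down, score down

and gene sets are derived from thresholded, multi-contrast intersections.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

P_FLOOR = 1e-300

QUADRANTS = ("QI", "QII", "QIII", "QIV", "unclassified")


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: dict

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("gene set provenance must be recorded")


def pac_score(lfc_region, lfc_utr3):
    """``lfc_region - lfc_utr3``; positive = shift toward the region.

    Accepts scalars or aligned arrays/Series; missing components give NaN.
    """
    return np.asarray(lfc_region, dtype=float) - np.asarray(lfc_utr3, dtype=float)


def build_pac_score_table(
    pac_diff: pd.DataFrame,
    rna_diff: pd.DataFrame,
    region_class: str,
) -> pd.DataFrame:
    """Join per-(gene, region) PAC log2FCs with RNA-seq log2FCs.

    ``pac_diff`` is indexed by (gene, region_class) with a ``log2fc``
    column; ``rna_diff`` is indexed by gene. Only genes quantifiable by all
    metrics (region log2FC, utr3 log2FC, expression log2FC) are returned.
    """
    lfc = pac_diff["log2fc"].unstack("region_class")
    if region_class not in lfc.columns or "utr3" not in lfc.columns:
        return pd.DataFrame(
            columns=["pac_score", "lfc_region", "lfc_utr3", "lfc_expr", "quadrant"]
        )
    tab = pd.DataFrame(
        {
            "lfc_region": lfc[region_class],
            "lfc_utr3": lfc["utr3"],
            "lfc_expr": rna_diff["log2fc"].reindex(lfc.index),
        }
    ).dropna()
    tab["pac_score"] = pac_score(tab["lfc_region"], tab["lfc_utr3"])
    tab["quadrant"] = classify_quadrants(tab["pac_score"], tab["lfc_expr"])
    return tab


def classify_quadrants(score, lfc_expr) -> pd.Series:
    """Quadrant label per gene from the signs of (expression lfc, score).

    Exact zeros in either coordinate are left ``unclassified``.
    """
    score = pd.Series(np.asarray(score, dtype=float))
    lfc = pd.Series(np.asarray(lfc_expr, dtype=float), index=score.index)
    out = pd.Series("unclassified", index=score.index, dtype=object)
    out[(lfc < 0) & (score > 0)] = "QI"
    out[(lfc > 0) & (score > 0)] = "QII"
    out[(lfc > 0) & (score < 0)] = "QIII"
    out[(lfc < 0) & (score < 0)] = "QIV"
    if isinstance(lfc_expr, pd.Series):
        out.index = lfc_expr.index
    return out


def quadrant_counts(quadrants: Iterable[str]) -> dict[str, int]:
    counts = {q: 0 for q in QUADRANTS}
    for q in quadrants:
        counts[q] += 1
    return counts


def derive_qi_geneset(
    contrast_tables: Sequence[pd.DataFrame],
    pac_min: float = 0.5,
    lfc_max: float = -0.25,
    min_contrasts: int = 2,
    name: str = "lengthened_down_QI",
) -> GeneSet:
    """Genes with downstream lengthening and decreased expression in at
    least ``min_contrasts`` contrasts.

    Per contrast the gene must satisfy ``pac_score > pac_min`` and
    ``lfc_expr < lfc_max`` (strict inequalities). ``contrast_tables`` are
    outputs of :func:`build_pac_score_table` for the same region class.
    """
    if len(contrast_tables) < min_contrasts:
        raise ValueError(
            f"need >= {min_contrasts} contrast tables, got {len(contrast_tables)}"
        )
    votes: dict[str, int] = {}
    for tab in contrast_tables:
        passing = tab.index[(tab["pac_score"] > pac_min) & (tab["lfc_expr"] < lfc_max)]
        for gene in passing:
            votes[gene] = votes.get(gene, 0) + 1
    members = frozenset(g for g, n in votes.items() if n >= min_contrasts)
    return GeneSet(
        name,
        members,
        {
            "pac_min": pac_min,
            "lfc_max": lfc_max,
            "min_contrasts": min_contrasts,
            "n_contrasts": len(contrast_tables),
        },
    )


def signed_log10_fdr(de_table: pd.DataFrame) -> pd.Series:
    """``sign(log2FC) * -log10(padj)`` with padj floored at 1e-300."""
    padj = de_table["padj"].clip(lower=P_FLOOR)
    return np.sign(de_table["log2fc"]) * -np.log10(padj)


def derive_extreme_fdr_genesets(
    de_tables: Sequence[pd.DataFrame],
    threshold: float = 4.0,
    name_prefix: str = "extreme",
) -> tuple[GeneSet, GeneSet]:
    """(up, down) gene sets: intersection across tables of genes whose
    signed -log10 FDR exceeds ``threshold`` (up) or falls below
    ``-threshold`` (down)."""
    ups: list[set[str]] = []
    downs: list[set[str]] = []
    for tab in de_tables:
        s = signed_log10_fdr(tab)
        ups.append(set(s.index[s > threshold]))
        downs.append(set(s.index[s < -threshold]))
    up = frozenset(set.intersection(*ups)) if ups else frozenset()
    down = frozenset(set.intersection(*downs)) if downs else frozenset()
    prov = {"threshold": threshold, "n_tables": len(de_tables)}
    return (
        GeneSet(f"{name_prefix}_UP", up, prov),
        GeneSet(f"{name_prefix}_DOWN", down, prov),
    )


def prerank_metric(de_table: pd.DataFrame) -> pd.Series:
    """Ranking metric ``sign(log2FC) * -log10(p)`` sorted descending.

    The most significantly up-regulated genes land at the top and the most
    significantly down-regulated at the bottom. Ties break lexicographically
    by gene id for determinism; p is floored at 1e-300.
    """
    p = de_table["p"].clip(lower=P_FLOOR)
    metric = np.sign(de_table["log2fc"]) * -np.log10(p)
    metric = metric.rename("metric")
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    return metric.loc[order]


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = ";".join(f"{k}={v}" for k, v in sorted(gs.provenance.items()))
            fh.write("\t".join([gs.name, desc, *sorted(gs.members)]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, desc, *members = line.rstrip("\n").split("\t")
            sets.append(GeneSet(name, frozenset(members), {"source": desc or str(path)}))
    return sets


def write_rnk(metric: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, value in metric.items():
            fh.write(f"{gene}\t{value:.6g}\n")
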