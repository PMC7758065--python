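"""Cell-type marker identification and parenchymal marker selection.

Positivity is defined once, package-wide: a cell is positive for a gene when
``ln(1 + CPM) >= threshold`` (default 1.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .expr_io import NormalizedMatrix, ValidationError, annotation_groups, as_cpm

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "rank_markers",
    "top_positive_markers",
    "select_parenchymal_markers",
    "remove_prefixed_genes",
    "read_gene_set",
    "write_gene_set",
]

DEFAULT_POSITIVITY_THRESHOLD = 1.0


@dataclass(frozen=True)
class GeneSet:
    """Ordered, duplicate-free list of gene ids with a provenance tag."""

    genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene id in GeneSet")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


def _group_masks(m: NormalizedMatrix, ann: pd.DataFrame, group: str):
    groups = annotation_groups(ann, m.cell_ids)
    if group not in groups:
        raise ValidationError(f"cell type {group!r} absent from annotations")
    in_mask = groups[group]
    annotated = np.zeros(len(m.cell_ids), dtype=bool)
    for mask in groups.values():
        annotated |= mask
    out_mask = annotated & ~in_mask
    return in_mask, out_mask


def _marker_stats(
    m: NormalizedMatrix,
    ann: pd.DataFrame,
    group: str,
    positivity_threshold: float,
) -> pd.DataFrame:
    """Vectorized per-gene fraction-positive and pseudocounted fold stats."""
    in_mask, out_mask = _group_masks(m, ann, group)
    if in_mask.sum() < 1 or out_mask.sum() < 1:
        raise ValidationError(f"group {group!r} needs cells both in and out of group")
    cpm = as_cpm(m)
    log1p = np.log1p(cpm)
    pos = log1p >= positivity_threshold
    frac_in = pos[in_mask].mean(axis=0)
    frac_out = pos[out_mask].mean(axis=0)
    mean_in = cpm[in_mask].mean(axis=0)
    mean_out = cpm[out_mask].mean(axis=0)
    fold = (mean_in + 1.0) / (mean_out + 1.0)
    return pd.DataFrame(
        {
            "frac_in": frac_in,
            "frac_out": frac_out,
            "mean_in": mean_in,
            "mean_out": mean_out,
            "fold": fold,
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )


def rank_markers(
    m: NormalizedMatrix,
    ann: pd.DataFrame,
    group: str,
    positivity_threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene marker statistics for one cell type versus all other cells.

    For every gene: fraction of positive cells in/out of group, mean CPM
    in/out, pseudocounted fold ``(mean_in + 1) / (mean_out + 1)``, a
    two-sided Wilcoxon rank-sum p-value on the per-cell normalized values,
    and Benjamini-Hochberg adjusted p-values across all genes.
    """
    in_mask, out_mask = _group_masks(m, ann, group)
    if in_mask.sum() < 2 or out_mask.sum() < 2:
        raise ValidationError(
            f"need >=2 cells in and out of group {group!r} "
            f"(got {int(in_mask.sum())} / {int(out_mask.sum())})"
        )
    table = _marker_stats(m, ann, group, positivity_threshold)
    vals_in = m.values[in_mask]
    vals_out = m.values[out_mask]
    pvals = np.ones(len(m.gene_ids))
    for j in range(len(m.gene_ids)):
        a, b = vals_in[:, j], vals_out[:, j]
        if np.all(a == a[0]) and np.all(b == a[0]):
            pvals[j] = 1.0  # constant gene: no evidence either way
            continue
        pvals[j] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    table["rank_sum_p"] = pvals
    table["adj_p"] = multipletests(pvals, method="fdr_bh")[1]
    return table


def top_positive_markers(t: pd.DataFrame, n: int = 300) -> GeneSet:
    """Top-``n`` positively associated markers from a :func:`rank_markers` table.

    Genes with ``fold > 1`` are ordered by ascending p, then descending
    fold, then gene id; fewer than ``n`` qualifying genes is not an error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    qualifying = t[t["fold"] > 1].reset_index()
    qualifying = qualifying.sort_values(
        by=["rank_sum_p", "fold", "gene_id"], ascending=[True, False, True]
    )
    chosen = tuple(qualifying["gene_id"].head(n))
    return GeneSet(chosen, provenance=f"top_positive_markers(n={n})")


def select_parenchymal_markers(
    m: NormalizedMatrix,
    ann: pd.DataFrame,
    target_group: str,
    min_frac: float = 0.60,
    min_fold: float = 10.0,
    n: int = 15,
    positivity_threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> GeneSet:
    """Select parenchymal signature genes by fraction-expressing and fold rules.

    A gene qualifies when it is positive in more than ``min_frac`` of
    ``target_group`` cells and its pseudocounted CPM fold over all other
    annotated cells is at least ``min_fold``. Qualifiers are ranked by fold
    (descending, gene id breaking ties) and truncated to ``n``; a shortfall
    is logged, not raised.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    stats = _marker_stats(m, ann, target_group, positivity_threshold)
    qual = stats[(stats["frac_in"] > min_frac) & (stats["fold"] >= min_fold)]
    qual = qual.reset_index().sort_values(by=["fold", "gene_id"], ascending=[False, True])
    if len(qual) < n:
        logger.info(
            "select_parenchymal_markers: only %d of requested %d genes qualify",
            len(qual), n,
        )
    chosen = tuple(qual["gene_id"].head(n))
    return GeneSet(
        chosen,
        provenance=(
            f"select_parenchymal_markers(group={target_group}, min_frac={min_frac}, "
            f"min_fold={min_fold}, n={n}, threshold={positivity_threshold})"
        ),
    )


def remove_prefixed_genes(gs: GeneSet, prefix: str = "mt-") -> GeneSet:
    """Drop genes whose id starts with ``prefix`` (case-insensitive).

    Used to exclude mitochondrial genes before exporting gene sets for
    accessibility profiling, where they are uninformative.
    """
    kept = tuple(g for g in gs.genes if not g.lower().startswith(prefix.lower()))
    return GeneSet(kept, provenance=f"{gs.provenance} | remove_prefix({prefix})")


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    """One gene per line, with a header comment recording provenance."""
    with open(path, "w") as fh:
        fh.write(f"# {gs.provenance}\n")
        for g in gs.genes:
            fh.write(g + "\n")


def read_gene_set(path: str | Path) -> GeneSet:
    provenance = ""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                provenance = line.lstrip("# ").strip()
            elif line:
                genes.append(line)
    return GeneSet(tuple(genes), provenance=provenance)
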