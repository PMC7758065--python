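"""Rank-correlation contamination statistics and marker positivity counting.

The central diagnostic: if transcripts detected in a target population were
ambient carry-over from a source population, their relative abundances
should mirror the source profile — a high rank correlation over the most
highly expressed genes. Cell-intrinsic, stochastic transcription predicts a
low correlation and few positive markers per positive cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .expr_io import NormalizedMatrix, ValidationError, annotation_groups
from .markers import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "TauResult",
    "MarkerCountDistribution",
    "top_expressed_genes",
    "kendall_tau",
    "contamination_rank_test",
    "positivity_matrix",
    "marker_count_distribution",
    "mds_embed",
    "classical_mds",
    "read_profiles_tsv",
]


@dataclass(frozen=True)
class TauResult:
    """Tie-corrected Kendall tau over a declared top-N gene universe."""

    tau: float
    n_genes: int
    gene_universe: GeneSet
    ranking_reference: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.tau <= 1.0 + 1e-12:
            raise ValidationError(f"tau out of range: {self.tau}")
        if self.n_genes != len(self.gene_universe):
            raise ValidationError("n_genes inconsistent with gene_universe")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "n_genes": self.n_genes,
                "ranking_reference": self.ranking_reference,
                "gene_universe": list(self.gene_universe.genes),
            },
            indent=2,
        )


@dataclass
class MarkerCountDistribution:
    """Per-group histogram of positive-marker counts per cell."""

    n_markers: int
    histograms: dict[str, np.ndarray] = field(default_factory=dict)

    def frac_ge1(self, group: str) -> float:
        h = self.histograms[group]
        total = h.sum()
        return float(h[1:].sum() / total) if total else float("nan")

    def median_positive_among_positive(self, group: str) -> float:
        """Median number of positive markers among cells with >=1 positive."""
        h = self.histograms[group]
        expanded = np.repeat(np.arange(1, self.n_markers + 1), h[1:])
        return float(np.median(expanded)) if expanded.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {g: h for g, h in self.histograms.items()},
            index=pd.Index(range(self.n_markers + 1), name="n_positive_markers"),
        )


def _as_series(profile: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(profile, dtype=float)
    if s.empty:
        raise ValidationError("empty expression profile")
    return s


def top_expressed_genes(profile: Mapping[str, float] | pd.Series, n: int = 300) -> GeneSet:
    """The ``n`` highest-expressed genes of a profile, ties broken by gene id."""
    s = _as_series(profile)
    if n > len(s):
        logger.info("top_expressed_genes: requested %d, only %d genes available", n, len(s))
        n = len(s)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return GeneSet(tuple(order[:n]), provenance=f"top_expressed_genes(n={n})")


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("kendall_tau requires two equal-length 1-D vectors")
    if len(x) < 2:
        raise ValidationError("kendall_tau requires length >= 2")
    return float(scipy.stats.kendalltau(x, y, variant="b").statistic)


def contamination_rank_test(
    profile_target: Mapping[str, float] | pd.Series,
    profile_source: Mapping[str, float] | pd.Series,
    n: int = 300,
    ranking_reference: str = "source",
    scale: str = "log2_cpm",
) -> TauResult:
    """Kendall tau-b between two expression profiles over a top-N universe.

    Both profiles are rescaled to CPM; the top-``n`` universe is chosen by
    the ``ranking_reference`` profile (``source``, ``target``, or ``union``
    = ranked by the sum of both CPM profiles). Correlation is computed on
    ``log2(CPM + 1)`` by default; ``scale="raw"`` correlates CPM directly
    (identical ranks, tie structure may differ).
    """
    t = _as_series(profile_target)
    s = _as_series(profile_source)
    shared = t.index.intersection(s.index)
    if len(shared) == 0:
        raise ValidationError("profiles share no genes")
    t = t[shared] / t[shared].sum() * 1e6
    s = s[shared] / s[shared].sum() * 1e6
    if len(shared) < n:
        logger.info(
            "contamination_rank_test: only %d shared genes for requested top %d",
            len(shared), n,
        )
        n = len(shared)
    if ranking_reference == "source":
        universe = top_expressed_genes(s, n)
    elif ranking_reference == "target":
        universe = top_expressed_genes(t, n)
    elif ranking_reference == "union":
        universe = top_expressed_genes(t + s, n)
    else:
        raise ValueError(f"unknown ranking_reference {ranking_reference!r}")
    genes = list(universe.genes)
    tv, sv = t[genes].to_numpy(), s[genes].to_numpy()
    if scale == "log2_cpm":
        tv, sv = np.log2(tv + 1.0), np.log2(sv + 1.0)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    return TauResult(
        tau=kendall_tau(tv, sv),
        n_genes=len(genes),
        gene_universe=universe,
        ranking_reference=ranking_reference,
    )


def positivity_matrix(
    m: NormalizedMatrix, genes: GeneSet, threshold: float = 1.0
) -> pd.DataFrame:
    """Binary cell x gene table: 1 iff ``ln(1 + CPM) >= threshold``.

    The boundary is inclusive: a value of exactly ``threshold`` is positive.
    """
    if m.scale != "log1p_cpm":
        raise ValidationError(
            f"positivity_matrix requires scale 'log1p_cpm', got {m.scale!r}"
        )
    missing = [g for g in genes if g not in m.gene_ids]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    cols = [m.gene_ids.index(g) for g in genes]
    values = (m.values[:, cols] >= threshold).astype(np.int8)
    return pd.DataFrame(values, index=m.cell_ids, columns=list(genes.genes))


def marker_count_distribution(
    p: pd.DataFrame, ann: pd.DataFrame, groups: Sequence[str]
) -> MarkerCountDistribution:
    """Histogram the per-cell number of positive markers for each group."""
    n_markers = p.shape[1]
    masks = annotation_groups(ann, list(p.index))
    result = MarkerCountDistribution(n_markers=n_markers)
    per_cell = p.to_numpy().sum(axis=1)
    for g in groups:
        if g not in masks or not masks[g].any():
            raise ValidationError(f"empty or unknown group {g!r}")
        counts = per_cell[masks[g]]
        result.histograms[g] = np.bincount(counts, minlength=n_markers + 1)
    return result


def mds_embed(
    profiles: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    top_variable: int = 1000,
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of expression profiles into two dimensions.

    Profiles (gene x sample) are CPM-scaled and log2(CPM+1)-transformed;
    the ``top_variable`` genes by cross-sample variance are kept; samples
    are embedded by double-centering the squared Euclidean distance matrix.
    Classical MDS reproduces Euclidean distance matrices exactly (up to
    rotation/reflection); axes are sign-fixed for determinism.
    """
    df = pd.DataFrame(profiles).astype(float)  # genes x samples
    if df.shape[1] < 3:
        raise ValidationError("mds_embed requires at least 3 samples")
    df = df / df.sum(axis=0) * 1e6
    df = np.log2(df + 1.0)
    if top_variable < len(df):
        variances = df.var(axis=1)
        order = sorted(df.index, key=lambda g: (-variances[g], g))
        df = df.loc[order[:top_variable]]
    else:
        logger.info("mds_embed: only %d genes available for top %d", len(df), top_variable)
    x = df.to_numpy().T  # samples x genes
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    coords = classical_mds(d, n_components=2)
    return pd.DataFrame(coords, index=df.columns, columns=["mds1", "mds2"])


def classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson scaling of a symmetric distance matrix.

    Double-centers the squared distances and takes the top eigenpairs;
    embeds Euclidean distance matrices exactly (up to rigid motion). Axes
    are sign-fixed (largest-magnitude coordinate positive) for determinism
    and the output is centered at the origin by construction.
    """
    d2 = np.asarray(distances, dtype=float) ** 2
    if d2.ndim != 2 or d2.shape[0] != d2.shape[1]:
        raise ValidationError("distance matrix must be square")
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:n_components]
    lam = np.clip(eigval[idx], 0.0, None)
    lam[lam < lam.max() * 1e-12] = 0.0  # numerically-zero axes carry no signal
    coords = eigvec[:, idx] * np.sqrt(lam)
    for k in range(coords.shape[1]):  # deterministic axis orientation
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] *= -1
    return coords


def read_profiles_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene ids in profile table")
    return df.astype(float)
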