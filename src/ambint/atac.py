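"""TSS-window accessibility, metaprofiles, and peak-set comparison.

Accessibility of a gene is measured as RPKM of reads overlapping a fixed
window around its TSS (default +/- 250 bp): ``count / (window_kb *
library_size / 1e6)``. Window counts use >= 1 bp interval overlap;
metaprofiles bin read *start* positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_io import GeneModelSet, ValidationError
from .markers import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ReadSet",
    "PeakSet",
    "tss_window_rpkm",
    "classify_accessibility",
    "tss_metaprofile",
    "relative_accessibility",
    "select_tissue_enriched",
    "peak_set_compare",
    "annotate_peaks_to_genes",
    "read_reads_bed",
    "write_reads_bed",
    "read_reads_sam",
    "read_peaks",
    "write_peaks",
]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "pvalue", "qvalue", "summit",
]


@dataclass
class ReadSet:
    """Genomic read intervals plus the library size used for normalization.

    ``library_size`` defaults to the number of intervals; supplying an
    explicit external total models the common case where only reads near a
    region of interest are materialized while normalization reflects the
    full library.
    """

    intervals: pd.DataFrame  # columns chrom, start, end
    library_size: int | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"ReadSet intervals missing column {col!r}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("ReadSet contains an empty or inverted interval")
        if self.library_size is None:
            self.library_size = len(df)
        if self.library_size <= 0:
            raise ValidationError("library_size must be positive")
        for chrom, sub in df.groupby("chrom", sort=False):
            self._index[str(chrom)] = (
                np.sort(sub["start"].to_numpy()),
                np.sort(sub["end"].to_numpy()),
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of intervals overlapping [start, end) by >= 1 bp."""
        if chrom not in self._index:
            return 0
        starts, ends = self._index[chrom]
        n = len(starts)
        n_right = n - np.searchsorted(starts, end, side="left")   # start >= end
        n_left = np.searchsorted(ends, start, side="right")       # end <= start
        return int(n - n_right - n_left)


@dataclass
class PeakSet:
    """Peak intervals with narrowPeak metadata preserved where present."""

    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.peaks.columns:
                raise ValidationError(f"PeakSet missing column {col!r}")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValidationError("PeakSet contains an empty or inverted interval")

    def __len__(self) -> int:
        return len(self.peaks)


def tss_window_rpkm(
    reads: ReadSet, models: GeneModelSet, halfwidth: int = 250
) -> pd.DataFrame:
    """Read count and RPKM in a +/- ``halfwidth`` window around each TSS.

    Genes on chromosomes with no reads get count 0, not an error.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    window_kb = 2 * halfwidth / 1000.0
    per_million = reads.library_size / 1e6
    rows = []
    for g in models:
        ws, we = g.tss - halfwidth, g.tss + halfwidth
        count = reads.count_overlapping(g.chrom, ws, we)
        rows.append(
            {
                "gene_id": g.gene_id, "chrom": g.chrom,
                "window_start": ws, "window_end": we,
                "read_count": count,
                "rpkm": count / (window_kb * per_million),
                "label": pd.NA,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def classify_accessibility(
    t: pd.DataFrame,
    closed_max: float = 1.5,
    open_min: float = 3.0,
    scale: str = "rpkm",
) -> pd.DataFrame:
    """Label genes open/closed/indeterminate by thresholding (log2-)RPKM.

    The scale is an explicit parameter because raw-RPKM and log2-RPKM
    thresholds are both in circulation; it is never guessed.
    """
    if closed_max >= open_min:
        raise ValidationError("closed_max must be below open_min")
    out = t.copy()
    if scale == "rpkm":
        v = out["rpkm"].to_numpy(dtype=float)
    elif scale == "log2_rpkm":
        with np.errstate(divide="ignore"):
            v = np.log2(out["rpkm"].to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    label = np.where(v < closed_max, "closed", np.where(v > open_min, "open", "indeterminate"))
    out["label"] = label
    return out


def tss_metaprofile(
    reads: ReadSet,
    genes: GeneSet,
    models: GeneModelSet,
    flank: int = 2000,
    binsize: int = 50,
) -> pd.DataFrame:
    """Mean read-start density around TSSs, strand-oriented.

    Bins run from ``-flank`` to ``+flank``; minus-strand genes are flipped
    so positive offsets point downstream of transcription. Signal is mean
    read starts per gene per bin, scaled per million library reads.
    """
    if not len(genes):
        raise ValidationError("tss_metaprofile requires a non-empty gene set")
    if flank % binsize:
        raise ValueError("flank must be a multiple of binsize")
    n_bins = 2 * flank // binsize
    counts = np.zeros(n_bins, dtype=float)
    by_chrom = {
        chrom: np.sort(sub["start"].to_numpy())
        for chrom, sub in reads.intervals.groupby("chrom", sort=False)
    }
    n_used = 0
    for gid in genes:
        if gid not in models:
            logger.warning("tss_metaprofile: gene %r has no model; skipped", gid)
            continue
        g = models[gid]
        n_used += 1
        starts = by_chrom.get(g.chrom)
        if starts is None:
            continue
        if g.strand == "+":
            lo = np.searchsorted(starts, g.tss - flank, side="left")
            hi = np.searchsorted(starts, g.tss + flank, side="left")
            offsets = starts[lo:hi] - g.tss
        else:  # flip orientation so positive offsets point downstream
            lo = np.searchsorted(starts, g.tss - flank, side="right")
            hi = np.searchsorted(starts, g.tss + flank, side="right")
            offsets = g.tss - starts[lo:hi]
        bins = (offsets + flank) // binsize
        np.add.at(counts, bins.astype(int), 1.0)
    if n_used == 0:
        raise ValidationError("tss_metaprofile: no gene in the set has a model")
    signal = counts / n_used / (reads.library_size / 1e6)
    offsets = np.arange(-flank, flank, binsize)
    return pd.DataFrame({"bin_offset": offsets, "mean_signal": signal})


def relative_accessibility(t: pd.DataFrame, gene: str, housekeeping: GeneSet) -> float:
    """Gene RPKM relative to the geometric mean of housekeeping RPKMs."""
    for hk in housekeeping:
        if hk not in t.index:
            raise ValidationError(f"housekeeping gene {hk!r} absent from table")
        if t.loc[hk, "rpkm"] <= 0:
            raise ValidationError(f"housekeeping gene {hk!r} has zero accessibility")
    if gene not in t.index:
        raise ValidationError(f"gene {gene!r} absent from table")
    hk_vals = np.array([t.loc[hk, "rpkm"] for hk in housekeeping], dtype=float)
    geomean = float(np.exp(np.mean(np.log(hk_vals))))
    return float(t.loc[gene, "rpkm"] / geomean)


def select_tissue_enriched(
    expr: pd.DataFrame,
    target_tissue: str,
    others: Sequence[str],
    min_expr: float = 10.0,
    min_fold: float = 2.0,
    eps: float = 0.1,
) -> GeneSet:
    """Genes enriched in one tissue over the maximum of the others.

    Selected when target expression >= ``min_expr`` and target / (max of
    others + ``eps``) > ``min_fold``. The comparison against the *maximum*
    other tissue is the conservative reading of "enriched versus each".
    """
    if not list(others):
        raise ValidationError("others must name at least one tissue")
    for t in (target_tissue, *others):
        if t not in expr.columns:
            raise ValidationError(f"tissue {t!r} absent from expression table")
    target = expr[target_tissue]
    other_max = expr[list(others)].max(axis=1)
    keep = expr.index[(target >= min_expr) & (target / (other_max + eps) > min_fold)]
    return GeneSet(
        tuple(sorted(keep)),
        provenance=(
            f"select_tissue_enriched(target={target_tissue}, others={list(others)}, "
            f"min_expr={min_expr}, min_fold={min_fold})"
        ),
    )


def _shared_mask(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int) -> np.ndarray:
    """For each interval of ``a``: does any interval of ``b`` overlap it by >= min bp."""
    mask = np.zeros(len(a), dtype=bool)
    b_by_chrom = {chrom: sub for chrom, sub in b.groupby("chrom", sort=False)}
    for chrom, sub in a.groupby("chrom", sort=False):
        bb = b_by_chrom.get(chrom)
        if bb is None:
            continue
        a_s = sub["start"].to_numpy()[:, None]
        a_e = sub["end"].to_numpy()[:, None]
        b_s = bb["start"].to_numpy()[None, :]
        b_e = bb["end"].to_numpy()[None, :]
        overlap = np.minimum(a_e, b_e) - np.maximum(a_s, b_s)
        mask[sub.index.to_numpy()] = (overlap >= min_overlap_bp).any(axis=1)
    return mask


def peak_set_compare(
    a: PeakSet, b: PeakSet, min_overlap_bp: int = 1
) -> dict[str, PeakSet]:
    """Partition two peak sets into shared and unique subsets.

    A peak is *shared* when it overlaps any peak of the other set by at
    least ``min_overlap_bp``; ``unique_a`` + ``shared_a`` partition ``a``
    (likewise for ``b``). The operation is symmetric in its inputs.
    """
    pa = a.peaks.reset_index(drop=True)
    pb = b.peaks.reset_index(drop=True)
    shared_a = _shared_mask(pa, pb, min_overlap_bp)
    shared_b = _shared_mask(pb, pa, min_overlap_bp)
    return {
        "unique_a": PeakSet(pa[~shared_a].reset_index(drop=True)),
        "shared_a": PeakSet(pa[shared_a].reset_index(drop=True)),
        "unique_b": PeakSet(pb[~shared_b].reset_index(drop=True)),
        "shared_b": PeakSet(pb[shared_b].reset_index(drop=True)),
    }


def annotate_peaks_to_genes(
    p: PeakSet, models: GeneModelSet, max_dist: int = 2000
) -> pd.DataFrame:
    """Assign each peak to every gene whose TSS is within ``max_dist`` of it.

    Distance is 0 when the TSS falls inside the peak interval, otherwise the
    gap between the TSS and the nearer peak edge.
    """
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in models:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    rows = []
    peaks = p.peaks.reset_index(drop=True)
    for i, peak in peaks.iterrows():
        for tss, gid in tss_by_chrom.get(peak["chrom"], []):
            dist = max(0, peak["start"] - tss, tss - peak["end"])
            if dist <= max_dist:
                rows.append(
                    {"peak_index": i, "chrom": peak["chrom"],
                     "peak_start": int(peak["start"]), "peak_end": int(peak["end"]),
                     "gene_id": gid, "distance": int(dist)}
                )
    return pd.DataFrame(rows, columns=["peak_index", "chrom", "peak_start",
                                       "peak_end", "gene_id", "distance"])


# ---------------------------------------------------------------------------
# I/O


def read_reads_bed(path: str | Path, library_size: int | None = None) -> ReadSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return ReadSet(df, library_size=library_size)


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    reads.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_reads_sam(path: str | Path, library_size: int | None = None) -> ReadSet:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            rows.append((aln.reference_name, aln.reference_start, aln.reference_end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return ReadSet(df, library_size=library_size)


def read_peaks(path: str | Path) -> PeakSet:
    """Read BED3+/narrowPeak; extra narrowPeak columns are preserved."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], len(NARROWPEAK_COLUMNS))
    df = df.iloc[:, :ncol]
    df.columns = NARROWPEAK_COLUMNS[:ncol]
    df["chrom"] = df["chrom"].astype(str)
    return PeakSet(df)


def write_peaks(p: PeakSet, path: str | Path) -> None:
    p.peaks.to_csv(path, sep="\t", header=False, index=False)
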