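"""Expression matrix, annotation and gene-model I/O.

All coordinate and normalization conventions for the package live here:

* internal genomic coordinates are 0-based half-open everywhere; GTF
  (1-based inclusive) is converted at the boundary,
* per-cell normalization is counts-per-million (CPM) with natural-log
  ``ln(1 + CPM)`` as the positivity scale and ``log2(1 + CPM)`` for display,
* the transcription start site of a gene is its start on ``+`` and its end
  on ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "CountMatrix",
    "NormalizedMatrix",
    "GeneModel",
    "GeneModelSet",
    "read_count_matrix",
    "write_count_matrix",
    "to_cpm",
    "to_log1p_cpm",
    "to_log2_cpm",
    "as_cpm",
    "read_gene_models",
    "write_gene_models",
    "read_cell_annotations",
    "write_cell_annotations",
    "merge_intervals",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer cell x gene count matrix with unique axis labels.

    ``counts`` is stored dense (``int64``); sparse input is densified at
    construction, which is adequate for the matrix sizes this package
    targets while keeping every downstream operation simple.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if scipy.sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix shape {self.counts.shape} does not match labels "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=0, rtol=0):
                bad = np.argwhere(self.counts != rounded)[0]
                raise ValidationError(
                    f"non-integer count at cell {self.cell_ids[bad[0]]!r}, "
                    f"gene {self.gene_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at cell {self.cell_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_ids)


#: allowed normalization scale tags
_SCALES = ("cpm", "log1p_cpm", "log2_cpm")


@dataclass
class NormalizedMatrix:
    """Normalized cell x gene matrix carrying an explicit scale tag."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale: str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("values shape does not match labels")
        if (self.values < 0).any():
            raise ValidationError("normalized values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def read_count_matrix(
    path: str | Path,
    layout: str = "dense_tsv",
    cells_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix.

    Parameters
    ----------
    path:
        For ``layout="dense_tsv"``: a TSV with cells as rows (first column
        = cell id) and genes as columns. For ``layout="mtx_triplet"``: a
        MatrixMarket coordinate file with genes as rows and cells as
        columns (the common single-cell convention), accompanied by one
        gene id per line and one cell id per line label files.
    cells_path, genes_path:
        Label files for the triplet layout; default to ``cells.txt`` /
        ``genes.txt`` next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            cell_ids=[str(c) for c in df.index],
            gene_ids=[str(g) for g in df.columns],
            counts=df.to_numpy(),
        )
    if layout == "mtx_triplet":
        cells_path = Path(cells_path) if cells_path else path.parent / "cells.txt"
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.txt"
        for p in (cells_path, genes_path):
            if not p.exists():
                raise FileNotFoundError(f"label file missing for mtx_triplet layout: {p}")
        cells = cells_path.read_text().split()
        genes = genes_path.read_text().split()
        mat = scipy.io.mmread(str(path))  # genes x cells
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match label files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return CountMatrix(cell_ids=cells, gene_ids=genes, counts=mat.T.tocsr())
    raise ValueError(f"unknown layout {layout!r}")


def write_count_matrix(m: CountMatrix, path: str | Path, layout: str = "dense_tsv") -> None:
    """Write ``m`` in one of the dialects :func:`read_count_matrix` accepts."""
    path = Path(path)
    if layout == "dense_tsv":
        df = m.to_frame()
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t")
    elif layout == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.counts.T))
        (path.parent / "cells.txt").write_text("\n".join(m.cell_ids) + "\n")
        (path.parent / "genes.txt").write_text("\n".join(m.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def to_cpm(m: CountMatrix) -> NormalizedMatrix:
    """Scale every cell to one million total counts.

    Cells whose raw total is zero are retained as all-zero rows and recorded
    in the result's ``warnings`` list (they are excluded from downstream
    per-cell statistics by convention, never imputed).
    """
    totals = m.counts.sum(axis=1).astype(float)
    warnings = [
        f"cell {m.cell_ids[i]!r} has zero total counts; left all-zero"
        for i in np.flatnonzero(totals == 0)
    ]
    safe = np.where(totals == 0, 1.0, totals)
    values = m.counts / safe[:, None] * 1e6
    for w in warnings:
        logger.warning(w)
    return NormalizedMatrix(list(m.cell_ids), list(m.gene_ids), values, "cpm", warnings)


def to_log1p_cpm(m: CountMatrix) -> NormalizedMatrix:
    """Natural log of (1 + CPM) — the positivity scale used throughout."""
    cpm = to_cpm(m)
    return NormalizedMatrix(
        cpm.cell_ids, cpm.gene_ids, np.log1p(cpm.values), "log1p_cpm", cpm.warnings
    )


def to_log2_cpm(m: CountMatrix) -> NormalizedMatrix:
    """log2(1 + CPM), the display scale used for scatter comparisons."""
    cpm = to_cpm(m)
    return NormalizedMatrix(
        cpm.cell_ids, cpm.gene_ids, np.log2(1.0 + cpm.values), "log2_cpm", cpm.warnings
    )


def as_cpm(m: NormalizedMatrix) -> np.ndarray:
    """Return the CPM-scale values of a normalized matrix of any scale."""
    if m.scale == "cpm":
        return m.values
    if m.scale == "log1p_cpm":
        return np.expm1(m.values)
    if m.scale == "log2_cpm":
        return np.exp2(m.values) - 1.0
    raise ValidationError(f"unknown scale {m.scale!r}")


# ---------------------------------------------------------------------------
# gene models


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals, returned sorted and non-overlapping.

    Adjacent (touching) intervals are merged as well.
    """
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValidationError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene with merged exon structure, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id!r}: start >= end")
        merged = merge_intervals(self.exons)
        object.__setattr__(self, "exons", merged)
        for s, e in merged:
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon ({s}, {e}) outside gene span "
                    f"({self.start}, {self.end})"
                )

    @property
    def tss(self) -> int:
        """Transcription start site: gene start on '+', gene end on '-'."""
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive merged exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)


class GeneModelSet:
    """Ordered mapping of gene id -> :class:`GeneModel`."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene model: {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> GeneModelSet:
    """Parse a GTF into gene models.

    Only ``gene`` and ``exon`` features are used and only the ``gene_id``
    attribute is required. GTF's 1-based inclusive coordinates are converted
    to 0-based half-open; exons of all transcripts of a gene are unioned.
    Genes that appear only through exon lines get a span equal to their exon
    hull.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = _gtf_attributes(attrs).get("gene_id")
            if not gene_id:
                raise ValidationError(f"{path}:{lineno}: missing gene_id attribute")
            s, e = int(start) - 1, int(end)  # GTF 1-based inclusive -> half-open
            if gene_id not in exons:
                order.append(gene_id)
                exons[gene_id] = []
            if feature == "gene":
                spans[gene_id] = (chrom, strand, s, e)
            else:
                exons[gene_id].append((s, e))
                if gene_id in spans:
                    chrom0, strand0, *_ = spans[gene_id]
                    if (chrom0, strand0) != (chrom, strand):
                        raise ValidationError(
                            f"{path}:{lineno}: exon of {gene_id!r} disagrees with gene line"
                        )
                else:
                    spans.setdefault(f"_exonhull:{gene_id}", (chrom, strand, s, e))
    models = []
    for gid in order:
        exon_list = exons[gid] or None
        if gid in spans:
            chrom, strand, s, e = spans[gid]
        else:
            merged = merge_intervals(exon_list)
            chrom, strand, _, _ = spans[f"_exonhull:{gid}"]
            s, e = merged[0][0], merged[-1][1]
        if exon_list is None:
            exon_list = [(s, e)]  # intronless gene described only by its gene line
        models.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, start=s, end=e,
                      exons=tuple(exon_list))
        )
    return GeneModelSet(models)


def write_gene_models(models: GeneModelSet, path: str | Path, source: str = "ambint") -> None:
    """Write gene models back to GTF (round-trip safe for id/strand/TSS/exons)."""
    with open(path, "w") as fh:
        for g in models:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# cell annotations

_ANNOTATION_COLUMNS = ("cell_id", "cell_type", "tissue")


def read_cell_annotations(path: str | Path) -> pd.DataFrame:
    """Read a cell annotation TSV with columns cell_id, cell_type, tissue."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns: {missing}")
    return validate_cell_annotations(df)


def validate_cell_annotations(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, list(_ANNOTATION_COLUMNS)].copy()
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate cell_id in annotations: {dup.iloc[0]!r}")
    if df["cell_type"].isna().any() or (df["cell_type"].astype(str) == "").any():
        raise ValidationError("empty cell_type in annotations")
    if df["tissue"].isna().any() or (df["tissue"].astype(str) == "").any():
        raise ValidationError("empty tissue in annotations")
    return df.reset_index(drop=True)


def write_cell_annotations(df: pd.DataFrame, path: str | Path) -> None:
    validate_cell_annotations(df).to_csv(path, sep="\t", index=False)


def annotation_groups(
    ann: pd.DataFrame, cell_ids: Sequence[str]
) -> Mapping[str, np.ndarray]:
    """Map cell_type -> boolean mask over ``cell_ids``.

    Cells absent from the annotation table are permitted; their count is
    logged and they belong to no group.
    """
    lookup = dict(zip(ann["cell_id"], ann["cell_type"]))
    unannotated = sum(1 for c in cell_ids if c not in lookup)
    if unannotated:
        logger.info("%d cells in matrix have no annotation; excluded from groups", unannotated)
    groups: dict[str, np.ndarray] = {}
    types = [lookup.get(c) for c in cell_ids]
    for t in sorted({t for t in types if t is not None}):
        groups[t] = np.array([x == t for x in types], dtype=bool)
    return groups
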