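"""Spliced/unspliced read classification and unspliced-fraction statistics.

A read is classified against a gene model as:

* ``unspliced`` — any aligned block overlaps intronic territory by >= 1 bp;
* ``spliced``  — all blocks lie in the exon union and the read is either a
  single fully-exonic block or every inter-block gap exactly matches an
  annotated intron;
* ``ambiguous`` — anything else (e.g. a gap that matches no intron).

Ambiguous reads are excluded from fraction numerators and denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .expr_io import GeneModel, GeneModelSet, ValidationError
from .markers import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ReadAlignment",
    "classify_read_splice_state",
    "count_splice_states",
    "merge_groups",
    "unspliced_fraction",
    "filter_genes_by_unspliced",
    "median_unspliced",
    "read_alignments_bed",
    "write_alignments_bed",
    "read_alignments_sam",
    "write_splice_counts",
    "read_splice_counts",
]

SPLICE_COLUMNS = ("spliced", "unspliced", "ambiguous")


@dataclass(frozen=True)
class ReadAlignment:
    """A junction-split read: sorted, non-overlapping half-open blocks."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    group: str
    strand: str | None = None

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.blocks:
            if s >= e:
                raise ValidationError(f"read {self.read_id!r}: empty block ({s}, {e})")
            if s < prev_end:
                raise ValidationError(f"read {self.read_id!r}: blocks unsorted/overlapping")
            prev_end = e

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_read_splice_state(r: ReadAlignment, g: GeneModel) -> str:
    """Classify one read against one gene model (see module docstring)."""
    if r.chrom != g.chrom or not _overlaps((r.start, r.end), (g.start, g.end)):
        raise ValidationError(
            f"read {r.read_id!r} does not overlap gene {g.gene_id!r}; caller must filter"
        )
    introns = g.introns
    for block in r.blocks:
        for intron in introns:
            if _overlaps(block, intron):
                return "unspliced"
    exons = g.exons
    for block in r.blocks:
        if not any(s <= block[0] and block[1] <= e for s, e in exons):
            return "ambiguous"  # exonic overlap but pokes outside the gene's exon union
    if len(r.blocks) == 1:
        return "spliced"
    intron_set = set(introns)
    for i in range(len(r.blocks) - 1):
        gap = (r.blocks[i][1], r.blocks[i + 1][0])
        if gap not in intron_set:
            return "ambiguous"
    return "spliced"


def _gene_index(models: GeneModelSet):
    """Per-chromosome gene list sorted by start, for overlap queries."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: g.start)
        starts = np.array([g.start for g in genes])
        max_span = max(g.end - g.start for g in genes)
        index[chrom] = (genes, starts, max_span)
    return index


def count_splice_states(
    reads: Iterable[ReadAlignment],
    models: GeneModelSet,
    ann: Mapping[str, str] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tally spliced/unspliced/ambiguous reads per gene per group.

    ``ann`` optionally maps a read's label (e.g. a cell id) to a group; when
    absent, read labels are used as groups directly. Reads overlapping
    several genes are counted once per overlapped gene (tally logged);
    reads with unresolvable labels or no gene overlap are skipped and
    counted in the log.
    """
    label_map: Mapping[str, str] | None
    if isinstance(ann, pd.DataFrame):
        label_map = dict(zip(ann["cell_id"], ann["cell_type"]))
    else:
        label_map = ann
    index = _gene_index(models)
    tallies: dict[tuple[str, str], np.ndarray] = {}
    n_multi = n_skipped_label = n_no_gene = 0
    for r in reads:
        if label_map is not None:
            if r.group not in label_map:
                n_skipped_label += 1
                continue
            group = label_map[r.group]
        else:
            group = r.group
        if r.chrom not in index:
            n_no_gene += 1
            continue
        genes, starts, max_span = index[r.chrom]
        lo = np.searchsorted(starts, r.start - max_span)
        hi = np.searchsorted(starts, r.end, side="right")
        hits = [g for g in genes[lo:hi] if _overlaps((r.start, r.end), (g.start, g.end))]
        if not hits:
            n_no_gene += 1
            continue
        if len(hits) > 1:
            n_multi += 1
        for g in hits:
            state = classify_read_splice_state(r, g)
            key = (g.gene_id, group)
            if key not in tallies:
                tallies[key] = np.zeros(3, dtype=np.int64)
            tallies[key][SPLICE_COLUMNS.index(state)] += 1
    if n_multi:
        logger.info("count_splice_states: %d reads overlapped multiple genes", n_multi)
    if n_skipped_label:
        logger.warning("count_splice_states: %d reads with unknown labels skipped", n_skipped_label)
    if n_no_gene:
        logger.info("count_splice_states: %d reads overlapped no gene", n_no_gene)
    rows = [
        {"gene_id": gene, "group": group,
         "spliced": int(v[0]), "unspliced": int(v[1]), "ambiguous": int(v[2])}
        for (gene, group), v in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "group", *SPLICE_COLUMNS])


def merge_groups(c: pd.DataFrame, groups: Iterable[str], merged_name: str) -> pd.DataFrame:
    """Component-wise sum of splice counts over ``groups`` into one group."""
    groups = set(groups)
    sub = c[c["group"].isin(groups)]
    merged = sub.groupby("gene_id", as_index=False)[list(SPLICE_COLUMNS)].sum()
    merged.insert(1, "group", merged_name)
    rest = c[~c["group"].isin(groups)]
    return pd.concat([rest, merged], ignore_index=True)


def unspliced_fraction(c: pd.DataFrame) -> pd.DataFrame:
    """Per gene per group ``unspliced / (unspliced + spliced)``.

    Ambiguous reads are excluded; a gene/group with zero informative reads
    gets NaN (missing), never 0.
    """
    out = c[["gene_id", "group"]].copy()
    total = c["spliced"] + c["unspliced"]
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, c["unspliced"] / total.replace(0, np.nan), np.nan)
    out["fraction"] = frac
    out["total"] = total
    return out


def filter_genes_by_unspliced(
    fractions: pd.DataFrame, reference_group: str, min_frac: float = 0.01
) -> GeneSet:
    """Genes whose unspliced fraction in ``reference_group`` is strictly above ``min_frac``."""
    sub = fractions[fractions["group"] == reference_group]
    if sub.empty and not fractions.empty:
        raise ValidationError(f"reference group {reference_group!r} absent from fractions")
    keep = sub[sub["fraction"] > min_frac].sort_values("gene_id")
    return GeneSet(
        tuple(keep["gene_id"]),
        provenance=f"filter_genes_by_unspliced(ref={reference_group}, min_frac={min_frac})",
    )


def median_unspliced(fractions: pd.DataFrame, genes: GeneSet, group: str) -> float:
    """Median unspliced fraction of ``genes`` in ``group``; NaNs excluded with a log."""
    sub = fractions[(fractions["group"] == group) & fractions["gene_id"].isin(set(genes))]
    vals = sub["fraction"].to_numpy()
    defined = vals[~np.isnan(vals)]
    n_missing = len(genes) - len(defined)
    if n_missing:
        logger.info("median_unspliced: %d of %d genes missing in group %r",
                    n_missing, len(genes), group)
    if defined.size == 0:
        raise ValidationError(f"no defined unspliced fractions for group {group!r}")
    return float(np.median(defined))


# ---------------------------------------------------------------------------
# I/O


def write_alignments_bed(reads: Iterable[ReadAlignment], path: str | Path) -> None:
    """BED12-style block table: chrom, start, end, read_id, group, strand, blocks."""
    with open(path, "w") as fh:
        for r in reads:
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - r.start) for s, e in r.blocks)
            strand = r.strand or "."
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.group}\t{strand}"
                f"\t{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )


def read_alignments_bed(path: str | Path) -> list[ReadAlignment]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 columns")
            chrom, start, _end, read_id, group, strand = f[:6]
            start = int(start)
            sizes = [int(x) for x in f[7].split(",") if x]
            offsets = [int(x) for x in f[8].split(",") if x]
            blocks = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            reads.append(
                ReadAlignment(
                    read_id=read_id, chrom=chrom, blocks=blocks, group=group,
                    strand=None if strand == "." else strand,
                )
            )
    return reads


def read_alignments_sam(path: str | Path, group_tag: str = "RG") -> list[ReadAlignment]:
    """Read junction-split alignments from SAM/BAM via pysam.

    Aligned blocks come from the CIGAR (N operations split blocks); the
    group label is taken from ``group_tag`` (default read group).
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            blocks: list[tuple[int, int]] = []
            for s, e in aln.get_blocks():  # M/=/X blocks; merge those split by I/D
                if blocks and s <= blocks[-1][1]:
                    blocks[-1] = (blocks[-1][0], max(blocks[-1][1], e))
                else:
                    blocks.append((s, e))
            try:
                group = aln.get_tag(group_tag)
            except KeyError:
                group = "unknown"
            reads.append(
                ReadAlignment(
                    read_id=aln.query_name, chrom=aln.reference_name,
                    blocks=tuple(blocks), group=str(group),
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return reads


def write_splice_counts(c: pd.DataFrame, path: str | Path) -> None:
    c.to_csv(path, sep="\t", index=False)


def read_splice_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "group": str})
    missing = [c for c in ("gene_id", "group", *SPLICE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValidationError(f"splice counts file missing columns: {missing}")
    return df
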