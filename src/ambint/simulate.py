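"""Synthetic two-population tissue with known ground truth.

Three modalities are generated under two contrasting scenarios:

* ``contamination`` — target cells receive a stated fraction ``f`` of their
  library from an ambient pool proportional to the mean parenchymal
  profile; their chromatin at parenchymal genes is closed and their
  parenchymal reads are almost entirely mature (spliced).
* ``intrinsic`` — each (target cell, parenchymal gene) pair independently
  activates with burst probability ``p_on``, adding expression for that
  gene only; chromatin at parenchymal genes is open in target cells and
  parenchymal transcripts carry an elevated nascent (unspliced) fraction.

Everything is deterministic given ``(seed, parameters)``; per-stage RNG
streams are derived from the seed with fixed offsets so modalities are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_io import CountMatrix, GeneModel, GeneModelSet
from .velocity import ReadAlignment
from .atac import ReadSet

__all__ = [
    "ScenarioTruth",
    "default_truth",
    "make_gene_ids",
    "simulate_expression",
    "make_toy_gene_models",
    "simulate_splice_reads",
    "simulate_atac_reads",
]

SCENARIOS = ("contamination", "intrinsic", "mixed")

#: stage offsets for deriving independent RNG streams from one seed
_STAGE_EXPR, _STAGE_MODELS, _STAGE_SPLICE, _STAGE_ATAC, _STAGE_TRUTH = range(5)

TOY_CHROM = "chrT"
TOY_GENOME_LENGTH = 10_000_000


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground-truth parameters of one simulated tissue."""

    scenario: str
    seed: int
    contamination_fraction: float = 0.02
    burst_probability: float = 0.08
    #: bursting targets transcribe at a low rate relative to the parenchyma;
    #: keeps planted folds far above the incidental folds of independent
    #: base profiles while remaining comfortably detectable at depth 1e5
    burst_level_scale: float = 0.05
    parenchymal_genes: tuple[str, ...] = ()
    nascent_fractions: dict = field(default_factory=dict)  # population -> rho
    open_genes: tuple[str, ...] = ()
    closed_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if not 0.0 <= self.burst_probability <= 1.0:
            raise ValueError("burst_probability must be in [0, 1]")
        for pop, rho in self.nascent_fractions.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"nascent fraction for {pop!r} must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioTruth":
        d = json.loads(text)
        d["parenchymal_genes"] = tuple(d.get("parenchymal_genes", ()))
        d["open_genes"] = tuple(d.get("open_genes", ()))
        d["closed_genes"] = tuple(d.get("closed_genes", ()))
        return cls(**d)


def make_gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def default_truth(
    scenario: str,
    seed: int,
    n_genes: int = 2000,
    n_parenchymal_genes: int = 15,
    contamination_fraction: float = 0.02,
    burst_probability: float = 0.08,
) -> ScenarioTruth:
    """Build a truth record with a seeded random choice of parenchymal genes.

    Nascent fractions default to 0.054 (target) / 0.024 (parenchyma) for the
    intrinsic scenario — chosen so end-to-end demos resemble familiar
    magnitudes — and to 0.005 (target) for contamination, where carried-over
    transcripts are mature. Parenchymal-gene chromatin in the target
    population is open under intrinsic transcription and closed under
    contamination.
    """
    rng = np.random.default_rng([seed, _STAGE_TRUTH])
    gene_ids = make_gene_ids(n_genes)
    pidx = np.sort(rng.choice(n_genes, size=n_parenchymal_genes, replace=False))
    pgenes = tuple(gene_ids[i] for i in pidx)
    if scenario == "contamination":
        nascent = {"target": 0.005, "parenchyma": 0.024}
        open_genes: tuple[str, ...] = ()
        closed_genes = pgenes
    else:  # intrinsic or mixed
        nascent = {"target": 0.054, "parenchyma": 0.024}
        open_genes = pgenes
        closed_genes = ()
    return ScenarioTruth(
        scenario=scenario,
        seed=seed,
        contamination_fraction=contamination_fraction,
        burst_probability=burst_probability,
        parenchymal_genes=pgenes,
        nascent_fractions=nascent,
        open_genes=open_genes,
        closed_genes=closed_genes,
    )


def _base_profiles(truth: ScenarioTruth, n_genes: int, rng: np.random.Generator):
    """Log-normal base profiles; parenchymal genes elevated 10-100x in the
    parenchyma and absent from the target base profile."""
    gene_ids = make_gene_ids(n_genes)
    pidx = np.array([gene_ids.index(g) for g in truth.parenchymal_genes])
    if pidx.size and pidx.max() >= n_genes:
        raise ValueError("parenchymal gene outside the simulated gene universe")
    base_par = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    lift = rng.uniform(10.0, 100.0, size=pidx.size)
    base_par[pidx] *= lift
    base_tgt = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base_tgt[pidx] = 0.0
    return gene_ids, pidx, base_par, base_tgt


def simulate_expression(
    truth: ScenarioTruth,
    n_parenchyma: int = 200,
    n_target: int = 500,
    n_genes: int = 2000,
    depth: int = 100_000,
) -> tuple[CountMatrix, pd.DataFrame, ScenarioTruth]:
    """Multinomial cell x gene counts for both populations.

    Parenchymal cells sample from the elevated base profile; target cells
    sample from their own profile modified per scenario (ambient admixture
    and/or per-cell gene bursts). Returns (counts, annotations, truth).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([truth.seed, _STAGE_EXPR])
    gene_ids, pidx, base_par, base_tgt = _base_profiles(truth, n_genes, rng)
    p_par = base_par / base_par.sum()
    par_counts = rng.multinomial(depth, p_par, size=n_parenchyma)

    contaminate = truth.scenario in ("contamination", "mixed")
    burst = truth.scenario in ("intrinsic", "mixed")

    profiles = np.tile(base_tgt, (n_target, 1))
    if burst and pidx.size:
        active = rng.random((n_target, pidx.size)) < truth.burst_probability
        level = truth.burst_level_scale * base_par[pidx]
        noise = rng.lognormal(mean=0.0, sigma=0.5, size=(n_target, pidx.size))
        profiles[:, pidx] = np.where(active, level[None, :] * noise, 0.0)
    p_tgt = profiles / profiles.sum(axis=1, keepdims=True)
    if contaminate and truth.contamination_fraction > 0:
        n_ambient = rng.binomial(depth, truth.contamination_fraction, size=n_target)
        own = rng.multinomial(depth - n_ambient, p_tgt)
        ambient = rng.multinomial(n_ambient, p_par[None, :].repeat(n_target, axis=0))
        tgt_counts = own + ambient
    else:
        tgt_counts = rng.multinomial(depth, p_tgt)

    cell_ids = [f"P{i:05d}" for i in range(n_parenchyma)] + [
        f"T{i:05d}" for i in range(n_target)
    ]
    counts = np.vstack([par_counts, tgt_counts])
    ann = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_type": ["parenchyma"] * n_parenchyma + ["target"] * n_target,
            "tissue": "toy",
        }
    )
    return CountMatrix(cell_ids, gene_ids, counts), ann, truth


def make_toy_gene_models(
    gene_ids: list[str],
    seed: int,
    min_exons: int = 2,
    max_exons: int = 4,
    exon_length: tuple[int, int] = (150, 400),
    intron_length: tuple[int, int] = (200, 800),
    spacing: int = 5000,
) -> GeneModelSet:
    """Multi-exon toy genes laid end to end on one chromosome.

    Every gene has at least two exons (so an unspliced state exists) and an
    exon shorter than no read; strands alternate deterministically.
    """
    rng = np.random.default_rng([seed, _STAGE_MODELS])
    models = []
    cursor = 10_000
    for k, gid in enumerate(gene_ids):
        n_exons = int(rng.integers(min_exons, max_exons + 1))
        exons = []
        pos = cursor
        for i in range(n_exons):
            elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += int(rng.integers(intron_length[0], intron_length[1] + 1))
        strand = "+" if k % 2 == 0 else "-"
        models.append(
            GeneModel(gene_id=gid, chrom=TOY_CHROM, strand=strand,
                      start=cursor, end=pos, exons=tuple(exons))
        )
        cursor = pos + spacing
    if cursor > TOY_GENOME_LENGTH:
        raise ValueError("toy gene layout exceeds the toy genome")
    return GeneModelSet(models)


def _mature_read_blocks(g: GeneModel, s: int, length: int) -> tuple[tuple[int, int], ...]:
    """Map a mature-transcript interval [s, s+length) onto genomic blocks."""
    blocks = []
    remaining = length
    offset = s
    for es, ee in g.exons:
        elen = ee - es
        if offset >= elen:
            offset -= elen
            continue
        take = min(remaining, elen - offset)
        blocks.append((es + offset, es + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return tuple(blocks)


def simulate_splice_reads(
    truth: ScenarioTruth,
    gene_ids: list[str] | None = None,
    reads_per_group: int = 20_000,
    read_length: int = 100,
    groups: tuple[str, str] = ("target", "parenchyma"),
) -> tuple[list[ReadAlignment], GeneModelSet, ScenarioTruth]:
    """Reads drawn from mature transcripts or pre-mRNA per population.

    With probability ``rho`` (that population's nascent fraction) a read is
    placed uniformly over the full gene span including introns; otherwise it
    is placed uniformly along the mature transcript, splitting across
    junctions. Genes are sampled uniformly.
    """
    if gene_ids is None:
        gene_ids = list(truth.parenchymal_genes)
    if not gene_ids:
        raise ValueError("no genes to simulate reads for")
    models = make_toy_gene_models(gene_ids, truth.seed)
    rng = np.random.default_rng([truth.seed, _STAGE_SPLICE])
    reads: list[ReadAlignment] = []
    for group in groups:
        rho = truth.nascent_fractions.get(group, 0.0)
        gene_choice = rng.integers(0, len(gene_ids), size=reads_per_group)
        nascent = rng.random(reads_per_group) < rho
        for i in range(reads_per_group):
            g = models[gene_ids[gene_choice[i]]]
            rid = f"{group}_r{i:07d}"
            if nascent[i]:
                s = int(rng.integers(g.start, g.end - read_length + 1))
                blocks: tuple[tuple[int, int], ...] = ((s, s + read_length),)
            else:
                s = int(rng.integers(0, g.mature_length - read_length + 1))
                blocks = _mature_read_blocks(g, s, read_length)
            reads.append(
                ReadAlignment(read_id=rid, chrom=g.chrom, blocks=blocks,
                              group=group, strand=g.strand)
            )
    return reads, models, truth


def simulate_atac_reads(
    truth: ScenarioTruth,
    models: GeneModelSet,
    reads_per_open_gene: int = 500,
    background_reads: int = 20_000,
    library_size: int = 5_000_000,
    tss_scale: float = 150.0,
    read_length: int = 50,
    open_enrichment: float = 1.0,
) -> tuple[ReadSet, ScenarioTruth]:
    """Chromatin reads: uniform background plus Laplace pileups at open TSSs.

    Open genes (per ``truth.open_genes``) each receive
    ``open_enrichment * reads_per_open_gene`` extra reads whose displacement
    from the TSS is double-exponential with scale ``tss_scale``. The declared
    ``library_size`` stands in for a full genome-wide library of which only
    the toy region is materialized.
    """
    rng = np.random.default_rng([truth.seed, _STAGE_ATAC])
    starts = [rng.integers(0, TOY_GENOME_LENGTH - read_length, size=background_reads)]
    n_open_reads = int(round(open_enrichment * reads_per_open_gene))
    for gid in truth.open_genes:
        if gid not in models or n_open_reads == 0:
            continue
        tss = models[gid].tss
        disp = rng.laplace(loc=0.0, scale=tss_scale, size=n_open_reads)
        s = np.clip(
            np.rint(tss + disp - read_length / 2).astype(np.int64),
            0, TOY_GENOME_LENGTH - read_length,
        )
        starts.append(s)
    all_starts = np.concatenate(starts)
    df = pd.DataFrame(
        {"chrom": TOY_CHROM, "start": all_starts, "end": all_starts + read_length}
    )
    return ReadSet(df, library_size=library_size), truth
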