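"""Evidence combination and pipeline orchestration.

Four evidence lines are each scored as consistent with cell-intrinsic
transcription or with ambient contamination:

* ``tau`` — rank correlation between target and source profiles over the
  top expressed genes; low tau (< tau_max) is intrinsic-consistent.
* ``dispersion`` — median number of positive markers among marker-positive
  target cells; a small number (<= k_max) is intrinsic-consistent.
* ``splice`` — unspliced-fraction medians; target >= source is
  intrinsic-consistent (nascent transcription in the target).
* ``chromatin`` — fraction of marker genes with open chromatin in the
  target; >= open_frac_min is intrinsic-consistent.

The verdict is ``intrinsic`` when at least three available lines (including
the tau line) are intrinsic-consistent, ``contamination`` when at least
three are contamination-consistent, ``indeterminate`` with fewer than three
available lines, and ``mixed`` otherwise. The quantitative rule and all
thresholds are this package's codification and fully configurable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import contamination as contam_mod
from . import expr_io
from . import markers as markers_mod
from . import simulate as sim_mod
from . import velocity as velo_mod
from .contamination import MarkerCountDistribution, TauResult

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "EvidenceReport",
    "build_evidence_report",
    "evaluate_scenario",
    "run_pipeline",
    "load_config",
]

DEFAULT_THRESHOLDS: dict[str, float] = {
    "tau_max": 0.3,
    "k_max": 2,
    "open_frac_min": 0.5,
}

VERDICTS = ("intrinsic", "contamination", "mixed", "indeterminate")


@dataclass
class EvidenceReport:
    """Combined verdict with one record per evidence line."""

    lines: dict[str, dict | None]
    verdict: str
    thresholds: dict[str, float]
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=float)


def _decide(lines: Mapping[str, dict | None]) -> str:
    available = [l for l in lines.values() if l is not None]
    if not available:
        raise expr_io.ValidationError("no evidence lines available")
    n_int = sum(1 for l in available if l["intrinsic_consistent"])
    n_con = len(available) - n_int
    tau_line = lines.get("tau")
    if (
        len(available) >= 3
        and n_int >= 3
        and tau_line is not None
        and tau_line["intrinsic_consistent"]
    ):
        return "intrinsic"
    if n_con >= 3:
        return "contamination"
    if len(available) < 3:
        return "indeterminate"
    return "mixed"


def build_evidence_report(
    tau: TauResult | None = None,
    dist: MarkerCountDistribution | None = None,
    splice_medians: Mapping[str, float] | None = None,
    access: pd.DataFrame | None = None,
    thresholds: Mapping[str, float] | None = None,
    target_group: str = "target",
    source_group: str = "parenchyma",
    config: dict | None = None,
    seeds: dict | None = None,
) -> EvidenceReport:
    """Score the available evidence lines and derive a verdict.

    ``splice_medians`` maps group name -> median unspliced fraction for the
    target and source groups; ``access`` is a labelled accessibility table
    already restricted to the marker genes under scrutiny.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    lines: dict[str, dict | None] = {
        "tau": None, "dispersion": None, "splice": None, "chromatin": None,
    }
    if tau is not None:
        lines["tau"] = {
            "tau": tau.tau,
            "n_genes": tau.n_genes,
            "ranking_reference": tau.ranking_reference,
            "threshold": th["tau_max"],
            "intrinsic_consistent": bool(tau.tau < th["tau_max"]),
        }
    if dist is not None:
        median_k = dist.median_positive_among_positive(target_group)
        lines["dispersion"] = {
            "median_markers_among_positive": median_k,
            "frac_ge1": dist.frac_ge1(target_group),
            "threshold": th["k_max"],
            "intrinsic_consistent": bool(
                not np.isnan(median_k) and median_k <= th["k_max"]
            ),
        }
    if splice_medians is not None:
        mt = splice_medians.get(target_group, float("nan"))
        ms = splice_medians.get(source_group, float("nan"))
        if not (np.isnan(mt) or np.isnan(ms)):
            lines["splice"] = {
                "median_target": mt,
                "median_source": ms,
                "intrinsic_consistent": bool(mt >= ms),
            }
    if access is not None and len(access):
        labels = access["label"].astype(str)
        open_frac = float((labels == "open").mean())
        lines["chromatin"] = {
            "n_genes": int(len(access)),
            "open_fraction": open_frac,
            "threshold": th["open_frac_min"],
            "intrinsic_consistent": bool(open_frac >= th["open_frac_min"]),
        }
    verdict = _decide(lines)
    return EvidenceReport(
        lines=lines, verdict=verdict, thresholds=th,
        config=config or {}, seeds=seeds or {},
    )


# ---------------------------------------------------------------------------
# in-memory end-to-end evaluation of one simulated tissue


def evaluate_scenario(
    truth: sim_mod.ScenarioTruth,
    n_parenchyma: int = 200,
    n_target: int = 500,
    n_genes: int = 2000,
    depth: int = 100_000,
    reads_per_group: int = 6000,
    thresholds: Mapping[str, float] | None = None,
    marker_params: Mapping[str, Any] | None = None,
    top_n: int = 300,
    ranking_reference: str = "source",
) -> tuple[EvidenceReport, dict]:
    """Run every stage on one simulated tissue and combine the evidence.

    Returns the report plus a dict of intermediate tables for inspection
    and serialization.
    """
    counts, ann, truth = sim_mod.simulate_expression(
        truth, n_parenchyma=n_parenchyma, n_target=n_target,
        n_genes=n_genes, depth=depth,
    )
    norm = expr_io.to_log1p_cpm(counts)
    mparams = {"min_frac": 0.60, "min_fold": 10.0, "n": 15}
    if marker_params:
        mparams.update(marker_params)
    marker_set = markers_mod.select_parenchymal_markers(
        norm, ann, target_group="parenchyma", **mparams
    )
    groups = expr_io.annotation_groups(ann, counts.cell_ids)
    pooled = {
        name: pd.Series(counts.counts[mask].sum(axis=0), index=counts.gene_ids, dtype=float)
        for name, mask in groups.items()
    }
    tau = contam_mod.contamination_rank_test(
        pooled["target"], pooled["parenchyma"],
        n=top_n, ranking_reference=ranking_reference,
    )
    dist = None
    if len(marker_set):
        pos = contam_mod.positivity_matrix(norm, marker_set)
        dist = contam_mod.marker_count_distribution(pos, ann, ["target", "parenchyma"])

    reads, toy_models, truth = sim_mod.simulate_splice_reads(
        truth, reads_per_group=reads_per_group
    )
    splice_counts = velo_mod.count_splice_states(reads, toy_models)
    fractions = velo_mod.unspliced_fraction(splice_counts)
    detectable = velo_mod.filter_genes_by_unspliced(fractions, "parenchyma")
    splice_medians: dict[str, float] | None = None
    if len(detectable):
        splice_medians = {
            g: velo_mod.median_unspliced(fractions, detectable, g)
            for g in ("target", "parenchyma")
        }

    atac_reads, truth = sim_mod.simulate_atac_reads(truth, toy_models)
    access = atac_mod.classify_accessibility(
        atac_mod.tss_window_rpkm(atac_reads, toy_models)
    )
    marker_access = access.loc[[g for g in marker_set if g in access.index]]

    report = build_evidence_report(
        tau=tau,
        dist=dist,
        splice_medians=splice_medians,
        access=marker_access if len(marker_access) else None,
        thresholds=thresholds,
        seeds={"seed": truth.seed},
        config={"scenario": truth.scenario},
    )
    intermediates = {
        "counts": counts,
        "annotations": ann,
        "markers": marker_set,
        "tau": tau,
        "distribution": dist,
        "splice_counts": splice_counts,
        "fractions": fractions,
        "accessibility": access,
        "truth": truth,
    }
    return report, intermediates


# ---------------------------------------------------------------------------
# config-driven pipeline with file outputs


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise expr_io.ValidationError("config must be a mapping")
    return cfg


def _require(cfg: Mapping, key: str, context: str) -> Any:
    if key not in cfg:
        raise expr_io.ValidationError(f"config missing required key {context}{key!r}")
    return cfg[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> EvidenceReport:
    """Run the full evidence chain from a config mapping, writing all
    intermediates, the JSON report, and a checksum manifest to ``out_dir``.

    Two input modes: a ``scenario`` key triggers simulation of all three
    modalities; otherwise an ``inputs`` section must point at a count
    matrix and annotation table (splice counts and ATAC reads optional —
    missing modalities simply leave their evidence lines empty).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thresholds = config.get("thresholds", {})

    if "scenario" in config:
        sim_cfg = config.get("simulate", {})
        truth = sim_mod.default_truth(
            config["scenario"],
            seed,
            n_genes=int(sim_cfg.get("n_genes", 2000)),
            contamination_fraction=float(sim_cfg.get("contamination_fraction", 0.02)),
            burst_probability=float(sim_cfg.get("burst_probability", 0.08)),
        )
        report, inter = evaluate_scenario(
            truth,
            n_parenchyma=int(sim_cfg.get("n_parenchyma", 200)),
            n_target=int(sim_cfg.get("n_target", 500)),
            n_genes=int(sim_cfg.get("n_genes", 2000)),
            depth=int(sim_cfg.get("depth", 100_000)),
            reads_per_group=int(sim_cfg.get("reads_per_group", 6000)),
            thresholds=thresholds,
            marker_params=config.get("markers"),
        )
        (out / "truth.json").write_text(inter["truth"].to_json() + "\n")
        expr_io.write_count_matrix(inter["counts"], out / "counts.tsv")
        expr_io.write_cell_annotations(inter["annotations"], out / "annotations.tsv")
        markers_mod.write_gene_set(inter["markers"], out / "markers.txt")
        velo_mod.write_splice_counts(inter["splice_counts"], out / "splice_counts.tsv")
        inter["fractions"].to_csv(out / "unspliced_fractions.tsv", sep="\t", index=False)
        inter["accessibility"].to_csv(out / "accessibility.tsv", sep="\t")
        if inter["distribution"] is not None:
            inter["distribution"].to_frame().to_csv(out / "marker_counts.tsv", sep="\t")
        (out / "tau.json").write_text(inter["tau"].to_json() + "\n")
    else:
        inputs = _require(config, "inputs", "")
        counts_path = _require(inputs, "counts", "inputs.")
        ann_path = _require(inputs, "annotations", "inputs.")
        counts = expr_io.read_count_matrix(
            counts_path, layout=inputs.get("counts_layout", "dense_tsv"),
            cells_path=inputs.get("cells"), genes_path=inputs.get("genes"),
        )
        ann = expr_io.read_cell_annotations(ann_path)
        groups_cfg = config.get("groups", {})
        target_group = groups_cfg.get("target", "target")
        source_group = groups_cfg.get("source", "parenchyma")
        norm = expr_io.to_log1p_cpm(counts)
        mparams = {"min_frac": 0.60, "min_fold": 10.0, "n": 15}
        mparams.update(config.get("markers", {}))
        marker_set = markers_mod.select_parenchymal_markers(
            norm, ann, target_group=source_group, **mparams
        )
        markers_mod.write_gene_set(marker_set, out / "markers.txt")
        masks = expr_io.annotation_groups(ann, counts.cell_ids)
        pooled = {
            name: pd.Series(counts.counts[m].sum(axis=0), index=counts.gene_ids, dtype=float)
            for name, m in masks.items()
        }
        ccfg = config.get("contamination", {})
        tau = contam_mod.contamination_rank_test(
            pooled[target_group], pooled[source_group],
            n=int(ccfg.get("top_n", 300)),
            ranking_reference=ccfg.get("ranking_reference", "source"),
        )
        (out / "tau.json").write_text(tau.to_json() + "\n")
        dist = None
        if len(marker_set):
            pos = contam_mod.positivity_matrix(norm, marker_set)
            dist = contam_mod.marker_count_distribution(
                pos, ann, [target_group, source_group]
            )
            dist.to_frame().to_csv(out / "marker_counts.tsv", sep="\t")
        splice_medians = None
        if "splice_counts" in inputs:
            sc = velo_mod.read_splice_counts(inputs["splice_counts"])
            fractions = velo_mod.unspliced_fraction(sc)
            fractions.to_csv(out / "unspliced_fractions.tsv", sep="\t", index=False)
            detectable = velo_mod.filter_genes_by_unspliced(
                fractions, source_group,
                min_frac=float(config.get("velocity", {}).get("min_frac", 0.01)),
            )
            if len(detectable):
                splice_medians = {
                    g: velo_mod.median_unspliced(fractions, detectable, g)
                    for g in (target_group, source_group)
                }
        marker_access = None
        if "atac_reads" in inputs:
            models = expr_io.read_gene_models(_require(inputs, "gene_models", "inputs."))
            reads = atac_mod.read_reads_bed(
                inputs["atac_reads"],
                library_size=inputs.get("atac_library_size"),
            )
            acfg = config.get("atac", {})
            access = atac_mod.classify_accessibility(
                atac_mod.tss_window_rpkm(
                    reads, models, halfwidth=int(acfg.get("halfwidth", 250))
                ),
                closed_max=float(acfg.get("closed_max", 1.5)),
                open_min=float(acfg.get("open_min", 3.0)),
                scale=acfg.get("scale", "rpkm"),
            )
            access.to_csv(out / "accessibility.tsv", sep="\t")
            marker_access = access.loc[[g for g in marker_set if g in access.index]]
        report = build_evidence_report(
            tau=tau, dist=dist, splice_medians=splice_medians,
            access=marker_access,
            thresholds=thresholds,
            target_group=target_group, source_group=source_group,
            seeds={"seed": seed},
            config={"inputs": {k: str(v) for k, v in inputs.items()}},
        )

    (out / "report.json").write_text(report.to_json() + "\n")
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: verdict=%s, outputs in %s", report.verdict, out)
    return report
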