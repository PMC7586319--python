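"""End-to-end orchestration: focus -> score -> cluster -> stratify -> report.

A run executes seven hermetic stages in order -- load, profile, focus,
score, cluster, stratify, report -- writing each stage's outputs as TSV /
JSON under the run directory and recording a manifest (stage, inputs,
output hashes, wall time). Re-running with an identical config and inputs
reproduces identical TSV outputs byte for byte for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import reporting
from .clustering import LatentWardClusterer, refine_majors
from .countstack import CountStack, read_mtx_dir, sparsity_profile, write_tables
from .focusing import MatrixFocuser, total_coverage
from .scoring import ExpressionScorer
from .simulate import SimulationConfig, simulate_stack
from .stratification import GeneStratifier

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("load", "profile", "focus", "score", "cluster", "stratify", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serializable run configuration; unknown keys are hard errors."""

    matrix_dir: str | None = None          # triplet matrix directory, or None to simulate
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    seed: int = 0
    focus_barcodes: bool = True
    spike_factor: float = 2.0
    n_starts: int = 3
    max_grid_points: int = 60
    family: str = "auto"
    rank: int | None = None
    k: int | None = None                   # None -> silhouette selection
    k_range: list = field(default_factory=lambda: list(range(2, 13)))
    alpha: float = 0.05
    ti_method: str = "howe"
    report_genes: int = 3                  # top Profiler genes to draw
    version: str = "0.1.0"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; on stage failure, keep partial outputs and a FAILED marker."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    manifest: list[dict[str, Any]] = []

    state: dict[str, Any] = {}

    def record(stage, outputs, t0):
        manifest.append({
            "stage": stage,
            "outputs": {str(p): _hash_file(Path(p)) for p in outputs},
            "wall_time_s": round(time.time() - t0, 3),
            "status": "PASS",
        })
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    def fail(stage, exc):
        manifest.append({"stage": stage, "status": "FAILED", "error": str(exc)})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    # ---- load ----
    t0 = time.time()
    try:
        if config.matrix_dir:
            stack = read_mtx_dir(config.matrix_dir)
            truth = None
        else:
            sim = SimulationConfig(**{"seed": config.stage_seed("load"), **config.simulate})
            stack, truth = simulate_stack(sim)
            pd.DataFrame({
                "barcode": stack.barcode_ids,
                "class": [truth.barcode_class[i] for i in range(stack.n_barcodes)],
                "cell_type": [truth.cell_type.get(i, -1) for i in range(stack.n_barcodes)],
            }).to_csv(out / "truth_barcodes.tsv", sep="\t", index=False)
        state["stack"] = stack
        (out / "load.json").write_text(json.dumps(
            {"n_genes": stack.n_genes, "n_barcodes": stack.n_barcodes,
             "total_umi": stack.total_umi}))
        record("load", [out / "load.json"], t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("load", exc)

    # ---- profile ----
    t0 = time.time()
    try:
        rep = sparsity_profile(state["stack"])
        paths = write_tables([rep], out)
        record("profile", paths, t0)
    except Exception as exc:  # noqa: BLE001
        fail("profile", exc)

    # ---- focus ----
    t0 = time.time()
    try:
        stack = state["stack"]
        parts = {}
        if config.focus_barcodes:
            bf = MatrixFocuser(axis="barcode", spike_factor=config.spike_factor,
                               n_starts=config.n_starts, max_grid_points=config.max_grid_points,
                               seed=config.stage_seed("focus")).fit(stack)
            parts["barcode"] = bf.partition_
            stack = bf.transform(stack)
        gf = MatrixFocuser(axis="gene", spike_factor=config.spike_factor,
                           n_starts=config.n_starts, max_grid_points=config.max_grid_points,
                           seed=config.stage_seed("focus")).fit(stack)
        parts["gene"] = gf.partition_
        focused = gf.transform(stack)
        state["prefocus"] = stack
        state["focused"] = focused
        paths = []
        for axis, part in parts.items():
            ids = stack.gene_ids if axis == "gene" else state["stack"].barcode_ids
            prof = total_coverage(stack if axis == "gene" else state["stack"], axis)
            df = pd.DataFrame({
                "index": sorted(prof.totals),
                "id": [ids[i] for i in sorted(prof.totals)],
                "total_umi": [prof.totals[i] for i in sorted(prof.totals)],
                "regime": [part.regime_of(i) for i in sorted(prof.totals)],
            })
            p = out / f"focus_{axis}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        record("focus", paths, t0)
    except Exception as exc:  # noqa: BLE001
        fail("focus", exc)

    # ---- score ----
    t0 = time.time()
    try:
        scorer = ExpressionScorer(family=config.family)
        ss = scorer.fit_transform(state["focused"], full_stack=state["prefocus"])
        state["scores"] = ss
        coo = ss.upt.tocoo()
        df = pd.DataFrame({
            "gene": [ss.gene_ids[g] for g in coo.row],
            "barcode": [ss.barcode_ids[c] for c in coo.col],
            "upt": coo.data,
            "btheta": ss.btheta.tocoo().data,
            "log2fc": ss.log2fc.tocoo().data,
        })
        p = out / "scores.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        (out / "score_meta.json").write_text(json.dumps({"family": ss.family}))
        record("score", [p, out / "score_meta.json"], t0)
    except Exception as exc:  # noqa: BLE001
        fail("score", exc)

    # ---- cluster (prospective) ----
    t0 = time.time()
    try:
        clus = LatentWardClusterer(rank=config.rank, k=config.k,
                                   k_range=config.k_range,
                                   seed=config.stage_seed("cluster")).fit(state["scores"])
        state["prospective"] = clus
        df = pd.DataFrame({
            "barcode": state["focused"].barcode_ids,
            "cluster": clus.labels_,
        })
        p = out / "clusters_prospective.tsv"
        df.to_csv(p, sep="\t", index=False)
        record("cluster", [p], t0)
    except Exception as exc:  # noqa: BLE001
        fail("cluster", exc)

    # ---- stratify (ladder + majors + final) ----
    t0 = time.time()
    try:
        ss = state["scores"]
        prospective = {i: int(l) for i, l in enumerate(state["prospective"].labels_)}
        first = GeneStratifier(alpha=config.alpha, ti_method=config.ti_method).fit(ss, prospective)
        order = list(first.strata_.strata.values())
        lstnr = [g for g, s in first.strata_.strata.items()
                 if s in ("LSTNR", "DEG", "DEGREE", "Profiler")]
        if lstnr:
            majors_assign = refine_majors(ss, lstnr, k=config.k, k_range=config.k_range,
                                          rank=config.rank,
                                          seed=config.stage_seed("stratify"))
            majors = majors_assign.labels
        else:
            majors_assign = None
            majors = prospective
        strat = GeneStratifier(alpha=config.alpha, ti_method=config.ti_method).fit(ss, majors)
        profilers = [g for g, s in strat.strata_.strata.items() if s == "Profiler"]
        if profilers:
            final_assign = refine_majors(ss, profilers, k=config.k, k_range=config.k_range,
                                         rank=config.rank,
                                         seed=config.stage_seed("stratify"), stage="final")
        else:
            final_assign = None
        state["stratifier"] = strat
        state["majors"] = majors
        state["final"] = final_assign
        gs = strat.strata_
        df = pd.DataFrame({
            "gene": [ss.gene_ids[g] for g in sorted(gs.strata)],
            "stratum": [gs.strata[g] for g in sorted(gs.strata)],
            "f_stat": [strat.stats_[g].f_stat for g in sorted(gs.strata)],
            "p_anova": [strat.stats_[g].p_anova for g in sorted(gs.strata)],
            "q_anova": [strat.stats_[g].q_anova for g in sorted(gs.strata)],
            "q_unweighted": [strat.stats_[g].q_unweighted for g in sorted(gs.strata)],
            "max_abs_mean": [strat.stats_[g].max_abs_mean for g in sorted(gs.strata)],
        })
        p1 = out / "gene_strata.tsv"
        df.to_csv(p1, sep="\t", index=False, float_format="%.6g")
        rows = [{"barcode": ss.barcode_ids[c], "major": k} for c, k in sorted(majors.items())]
        p2 = out / "cell_majors.tsv"
        pd.DataFrame(rows).to_csv(p2, sep="\t", index=False)
        paths = [p1, p2]
        if final_assign is not None:
            p3 = out / "cells_final.tsv"
            pd.DataFrame([{"barcode": ss.barcode_ids[c], "cluster": k}
                          for c, k in sorted(final_assign.labels.items())
                          ]).to_csv(p3, sep="\t", index=False)
            paths.append(p3)
        record("stratify", paths, t0)
    except Exception as exc:  # noqa: BLE001
        fail("stratify", exc)

    # ---- report ----
    t0 = time.time()
    try:
        ss = state["scores"]
        strat = state["stratifier"]
        gs = strat.strata_
        focus_tsv = pd.read_csv(out / "focus_gene.tsv", sep="\t")
        n_const = int((focus_tsv["regime"] == "constitutive").sum())
        n_rare = int((focus_tsv["regime"] == "rare").sum())
        retained = len(gs.retained_barcodes) / max(state["focused"].n_barcodes, 1)
        spec = reporting.frosty_plot(gs, n_const, n_rare, retained, out / "frosty")
        paths = [spec["json"]]
        if state["final"] is not None and state["final"].layout2d:
            genes_by_q = sorted(
                (g for g, s in gs.strata.items() if s == "Profiler"),
                key=lambda g: strat.stats_[g].q_anova)
            layout = state["final"].layout2d
            majors = {c: k for c, k in state["majors"].items() if c in layout}
            for g in genes_by_q[:config.report_genes]:
                try:
                    t = reporting.topograph(ss, majors, layout, g,
                                            out / f"topograph_{ss.gene_ids[g]}")
                    paths.append(t["json"])
                except ValueError:
                    continue
        record("report", paths, t0)
    except Exception as exc:  # noqa: BLE001
        fail("report", exc)

    return out
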