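"""End-to-end orchestration: simulate -> preprocess -> measures -> statistics.

A run is a pure function of its :class:`RunConfig`; the config is serialized
verbatim into the output directory so any run can be reproduced from its
artifacts alone.  Stages communicate only through the documented on-disk
artifacts (or their in-memory twins), so subsets of stages can be re-run.
"""

from __future__ import annotations

import configparser
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import global_mean_edge_value, pearson_fc
from .containers import CohortManifest, RoiTimeSeriesMatrix, SymmetricEdgeMatrix
from .graph import compute_graph_metrics, threshold_sweep
from .io import (
    load_cohort,
    read_manifest,
    validate_cohort,
    write_edge_matrix,
    write_manifest,
    write_result_table,
    write_timeseries,
)
from .pointprocess import coactivation_matrix, point_events
from .preprocess import bandpass, zscore
from .simulate import (
    GeneratorConfig,
    NetworkBlockSpec,
    PlantedEffect,
    default_block_spec,
    simulate_cohort,
)
from .sliding_window import fc_variability, make_windows, window_size_assessment, windowed_fc
from .stats import edgewise_screen, scalar_anova_table

__all__ = ["RunConfig", "run_pipeline", "STAGES",
           "stage_fc", "stage_swa", "stage_ppa", "stage_graph"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fc", "swa", "ppa", "graph", "stats")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; round-trips through an INI file."""

    out_dir: str = "restfc_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # generator
    n_per_group: tuple[tuple[str, int], ...] = (
        ("HC", 35), ("EMCI", 29), ("LMCI", 30), ("AD", 34)
    )
    n_rois: int = 116
    n_timepoints: int = 140
    tr_seconds: float = 3.0
    passband_hz: tuple[float, float] = (0.01, 0.05)
    n_blocks: int = 8
    r_within: float = 0.5
    r_between: float = 0.25
    planted_effects: tuple[tuple[str, int, int, float], ...] = ()
    # optional extra preprocessing of loaded data
    extra_bandpass: tuple[float, float] | None = None
    bandpass_order: int = 2
    # analysis parameters
    window_tp: int = 30
    window_step_tp: int = 1
    run_window_assessment: bool = False
    ppa_threshold_sigma: float = 1.0
    ppa_mode: str = "point"
    graph_threshold_r: float = 0.3
    run_graph_sweep: bool = False
    alpha: float = 0.05
    family_scope: str = "posthoc_only"
    # external data (skips the simulate stage)
    manifest_path: str | None = None

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_per_group=dict(self.n_per_group),
            n_rois=self.n_rois,
            n_timepoints=self.n_timepoints,
            tr_seconds=self.tr_seconds,
            passband_hz=self.passband_hz,
            seed=self.seed,
        )

    def block_spec(self) -> NetworkBlockSpec:
        return default_block_spec(self.n_rois, self.n_blocks, self.r_within, self.r_between)

    def effects(self) -> tuple[PlantedEffect, ...]:
        return tuple(
            PlantedEffect(g, (i, j), r) for g, i, j, r in self.planted_effects
        )

    # -- INI round-trip -----------------------------------------------------

    def to_file(self, path: str | os.PathLike) -> None:
        cp = configparser.ConfigParser()
        cp["run"] = {
            "out_dir": self.out_dir,
            "seed": str(self.seed),
            "stages": ",".join(self.stages),
            "alpha": str(self.alpha),
            "family_scope": self.family_scope,
            "manifest_path": self.manifest_path or "",
        }
        cp["generator"] = {
            "n_per_group": ",".join(f"{g}={n}" for g, n in self.n_per_group),
            "n_rois": str(self.n_rois),
            "n_timepoints": str(self.n_timepoints),
            "tr_seconds": str(self.tr_seconds),
            "passband_hz": f"{self.passband_hz[0]},{self.passband_hz[1]}",
            "n_blocks": str(self.n_blocks),
            "r_within": str(self.r_within),
            "r_between": str(self.r_between),
            "planted_effects": ";".join(
                f"{g}:{i}:{j}:{r}" for g, i, j, r in self.planted_effects
            ),
        }
        cp["analysis"] = {
            "extra_bandpass": (
                f"{self.extra_bandpass[0]},{self.extra_bandpass[1]}"
                if self.extra_bandpass else ""
            ),
            "bandpass_order": str(self.bandpass_order),
            "window_tp": str(self.window_tp),
            "window_step_tp": str(self.window_step_tp),
            "run_window_assessment": str(self.run_window_assessment),
            "ppa_threshold_sigma": str(self.ppa_threshold_sigma),
            "ppa_mode": self.ppa_mode,
            "graph_threshold_r": str(self.graph_threshold_r),
            "run_graph_sweep": str(self.run_graph_sweep),
        }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        run, gen, ana = cp["run"], cp["generator"], cp["analysis"]
        npg = tuple(
            (kv.split("=")[0], int(kv.split("=")[1]))
            for kv in gen["n_per_group"].split(",") if kv
        )
        effects = tuple(
            (p.split(":")[0], int(p.split(":")[1]), int(p.split(":")[2]),
             float(p.split(":")[3]))
            for p in gen["planted_effects"].split(";") if p
        )
        band = tuple(float(x) for x in gen["passband_hz"].split(","))
        extra = ana["extra_bandpass"]
        return cls(
            out_dir=run["out_dir"],
            seed=int(run["seed"]),
            stages=tuple(s for s in run["stages"].split(",") if s),
            alpha=float(run["alpha"]),
            family_scope=run["family_scope"],
            manifest_path=run["manifest_path"] or None,
            n_per_group=npg,
            n_rois=int(gen["n_rois"]),
            n_timepoints=int(gen["n_timepoints"]),
            tr_seconds=float(gen["tr_seconds"]),
            passband_hz=(band[0], band[1]),
            n_blocks=int(gen["n_blocks"]),
            r_within=float(gen["r_within"]),
            r_between=float(gen["r_between"]),
            planted_effects=effects,
            extra_bandpass=(
                tuple(float(x) for x in extra.split(","))[:2] if extra else None  # type: ignore[arg-type]
            ),
            bandpass_order=int(ana["bandpass_order"]),
            window_tp=int(ana["window_tp"]),
            window_step_tp=int(ana["window_step_tp"]),
            run_window_assessment=ana.getboolean("run_window_assessment"),
            ppa_threshold_sigma=float(ana["ppa_threshold_sigma"]),
            ppa_mode=ana["ppa_mode"],
            graph_threshold_r=float(ana["graph_threshold_r"]),
            run_graph_sweep=ana.getboolean("run_graph_sweep"),
        )


# --------------------------------------------------------------------------
# stage functions (in-memory; the CLI adds the file plumbing)


def stage_fc(cohort: dict[str, RoiTimeSeriesMatrix]) -> dict[str, SymmetricEdgeMatrix]:
    return {sid: pearson_fc(ts) for sid, ts in cohort.items()}


def stage_swa(cohort: dict[str, RoiTimeSeriesMatrix], window_tp: int = 30,
              step_tp: int = 1) -> dict[str, SymmetricEdgeMatrix]:
    out = {}
    for sid, ts in cohort.items():
        spec = make_windows(ts.n_timepoints, window_tp, step_tp)
        out[sid] = fc_variability(windowed_fc(ts, spec))
    return out


def stage_ppa(cohort: dict[str, RoiTimeSeriesMatrix], threshold_sigma: float = 1.0,
              mode: str = "point") -> dict[str, SymmetricEdgeMatrix]:
    out = {}
    for sid, ts in cohort.items():
        raster = point_events(zscore(ts), threshold_sigma, mode)
        out[sid] = coactivation_matrix(raster)
    return out


def stage_graph(fc_mats: dict[str, SymmetricEdgeMatrix], threshold_r: float = 0.3,
                sweep: bool = False) -> pd.DataFrame:
    if sweep:
        return pd.concat(
            [threshold_sweep(m, subject_id=sid) for sid, m in fc_mats.items()],
            ignore_index=True,
        )
    rows = []
    for sid, m in fc_mats.items():
        rec = compute_graph_metrics(m, threshold_r, sid)
        rows.append(vars(rec))
    return pd.DataFrame(rows)


def _write_matrices(mats: dict[str, SymmetricEdgeMatrix], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for sid, m in mats.items():
        write_edge_matrix(m, os.path.join(out_dir, f"{sid}.tsv"))


def run_pipeline(config: RunConfig) -> str:
    """Run the configured stages; returns the output directory.

    Emits per-subject FC / across-window-SD / co-activation matrices, the
    graph-metric table, four edge-wise result tables (static FC before and
    after the per-edge outlier rescreen, window variability, co-activation),
    one scalar graph table, one global-means scalar table, the window
    assessment curve when enabled, the saved config, and a run log.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    config.to_file(os.path.join(out, "run_config.ini"))
    logging.basicConfig(level=logging.INFO)
    logger.info("restfc %s | numpy %s | seed %d", __version__, np.__version__, config.seed)

    # --- data acquisition -------------------------------------------------
    stage = "simulate"
    try:
        if config.manifest_path:
            manifest = read_manifest(config.manifest_path)
            cohort = load_cohort(manifest, os.path.dirname(config.manifest_path),
                                 config.tr_seconds)
        elif "simulate" in config.stages:
            manifest, cohort = simulate_cohort(
                config.generator_config(), config.block_spec(), config.effects()
            )
            ts_dir = os.path.join(out, "timeseries")
            os.makedirs(ts_dir, exist_ok=True)
            for e in manifest.entries:
                write_timeseries(cohort[e.subject_id], os.path.join(ts_dir, e.path))
            write_manifest(manifest, os.path.join(out, "manifest.csv"))
        else:
            raise ValueError("no manifest_path and no simulate stage: nothing to analyse")
        validate_cohort(manifest, cohort).raise_if_failed()
        if config.extra_bandpass is not None:
            low, high = config.extra_bandpass
            cohort = {s: bandpass(ts, low, high, config.bandpass_order)
                      for s, ts in cohort.items()}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    results: dict[str, dict[str, SymmetricEdgeMatrix]] = {}
    per_subject_globals: dict[str, dict[str, float]] = {
        sid: {} for sid in cohort
    }

    def run_stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if "fc" in config.stages or "graph" in config.stages:
        fc_mats = run_stage("fc", lambda: stage_fc(cohort))
        if "fc" in config.stages:
            results["fc"] = fc_mats
            _write_matrices(fc_mats, os.path.join(out, "fc"))
            for sid, m in fc_mats.items():
                per_subject_globals[sid]["global_mean_fc"] = global_mean_edge_value(m)
    if "swa" in config.stages:
        swa_mats = run_stage(
            "swa", lambda: stage_swa(cohort, config.window_tp, config.window_step_tp)
        )
        results["swa"] = swa_mats
        _write_matrices(swa_mats, os.path.join(out, "swa"))
        for sid, m in swa_mats.items():
            per_subject_globals[sid]["global_mean_sd"] = global_mean_edge_value(m)
        if config.run_window_assessment:
            first = next(iter(cohort))
            curve = window_size_assessment(cohort[first])
            write_result_table(curve, os.path.join(out, "window_assessment.tsv"))
    if "ppa" in config.stages:
        ppa_mats = run_stage(
            "ppa", lambda: stage_ppa(cohort, config.ppa_threshold_sigma, config.ppa_mode)
        )
        results["ppa"] = ppa_mats
        _write_matrices(ppa_mats, os.path.join(out, "ppa"))
        for sid, m in ppa_mats.items():
            per_subject_globals[sid]["global_mean_coactivation"] = global_mean_edge_value(m)
    if "graph" in config.stages:
        graph_table = run_stage(
            "graph",
            lambda: stage_graph(fc_mats, config.graph_threshold_r, config.run_graph_sweep),
        )
        write_result_table(graph_table, os.path.join(out, "graph_metrics.tsv"))

    if "stats" in config.stages:
        def stats_stage():
            for metric, mats in results.items():
                policy = "rescreen" if metric == "fc" else "none"
                table = edgewise_screen(mats, manifest, config.alpha,
                                        config.family_scope, outlier_policy=policy)
                write_result_table(table, os.path.join(out, f"{metric}_edges.tsv"))
            if "graph" in config.stages and not config.run_graph_sweep:
                g = graph_table.rename(columns={"char_path_length": "path_length"})
                scalars = g[["subject_id", "path_length", "mean_clustering", "mean_degree"]]
                write_result_table(
                    scalar_anova_table(scalars, manifest, config.alpha),
                    os.path.join(out, "graph_scalars.tsv"),
                )
            if per_subject_globals and any(per_subject_globals.values()):
                gdf = pd.DataFrame(
                    [{"subject_id": sid, **vals} for sid, vals in per_subject_globals.items()]
                )
                if gdf.shape[1] > 1:
                    write_result_table(
                        scalar_anova_table(gdf, manifest, config.alpha),
                        os.path.join(out, "global_scalars.tsv"),
                    )
        run_stage("stats", stats_stage)

    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write(f"restfc {__version__}\nnumpy {np.__version__}\nseed {config.seed}\n"
                 f"stages {','.join(config.stages)}\n")
    return out
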