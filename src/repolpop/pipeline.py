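"""End-to-end study orchestration with resumable, file-backed stages.

A :class:`RunConfig` (YAML-serializable) fully determines a run: sample
conductance sets -> simulate control behavior and extract biomarkers ->
derive calibration ranges (from a synthetic cohort or a provided CSV) ->
calibrate -> run the block grid on the accepted models -> classify
susceptibility -> compute summary statistics.  Every artifact is a CSV/JSON
file in the output directory together with a provenance record (config hash,
seed, package version).  A stage whose output file already exists is skipped,
so deleting only downstream artifacts and re-running reproduces them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import BIOMARKER_NAMES, NoActionPotentialError, compute_biomarkers
from .experiments import (ScenarioMatrix, SimOptions, build_block_grid,
                          run_block_study)
from .ord_model import PacingProtocol, simulate
from .population import (CalibrationRanges, calibrate,
                         compute_experimental_ranges, lhs_sample,
                         load_population, SamplingSpec, scaling_from_row)
from .stats import hs_classifier_cv, mann_whitney_u, partial_correlation_matrix
from .synthetic_data import SyntheticCohortSpec, gen_experimental_biomarkers

__all__ = ["RunConfig", "run_full_study"]


@dataclass
class RunConfig:
    """Serializable configuration of a full study run."""

    out_dir: str = "study_out"
    seed: int = 0
    n_samples: int = 100
    beats_control: int = 500
    beats_scenario: int = 500
    celltype: str = "endo"
    dt: float = 0.005
    cycle_length: float = 1000.0
    # restrict the 96-scenario grid to its first n entries (0 = full grid)
    max_scenarios: int = 0
    # optional file inputs; a provided population skips sampling+calibration
    population_csv: Optional[str] = None
    ranges_csv: Optional[str] = None
    cohort_seed: int = 0
    run_stats: bool = True
    classifier_iterations: int = 10
    workers: int = 1

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def sim_options(self) -> SimOptions:
        return SimOptions(cycle_length=self.cycle_length,
                          beats_control=self.beats_control,
                          beats_scenario=self.beats_scenario,
                          celltype=self.celltype, dt=self.dt)


def _control_biomarkers(models: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Control-conditions biomarkers per model (NaN row on failure/no-AP)."""
    rows = []
    proto = PacingProtocol(cycle_length=cfg.cycle_length,
                           n_beats=cfg.beats_control, record_last=1)
    for _, row in models.iterrows():
        scal = scaling_from_row(row)
        res = simulate(proto, scal, celltype=cfg.celltype, dt=cfg.dt)
        rec = {"model_id": row["model_id"]}
        if res.failed:
            rec.update({b: np.nan for b in BIOMARKER_NAMES})
        else:
            try:
                bm = compute_biomarkers(res.time, res.vm,
                                        res.beat_boundaries[-1])
                rec.update(bm.as_dict())
            except NoActionPotentialError:
                rec.update({b: np.nan for b in BIOMARKER_NAMES})
        rows.append(rec)
    return pd.DataFrame(rows)


def _stage(status: dict, out: Path, name: str, filename: str, build):
    """Run one resumable stage: reuse ``filename`` if present, else call
    ``build`` (which must write the file)."""
    path = out / filename
    if path.exists():
        status["stages"][name] = "cached"
        return path
    build(path)
    status["stages"][name] = "computed"
    return path


def run_full_study(config: RunConfig) -> dict:
    """Execute the pipeline; returns the machine-readable status record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status = {"config_hash": config.config_hash(), "seed": config.seed,
              "version": __version__, "stages": {}, "ok": False}
    config.save_yaml(out / "config.yaml")
    try:
        _run_stages(config, out, status)
        status["ok"] = True
    finally:
        (out / "status.json").write_text(json.dumps(status, indent=2))
    return status


def _run_stages(cfg: RunConfig, out: Path, status: dict) -> None:
    # -- population ---------------------------------------------------------
    if cfg.population_csv:
        models = load_population(cfg.population_csv)
        models.to_csv(out / "population.csv", index=False)
        status["stages"]["sample"] = "provided"
    else:
        def build_pop(path):
            lhs_sample(SamplingSpec(cfg.n_samples, seed=cfg.seed)
                       ).to_csv(path, index=False)
        _stage(status, out, "sample", "population.csv", build_pop)
        models = pd.read_csv(out / "population.csv")

    # -- control biomarkers --------------------------------------------------
    def build_bm(path):
        _control_biomarkers(models, cfg).to_csv(path, index=False)
    _stage(status, out, "biomarkers", "biomarkers.csv", build_bm)
    bm_table = pd.read_csv(out / "biomarkers.csv")

    # -- calibration ---------------------------------------------------------
    if cfg.population_csv:
        # a provided (already calibrated) population skips calibration
        accepted = list(models["model_id"])
        status["stages"]["calibrate"] = "skipped"
        pd.DataFrame({"model_id": accepted}).to_csv(out / "accepted.csv",
                                                    index=False)
    else:
        def build_ranges(path):
            if cfg.ranges_csv:
                CalibrationRanges.load_csv(cfg.ranges_csv).save_csv(path)
            else:
                cohort = gen_experimental_biomarkers(
                    SyntheticCohortSpec(seed=cfg.cohort_seed))
                ranges, _ = compute_experimental_ranges(cohort)
                ranges.save_csv(path)
        _stage(status, out, "ranges", "ranges.csv", build_ranges)
        ranges = CalibrationRanges.load_csv(out / "ranges.csv")

        def build_accepted(path):
            acc = calibrate(bm_table, ranges)
            pd.DataFrame({"model_id": acc}).to_csv(path, index=False)
        _stage(status, out, "calibrate", "accepted.csv", build_accepted)
        accepted = list(pd.read_csv(out / "accepted.csv")["model_id"])

    accepted_models = models[models["model_id"].isin(accepted)]

    # -- block grid ----------------------------------------------------------
    grid = build_block_grid()
    if cfg.max_scenarios:
        grid = grid[:cfg.max_scenarios]

    def build_matrix(path):
        if len(accepted_models) == 0:
            ScenarioMatrix(pd.DataFrame(
                columns=[s.scenario_id for s in grid])).save_csv(path)
            return
        run_block_study(accepted_models, grid,
                        cfg.sim_options()).save_csv(path)
    _stage(status, out, "block_grid", "scenario_matrix.csv", build_matrix)
    matrix = ScenarioMatrix.load_csv(out / "scenario_matrix.csv")

    def build_summary(path):
        matrix.summary().rename_axis("model_id").to_csv(path)
    _stage(status, out, "classify", "summary.csv", build_summary)

    def build_incidence(path):
        inc = {}
        for s in grid:
            col = matrix.outcomes[s.scenario_id]
            ok = (col != "failed").sum()
            inc[s.scenario_id] = {
                "incidence_pct": (100.0 * (col == "abnormal").sum() / ok
                                  if ok else None),
                "n_failed": int((col == "failed").sum())}
        Path(path).write_text(json.dumps(inc, indent=2))
    _stage(status, out, "incidence", "incidence.json", build_incidence)

    # -- statistics ----------------------------------------------------------
    if cfg.run_stats and len(matrix.outcomes):
        def build_stats(path):
            summary = matrix.summary()
            bm = bm_table.set_index("model_id").loc[summary.index]
            labels = (summary["susceptibility"] == "HS").to_numpy()
            rec = {"mann_whitney": {}, "classifier": None}
            if labels.any() and not labels.all():
                for b in BIOMARKER_NAMES:
                    r = mann_whitney_u(bm.loc[labels, b].dropna(),
                                       bm.loc[~labels, b].dropna())
                    rec["mann_whitney"][b] = {"U": r.statistic,
                                              "p": r.p_value}
                X = bm[list(BIOMARKER_NAMES)].to_numpy()
                if np.isfinite(X).all() and labels.sum() >= 10:
                    ev = hs_classifier_cv(X, labels,
                                          iterations=cfg.classifier_iterations,
                                          seed=cfg.seed)
                    rec["classifier"] = {
                        "mean_sensitivity": ev.mean_sensitivity,
                        "iterations": ev.iterations}
            conds = accepted_models[list(
                c for c in accepted_models.columns if c.startswith("g_"))]
            if len(conds) > len(conds.columns) + 2:
                try:
                    pcc = partial_correlation_matrix(conds.to_numpy())
                    rec["conductance_pcc"] = pcc.tolist()
                except ValueError:
                    rec["conductance_pcc"] = None
            Path(path).write_text(json.dumps(rec, indent=2))
        _stage(status, out, "stats", "stats.json", build_stats)
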