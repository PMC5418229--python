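"""Block-scenario grid, population incidence, and perturbation studies.

The central experiment blocks pairs of the four main repolarization-phase
currents (IKr, IKs, IK1, ICaL) at four strengths (25/50/75/90 %): 6 unordered
pairs x 16 strength combinations = 96 scenarios.  Each model is paced to its
control steady state, the block is applied (mirroring drug application onto
an equilibrated cell), the model is re-paced under block, and the final two
beats are screened for repolarization abnormalities.  Per-model abnormality
counts over the grid give the NS / MS / HS susceptibility classes.

Perturbation studies rerun IKr-block titrations under mechanistic presets:
restoring the Na+/K+ pump conductance to baseline, clamping intracellular
Na+ (7 or 20 mM, the latter with K+ held at 145 mM to prevent rundown),
removing the pump's electrogenic contribution to dV/dt, mild hypokalemia
(extracellular K+ 4.0 mM), and rapid pacing (2.5 Hz with a final switch to
1 Hz) to provoke Ca2+ loading.  Presets re-equilibrate with the perturbation
active before the IKr block is added (perturb -> equilibrate -> block ->
equilibrate -> analyze).

Beat counts default to 500 per equilibration stage; scaled-down studies pass
smaller counts through :class:`SimOptions`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import DetectorConfig, detect_abnormality, classify_susceptibility
from .ord_model import (ConductanceScaling, PacingProtocol, PerturbationConfig,
                        OrdState, simulate, pace_to_steady_state)
from .population import CONDUCTANCE_COLUMNS, scaling_from_row

__all__ = [
    "BlockScenario",
    "build_block_grid",
    "SimOptions",
    "ScenarioMatrix",
    "run_block_study",
    "incidence",
    "PerturbationStudySpec",
    "PERTURBATION_PRESETS",
    "run_perturbation_study",
    "run_rate_study",
]

_GRID_CURRENTS = ("ICaL", "IK1", "IKr", "IKs")   # lexicographic
_GRID_STRENGTHS = (0.25, 0.5, 0.75, 0.9)


@dataclass(frozen=True)
class BlockScenario:
    scenario_id: str
    pair: Tuple[str, str]
    fractions: Tuple[float, float]

    @property
    def block(self) -> Dict[str, float]:
        return dict(zip(self.pair, self.fractions))

    def fraction_of(self, current: str) -> float:
        return self.block.get(current, 0.0)


def build_block_grid() -> List[BlockScenario]:
    """The canonical 96-scenario two-current block grid: unordered current
    pairs in lexicographic order, then strength combinations in
    lexicographic order."""
    grid = []
    for pair in itertools.combinations(_GRID_CURRENTS, 2):
        for fracs in itertools.product(_GRID_STRENGTHS, repeat=2):
            sid = "{}{:02.0f}_{}{:02.0f}".format(
                pair[0], fracs[0] * 100, pair[1], fracs[1] * 100)
            grid.append(BlockScenario(sid, pair, fracs))
    return grid


@dataclass(frozen=True)
class SimOptions:
    """Shared simulation settings for population studies."""

    cycle_length: float = 1000.0
    beats_control: int = 500     # control pre-pacing
    beats_scenario: int = 500    # re-equilibration after block/perturbation
    record_last: int = 2
    celltype: str = "endo"
    dt: float = 0.005
    output_dt: float = 1.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)

    def protocol(self, n_beats: int, record_last: Optional[int] = None,
                 **kw) -> PacingProtocol:
        return PacingProtocol(cycle_length=self.cycle_length, n_beats=n_beats,
                              record_last=record_last or self.record_last,
                              output_dt=self.output_dt, **kw)


@dataclass
class ScenarioMatrix:
    """Model x scenario outcome table with per-model susceptibility summary.

    ``outcomes`` is a DataFrame indexed by model_id with one column per
    scenario_id holding "normal" / "abnormal" / "failed".
    """

    outcomes: pd.DataFrame

    @property
    def model_ids(self) -> List:
        return list(self.outcomes.index)

    def abnormal_counts(self) -> pd.Series:
        return (self.outcomes == "abnormal").sum(axis=1)

    def classes(self) -> pd.Series:
        return self.abnormal_counts().map(classify_susceptibility)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"abnormal_count": self.abnormal_counts(),
                             "susceptibility": self.classes()})

    def to_long_frame(self, grid: Optional[Sequence[BlockScenario]] = None
                      ) -> pd.DataFrame:
        """(model_id, scenario_id, pair, strengths, outcome) rows."""
        meta = {s.scenario_id: s for s in (grid or build_block_grid())}
        rows = []
        for mid, row in self.outcomes.iterrows():
            for sid, outcome in row.items():
                s = meta.get(sid)
                rows.append({
                    "model_id": mid, "scenario_id": sid,
                    "pair": "+".join(s.pair) if s else "",
                    "strengths": "/".join(str(f) for f in s.fractions) if s else "",
                    "outcome": outcome})
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.outcomes.rename_axis("model_id").to_csv(path)

    @classmethod
    def load_csv(cls, path) -> "ScenarioMatrix":
        return cls(pd.read_csv(path, index_col="model_id").rename_axis(None))


def _analyze(result, detector: DetectorConfig) -> str:
    if result.failed:
        return "failed"
    report = detect_abnormality(result.time, result.vm,
                                result.beat_boundaries, detector)
    return "abnormal" if report.abnormal else "normal"


def control_steady_states(models: pd.DataFrame,
                          opts: SimOptions,
                          perturbation: Optional[PerturbationConfig] = None,
                          scaling_override: Optional[Mapping[str, float]] = None,
                          ) -> Dict[str, Optional[OrdState]]:
    """Control (no-block) steady state per model; None where pacing failed."""
    states: Dict[str, Optional[OrdState]] = {}
    for _, row in models.iterrows():
        scal = scaling_from_row(row)
        if scaling_override:
            scal = replace(scal, **dict(scaling_override))
        states[row["model_id"]] = pace_to_steady_state(
            scal, perturbation=perturbation, cycle_length=opts.cycle_length,
            n_beats=opts.beats_control, celltype=opts.celltype, dt=opts.dt)
    return states


def run_block_study(models: pd.DataFrame,
                    grid: Optional[Sequence[BlockScenario]] = None,
                    opts: Optional[SimOptions] = None,
                    control_states: Optional[Mapping[str, OrdState]] = None,
                    ) -> ScenarioMatrix:
    """Simulate every (model, scenario) cell of the block grid.

    Each cell restarts from the model's control steady state, re-equilibrates
    under block for ``opts.beats_scenario`` beats and screens the final two
    beats.  Per-cell numerical failures are recorded as "failed" and never
    abort the study; cells are independent, so execution order is
    immaterial.
    """
    grid = list(grid if grid is not None else build_block_grid())
    opts = opts or SimOptions()
    if control_states is None:
        control_states = control_steady_states(models, opts)

    table = {}
    for _, row in models.iterrows():
        mid = row["model_id"]
        scal = scaling_from_row(row)
        st = control_states.get(mid)
        outcomes = {}
        for scen in grid:
            if st is None:
                outcomes[scen.scenario_id] = "failed"
                continue
            res = simulate(opts.protocol(opts.beats_scenario), scal,
                           block=scen.block, initial=st,
                           celltype=opts.celltype, dt=opts.dt)
            outcomes[scen.scenario_id] = _analyze(res, opts.detector)
        table[mid] = outcomes
    out = pd.DataFrame.from_dict(table, orient="index")
    out = out.reindex(columns=[s.scenario_id for s in grid])
    return ScenarioMatrix(out)


def incidence(matrix: ScenarioMatrix,
              scenarios: Optional[Iterable[str]] = None,
              models: Optional[Iterable] = None) -> float:
    """Percentage of (non-failed) models abnormal in at least one of the
    selected scenarios."""
    df = matrix.outcomes
    if scenarios is not None:
        scenarios = list(scenarios)
        if not scenarios:
            raise ValueError("empty scenario subset")
        df = df[scenarios]
    if models is not None:
        models = list(models)
        if not models:
            raise ValueError("empty model subset")
        df = df.loc[models]
    ok = ~(df == "failed").all(axis=1)
    if not ok.any():
        raise ValueError("all models failed in the selected subset")
    abnormal = (df[ok] == "abnormal").any(axis=1)
    return 100.0 * abnormal.sum() / ok.sum()


@dataclass(frozen=True)
class PerturbationStudySpec:
    """A named mechanistic preset plus the IKr-block titration levels."""

    name: str
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    scaling_override: Optional[Mapping[str, float]] = None
    rapid_pacing: bool = False
    block_levels: Tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 0.9)


PERTURBATION_PRESETS: Dict[str, PerturbationStudySpec] = {
    "gnak_restore": PerturbationStudySpec(
        "gnak_restore", scaling_override={"g_nak": 1.0}),
    "nai_7": PerturbationStudySpec(
        "nai_7", PerturbationConfig(nai_clamp=7.0)),
    "nai_20_ki_145": PerturbationStudySpec(
        "nai_20_ki_145", PerturbationConfig(nai_clamp=20.0, ki_clamp=145.0)),
    "inak_nonelectrogenic": PerturbationStudySpec(
        "inak_nonelectrogenic",
        PerturbationConfig(remove_inak_electrogenicity=True)),
    "hypokalemia": PerturbationStudySpec(
        "hypokalemia", PerturbationConfig(k_o=4.0)),
    "rapid_pacing": PerturbationStudySpec("rapid_pacing", rapid_pacing=True),
}


def run_perturbation_study(models: pd.DataFrame,
                           spec,
                           opts: Optional[SimOptions] = None,
                           block_levels: Optional[Sequence[float]] = None,
                           ) -> pd.DataFrame:
    """Incidence of repolarization abnormalities per IKr-block level under a
    mechanistic preset (name or :class:`PerturbationStudySpec`).

    Returns a DataFrame with columns block_level, incidence_pct, n_models,
    n_failed.  The rapid-pacing preset is dispatched to
    :func:`run_rate_study`.
    """
    if isinstance(spec, str):
        spec = PERTURBATION_PRESETS[spec]
    if spec.rapid_pacing:
        inc, _ = run_rate_study(models, opts=opts,
                                block_levels=block_levels or spec.block_levels)
        return inc
    opts = opts or SimOptions()
    levels = tuple(block_levels if block_levels is not None
                   else spec.block_levels)

    states = control_steady_states(models, opts,
                                   perturbation=spec.perturbation,
                                   scaling_override=spec.scaling_override)
    rows = []
    for level in levels:
        outcomes = []
        for _, row in models.iterrows():
            st = states[row["model_id"]]
            if st is None:
                outcomes.append("failed")
                continue
            scal = scaling_from_row(row)
            if spec.scaling_override:
                scal = replace(scal, **dict(spec.scaling_override))
            block = {"IKr": level} if level > 0 else None
            res = simulate(opts.protocol(opts.beats_scenario), scal,
                           block=block, perturbation=spec.perturbation,
                           initial=st, celltype=opts.celltype, dt=opts.dt)
            outcomes.append(_analyze(res, opts.detector))
        outcomes = np.array(outcomes)
        n_ok = int((outcomes != "failed").sum())
        n_abn = int((outcomes == "abnormal").sum())
        rows.append({"block_level": level,
                     "incidence_pct": 100.0 * n_abn / n_ok if n_ok else np.nan,
                     "n_models": len(outcomes),
                     "n_failed": len(outcomes) - n_ok})
    return pd.DataFrame(rows)


def run_rate_study(models: pd.DataFrame,
                   opts: Optional[SimOptions] = None,
                   block_levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 0.9),
                   rapid_cycle_length: float = 400.0,
                   slow_beats: int = 2,
                   ca_loading_threshold: float = 1.5,
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Rapid pacing (2.5 Hz) followed by a switch to 1 Hz for the final
    beats, under an IKr-block titration.

    Returns (incidence table, Ca-loading table).  Ca2+ loading is the ratio
    of the beat-averaged cytosolic Ca2+ of the final rapid beat to that of
    the final beat of an unblocked 1 Hz control run with the same total beat
    count; the loading table reports the per-model ratio at zero block and
    the fraction of models at or above ``ca_loading_threshold``.
    """
    opts = opts or SimOptions()
    n_rapid = opts.beats_scenario
    total_beats = opts.beats_control + n_rapid + slow_beats

    rows = []
    ca_rows = []
    # control 1 Hz runs (one per model, shared across block levels)
    control_ca = {}
    control_states = {}
    for _, row in models.iterrows():
        mid = row["model_id"]
        scal = scaling_from_row(row)
        res = simulate(opts.protocol(total_beats, record_last=1), scal,
                       celltype=opts.celltype, dt=opts.dt)
        control_ca[mid] = np.nan if res.failed else float(
            np.mean(res.concentrations["cai"]))
        # the rapid runs restart from a plain control steady state
        control_states[mid] = pace_to_steady_state(
            scal, cycle_length=opts.cycle_length, n_beats=opts.beats_control,
            celltype=opts.celltype, dt=opts.dt)

    for level in block_levels:
        outcomes = []
        for _, row in models.iterrows():
            mid = row["model_id"]
            st = control_states[mid]
            if st is None:
                outcomes.append("failed")
                continue
            scal = scaling_from_row(row)
            block = {"IKr": level} if level > 0 else None
            proto = PacingProtocol(
                cycle_length=rapid_cycle_length, n_beats=n_rapid,
                record_last=slow_beats + 1, output_dt=opts.output_dt,
                rate_switch=(opts.cycle_length, slow_beats))
            res = simulate(proto, scal, block=block, initial=st,
                           celltype=opts.celltype, dt=opts.dt)
            if res.failed:
                outcomes.append("failed")
                if level == 0.0:
                    ca_rows.append({"model_id": mid, "ca_ratio": np.nan})
                continue
            # analyze only the final slow beats
            slow_starts = res.beat_boundaries[-slow_beats:]
            keep = res.time >= slow_starts[0] - 1e-9
            report = detect_abnormality(res.time[keep], res.vm[keep],
                                        slow_starts, opts.detector)
            outcomes.append("abnormal" if report.abnormal else "normal")
            if level == 0.0:
                # final rapid beat = the one before the rate switch
                rb_lo = res.beat_boundaries[-slow_beats - 1]
                rb_hi = slow_starts[0]
                m = (res.time >= rb_lo - 1e-9) & (res.time < rb_hi)
                rapid_ca = float(np.mean(res.concentrations["cai"][m]))
                ca_rows.append({"model_id": mid,
                                "ca_ratio": rapid_ca / control_ca[mid]})
        outcomes = np.array(outcomes)
        n_ok = int((outcomes != "failed").sum())
        n_abn = int((outcomes == "abnormal").sum())
        rows.append({"block_level": level,
                     "incidence_pct": 100.0 * n_abn / n_ok if n_ok else np.nan,
                     "n_models": len(outcomes),
                     "n_failed": len(outcomes) - n_ok})

    ca_df = pd.DataFrame(ca_rows)
    if len(ca_df):
        frac = float(np.mean(ca_df["ca_ratio"].dropna()
                             >= ca_loading_threshold))
        ca_df.attrs["fraction_loaded"] = frac
    return pd.DataFrame(rows), ca_df
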