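"""Synthetic stand-ins for the experimental inputs of the pipeline.

Three generators, all pure functions of (spec, seed):

* a synthetic microelectrode-study biomarker cohort emulating a 62-recording
  human right-ventricular dataset (APD90 mean 293 +- 66 ms, time-to-peak mean
  6.7 +- 5.4 ms) with three planted outliers: one exceptionally long APD90
  (543 ms) and two long times-to-peak (26 and 38 ms);
* parameterized AP voltage traces with analytically exact APD40/50/90 and an
  optional EAD-like depolarizing bump of known peak gradient, used to
  exercise the biomarker extractor and the abnormality detector;
* fixture model populations with known susceptibility structure (a low-pump /
  high-Ca "HS-like" archetype, a baseline-like "robust" archetype, and a
  low-IKs-but-normal-pump archetype).

Biomarker moments not reported for the real dataset (vm_peak, apd40, apd50,
rmp) default to values consistent with the baseline ORd endocardial model
plus documented spreads; they are stand-ins, not measured moments, and are
configurable.  Draws use truncated normals to avoid unphysiological values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ord_model import ConductanceScaling
from .population import CONDUCTANCE_COLUMNS

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticApSpec",
    "SyntheticTrace",
    "gen_experimental_biomarkers",
    "gen_ap_trace",
    "gen_fixture_population",
    "DEFAULT_ARCHETYPES",
]


# (mean, sd, lower bound, upper bound); durations ms, potentials mV.
_DEFAULT_MOMENTS: Dict[str, Tuple[float, float, float, float]] = {
    "apd90": (293.0, 66.0, 150.0, 460.0),
    "vm_time": (6.7, 5.4, 1.0, 20.0),
    "vm_peak": (33.0, 3.0, 25.0, 42.0),
    "rmp": (-85.0, 2.5, -92.0, -78.0),
}

# APD40 and APD50 are generated as fractions of the drawn APD90 so that
# apd40 <= apd50 <= apd90 holds row-wise by construction.
_DEFAULT_RATIOS: Dict[str, Tuple[float, float, float, float]] = {
    "apd40": (0.74, 0.05, 0.55, 0.88),
    "apd50": (0.84, 0.03, 0.70, 0.95),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Specification of a synthetic biomarker cohort.

    ``moments`` maps biomarker -> (mean, sd, lo, hi) truncated-normal
    parameters; ``apd_ratios`` maps apd40/apd50 -> fraction-of-APD90
    truncated-normal parameters.  ``outliers`` are appended after sampling
    ``n_recordings - len(outliers)`` regular rows.
    """

    n_recordings: int = 62
    moments: Mapping[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MOMENTS))
    apd_ratios: Mapping[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RATIOS))
    outliers: Sequence[Mapping[str, float]] = (
        {"apd90": 543.0},
        {"vm_time": 26.0},
        {"vm_time": 38.0},
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (mean, sd, lo, hi) in {**dict(self.moments),
                                         **dict(self.apd_ratios)}.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")
            if not lo < hi:
                raise ValueError(f"impossible truncation bounds for {name}")
        if len(self.outliers) > self.n_recordings:
            raise ValueError("more outliers than recordings")


def _trunc_draw(rng, mean, sd, lo, hi, size):
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate draw outside truncation bounds")
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def gen_experimental_biomarkers(spec: Optional[SyntheticCohortSpec] = None
                                ) -> pd.DataFrame:
    """Synthetic biomarker dataset with one row per recording.

    Regular rows are truncated-normal draws; the planted outliers are then
    appended verbatim (missing fields filled with the biomarker means).
    Column layout matches the calibration pipeline: recording_id plus the
    seven biomarkers.
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed)
    n_reg = spec.n_recordings - len(spec.outliers)

    cols = {}
    for name, (mean, sd, lo, hi) in spec.moments.items():
        cols[name] = _trunc_draw(rng, mean, sd, lo, hi, n_reg)
    for name, (mean, sd, lo, hi) in spec.apd_ratios.items():
        cols[name] = cols["apd90"] * _trunc_draw(rng, mean, sd, lo, hi, n_reg)
    # keep apd40 <= apd50 within each row (ratio draws are independent)
    lo_ = np.minimum(cols["apd40"], cols["apd50"])
    hi_ = np.maximum(cols["apd40"], cols["apd50"])
    cols["apd40"], cols["apd50"] = lo_, hi_
    cols["triangulation"] = cols["apd90"] - cols["apd40"]

    df = pd.DataFrame(cols)
    means = {name: m[0] for name, m in spec.moments.items()}
    out_rows = []
    for planted in spec.outliers:
        row = dict(means)
        row.update(planted)
        row.setdefault("apd40", 0.74 * row["apd90"])
        row.setdefault("apd50", 0.84 * row["apd90"])
        row["triangulation"] = row["apd90"] - row["apd40"]
        out_rows.append(row)
    df = pd.concat([df, pd.DataFrame(out_rows)], ignore_index=True)
    df.insert(0, "recording_id", [f"r{i:03d}" for i in range(len(df))])
    order = ["recording_id", "vm_peak", "vm_time", "apd40", "apd50",
             "apd90", "triangulation", "rmp"]
    return df[order]


@dataclass(frozen=True)
class SyntheticApSpec:
    """Parameterized single-beat AP trace with exact APD targets.

    The trace rests at ``rmp``, rises to ``peak`` in one sample at
    ``upstroke_time`` and then repolarizes piecewise-linearly through anchor
    points placed exactly at the 40/50/90 % repolarization levels at the
    target APDs, reaching rest ``tail`` ms after APD90.  The optional EAD
    bump is a Gaussian deflection whose maximum upward gradient is
    amplitude / (width * sqrt(e)).
    """

    rmp: float = -85.0
    peak: float = 35.0
    upstroke_time: float = 50.0
    apd40: float = 200.0
    apd50: float = 230.0
    apd90: float = 290.0
    cycle_length: float = 1000.0
    dt: float = 1.0
    tail: float = 60.0
    noise_sd: float = 0.0
    ead_onset: Optional[float] = None   # ms after upstroke
    ead_amplitude: float = 10.0         # mV
    ead_width: float = 40.0             # ms (Gaussian sigma)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.apd40 <= self.apd50 <= self.apd90:
            raise ValueError("APD targets must be ordered")
        if self.peak <= self.rmp:
            raise ValueError("peak must exceed rmp")
        if self.ead_onset is not None:
            if self.ead_onset - 3.0 * self.ead_width < 20.0:
                raise ValueError("EAD bump overlaps the upstroke window")

    @property
    def ead_peak_gradient(self) -> float:
        """Maximum upward dV/dt contributed by the bump (mV/ms)."""
        return self.ead_amplitude / (self.ead_width * np.sqrt(np.e))


@dataclass
class SyntheticTrace:
    time: np.ndarray
    vm: np.ndarray
    stimulus_onset: float
    spec: SyntheticApSpec

    @property
    def beat_starts(self) -> np.ndarray:
        return np.array([self.stimulus_onset])


def gen_ap_trace(spec: Optional[SyntheticApSpec] = None) -> SyntheticTrace:
    """Build the synthetic AP described by ``spec`` on a uniform grid."""
    spec = spec or SyntheticApSpec()
    t = np.arange(0.0, spec.cycle_length + spec.dt / 2, spec.dt)
    amp = spec.peak - spec.rmp
    t_up = spec.upstroke_time
    # anchors: (time after upstroke, vm); linear in between, so the 40/50/90%
    # levels are crossed exactly at the target APDs.
    anchors_t = np.array([t_up, t_up + spec.apd40, t_up + spec.apd50,
                          t_up + spec.apd90, t_up + spec.apd90 + spec.tail])
    anchors_v = np.array([spec.peak,
                          spec.peak - 0.40 * amp,
                          spec.peak - 0.50 * amp,
                          spec.peak - 0.90 * amp,
                          spec.rmp])
    vm = np.full_like(t, spec.rmp)
    rising = t >= t_up
    vm[rising] = np.interp(t[rising], anchors_t, anchors_v,
                           left=spec.peak, right=spec.rmp)
    if spec.ead_onset is not None:
        center = t_up + spec.ead_onset
        vm = vm + spec.ead_amplitude * np.exp(
            -0.5 * ((t - center) / spec.ead_width) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vm = vm + rng.normal(0.0, spec.noise_sd, size=vm.shape)
    # the nominal stimulus onset sits just before the upstroke, so the
    # sample preceding it is diastolic (as in a recorded paced beat)
    onset = max(t_up - 2.0 * spec.dt, 0.0)
    return SyntheticTrace(time=t, vm=vm, stimulus_onset=onset, spec=spec)


#: archetype conductance profiles with known susceptibility structure
DEFAULT_ARCHETYPES: Dict[str, ConductanceScaling] = {
    # low Na+/K+ pump, high L-type Ca2+: the profile of highly susceptible
    # models (pump below half baseline, ICaL above ~0.78x baseline)
    "hs_like": ConductanceScaling(g_nak=0.2, g_cal=1.2),
    # representative low-pump model used in pump-restoration experiments
    "hs_representative": ConductanceScaling(g_nak=0.1675, g_cal=1.2),
    # baseline-like robust profile; g_na slightly reduced because the
    # unmodified model's AP peak sits just above recorded maxima (most
    # calibrated models have g_na below baseline)
    "robust": ConductanceScaling(g_na=0.8),
    # low repolarization reserve through IKs, but a normal pump: not
    # expected to be highly susceptible
    "low_reserve_ns": ConductanceScaling(g_ks=0.2),
}


def gen_fixture_population(
        archetypes: Optional[Mapping[str, ConductanceScaling]] = None,
        n_per_archetype: int = 1,
        jitter: float = 0.0,
        seed: int = 0,
        clip_range: Tuple[float, float] = (0.0, 2.0)) -> pd.DataFrame:
    """Population table of jittered copies of archetype conductance sets.

    Each copy adds independent N(0, jitter) noise to every scaling factor,
    clipped to ``clip_range``; jitter=0 reproduces the archetypes exactly.
    """
    archetypes = dict(archetypes or DEFAULT_ARCHETYPES)
    rng = np.random.default_rng(seed)
    rows = []
    for name, arch in archetypes.items():
        base = arch.to_array()
        for k in range(n_per_archetype):
            vals = base + rng.normal(0.0, jitter, size=9) if jitter > 0 \
                else base.copy()
            vals = np.clip(vals, *clip_range)
            rows.append({"model_id": f"{name}-{k}",
                         **dict(zip(CONDUCTANCE_COLUMNS, vals))})
    return pd.DataFrame(rows)
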