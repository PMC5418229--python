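"""Action-potential biomarkers and repolarization-abnormality detection.

Seven biomarkers summarise a paced AP: peak membrane potential, time from
stimulus onset to peak, AP duration at 40/50/90 % repolarization, a
triangulation index (APD90 - APD40 by default) and the resting membrane
potential.  APDs are measured from the instant of maximum upstroke velocity,
with repolarization levels taken relative to the peak-to-RMP amplitude and
crossing times refined by linear interpolation between samples.

Abnormality detection follows a voltage-gradient rule: a positive dV/dt
greater than a threshold (default 0.02 mV/ms), occurring more than a delay
(default 100 ms) after a cycle's initial upstroke, marks an
afterdepolarization.  The delay prevents delayed upstrokes and spike-and-dome
morphologies from being misread.  A cycle that ends still depolarized
(end-of-cycle vm above a failure threshold, default -40 mV) is flagged as
repolarization failure, a subtype that counts as abnormal even without a
positive-gradient event because a monotone failure to repolarize produces
none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BIOMARKER_NAMES",
    "BiomarkerSet",
    "DetectorConfig",
    "AbnormalityReport",
    "NoActionPotentialError",
    "compute_biomarkers",
    "detect_abnormality",
    "classify_susceptibility",
]

BIOMARKER_NAMES = ("vm_peak", "vm_time", "apd40", "apd50", "apd90",
                   "triangulation", "rmp")


class NoActionPotentialError(ValueError):
    """The trace contains no action potential (distinct from numeric failure)."""


@dataclass
class BiomarkerSet:
    """The seven AP biomarkers. Durations in ms, potentials in mV.

    ``unrepolarized`` marks a beat whose APD90 crossing never occurred within
    the analyzed cycle; duration biomarkers needing that crossing are NaN.
    """

    vm_peak: float
    vm_time: float
    apd40: float
    apd50: float
    apd90: float
    triangulation: float
    rmp: float
    unrepolarized: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in BIOMARKER_NAMES}

    def is_complete(self) -> bool:
        return all(math.isfinite(getattr(self, k)) for k in BIOMARKER_NAMES)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the afterdepolarization detector."""

    gradient_threshold: float = 0.02   # mV/ms, strict inequality
    upstroke_delay: float = 100.0      # ms after the initial upstroke
    n_cycles: int = 2                  # final cycles analyzed
    failure_vm_threshold: float = -40.0  # mV at end of cycle

    def __post_init__(self) -> None:
        if self.gradient_threshold <= 0:
            raise ValueError("gradient_threshold must be > 0")
        if self.upstroke_delay < 0:
            raise ValueError("upstroke_delay must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class AbnormalityReport:
    abnormal: bool
    subtype: str                     # "none" | "EAD" | "repolarization_failure"
    first_event_time: Optional[float] = None  # ms, absolute trace time

    def __post_init__(self) -> None:
        if (self.subtype == "none") != (not self.abnormal):
            raise ValueError("subtype 'none' iff not abnormal")


def _downward_crossing(time: np.ndarray, vm: np.ndarray, start: int,
                       level: float) -> float:
    """First time after index ``start`` where vm crosses ``level`` downward,
    linearly interpolated; NaN if it never does."""
    v = vm[start:]
    below = np.nonzero(v <= level)[0]
    if below.size == 0:
        return math.nan
    if below[0] == 0:
        return time[start]
    k = below[0]
    i0 = start + k - 1
    v0, v1 = vm[i0], vm[i0 + 1]
    t0, t1 = time[i0], time[i0 + 1]
    if v1 == v0:
        return t1
    return t0 + (v0 - level) / (v0 - v1) * (t1 - t0)


def _max_dvdt_index(time: np.ndarray, vm: np.ndarray, lo: int, hi: int) -> int:
    dvdt = np.gradient(vm, time)
    hi = max(hi, lo + 1)
    return lo + int(np.argmax(dvdt[lo:hi]))


def compute_biomarkers(time: Sequence[float], vm: Sequence[float],
                       stimulus_onset: float,
                       min_amplitude: float = 30.0,
                       triangulation_lower: str = "apd40") -> BiomarkerSet:
    """Extract the seven AP biomarkers from one beat of a voltage trace.

    ``time``/``vm`` must span one full pacing cycle containing the stimulus
    onset.  ``triangulation_lower`` selects the lower APD level of the
    triangulation index ("apd40" default, "apd50" optional).

    Raises :class:`NoActionPotentialError` when the voltage excursion is
    below ``min_amplitude``.  A beat whose 90 % repolarization is never
    reached is returned with ``unrepolarized=True`` and NaN durations.
    """
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if time.shape != vm.shape or time.ndim != 1 or time.size < 4:
        raise ValueError("time and vm must be equal-length 1-D arrays")
    if not np.all(np.isfinite(vm)):
        raise ValueError("non-finite values in trace")
    if triangulation_lower not in ("apd40", "apd50"):
        raise ValueError("triangulation_lower must be 'apd40' or 'apd50'")

    if vm.max() - vm.min() < min_amplitude:
        raise NoActionPotentialError(
            f"voltage excursion {vm.max() - vm.min():.1f} mV "
            f"< {min_amplitude} mV")

    onset_idx = int(np.searchsorted(time, stimulus_onset))
    onset_idx = min(max(onset_idx, 0), time.size - 2)
    # RMP: membrane potential immediately before stimulus onset
    rmp = float(vm[max(onset_idx - 1, 0)])

    peak_idx = onset_idx + int(np.argmax(vm[onset_idx:]))
    vm_peak = float(vm[peak_idx])
    vm_time = float(time[peak_idx] - stimulus_onset)

    # APD reference instant: maximum upstroke velocity between onset and peak
    up_idx = _max_dvdt_index(time, vm, onset_idx, peak_idx + 1)
    t_up = time[up_idx]

    amp = vm_peak - rmp
    apds = {}
    for pct in (40, 50, 90):
        level = vm_peak - (pct / 100.0) * amp
        t_cross = _downward_crossing(time, vm, peak_idx, level)
        apds[pct] = t_cross - t_up if math.isfinite(t_cross) else math.nan

    unrepolarized = not math.isfinite(apds[90])
    lower = apds[40] if triangulation_lower == "apd40" else apds[50]
    tri = apds[90] - lower
    return BiomarkerSet(vm_peak=vm_peak, vm_time=vm_time,
                        apd40=apds[40], apd50=apds[50], apd90=apds[90],
                        triangulation=tri, rmp=rmp,
                        unrepolarized=unrepolarized)


def detect_abnormality(time: Sequence[float], vm: Sequence[float],
                       beat_starts: Sequence[float],
                       config: Optional[DetectorConfig] = None
                       ) -> AbnormalityReport:
    """Scan the final cycles of a uniformly sampled trace for EADs and
    repolarization failure.

    ``beat_starts`` are the stimulus-onset times of the cycles contained in
    the trace; the last ``config.n_cycles`` of them are analyzed.  The
    gradient is a central finite difference on the uniform grid (one-sided at
    the ends); the positive-gradient criterion is a strict inequality.
    """
    cfg = config or DetectorConfig()
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    beat_starts = np.asarray(beat_starts, dtype=float)
    if beat_starts.size < cfg.n_cycles:
        raise ValueError(
            f"need at least {cfg.n_cycles} cycles, got {beat_starts.size}")

    dvdt = np.gradient(vm, time)
    starts = beat_starts[-cfg.n_cycles:]
    edges = list(starts) + [time[-1]]

    abnormal = False
    failure = False
    first_event: Optional[float] = None
    for c in range(cfg.n_cycles):
        lo = int(np.searchsorted(time, edges[c] - 1e-9))
        hi = int(np.searchsorted(time, edges[c + 1] - 1e-9))
        if hi - lo < 3:
            continue
        # initial upstroke of this cycle: max dV/dt within 50 ms of onset
        win_hi = int(np.searchsorted(time, edges[c] + 50.0))
        up_idx = _max_dvdt_index(time, vm, lo, max(win_hi, lo + 2))
        t_up = time[up_idx]

        mask = time[lo:hi] > t_up + cfg.upstroke_delay
        seg = dvdt[lo:hi][mask]
        seg_t = time[lo:hi][mask]
        events = np.nonzero(seg > cfg.gradient_threshold)[0]
        if events.size:
            abnormal = True
            t_ev = float(seg_t[events[0]])
            if first_event is None or t_ev < first_event:
                first_event = t_ev
        if vm[hi - 1] > cfg.failure_vm_threshold:
            failure = True
            abnormal = True

    if not abnormal:
        return AbnormalityReport(False, "none")
    subtype = "repolarization_failure" if failure else "EAD"
    return AbnormalityReport(True, subtype, first_event)


def classify_susceptibility(abnormal_scenario_count: int) -> str:
    """NS / MS / HS susceptibility class from the number of block scenarios
    that produced a repolarization abnormality (0 / 1-9 / >=10)."""
    count = int(abnormal_scenario_count)
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return "NS"
    if count <= 9:
        return "MS"
    return "HS"
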