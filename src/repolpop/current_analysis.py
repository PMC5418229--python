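"""Current contributions during early and late repolarization.

Early repolarization is defined as the window from the AP peak to 40 %
repolarization (APD40), late repolarization as APD40 to APD90.  For each
named current the trapezoidal time-average over the early, late and full
(peak to APD90) windows quantifies its contribution to the repolarizing
current budget.  The ORd sign convention is retained: outward current is
positive, so inward contributors (ICaL, INa) average negative.

Group statistics over a model subset are reported as mean +- SD of the
per-model window means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import compute_biomarkers
from .ord_model import SimulationResult

__all__ = [
    "DEFAULT_CURRENTS",
    "UnrepolarizedBeatError",
    "CurrentContribution",
    "mean_current_contributions",
    "summarize_contributions",
]

DEFAULT_CURRENTS = ("INa", "INaL", "ICaL", "Ito", "IKr", "IKs", "IK1",
                    "INCX", "INaK")


class UnrepolarizedBeatError(ValueError):
    """The beat never reaches 90 % repolarization; the late window is
    undefined."""


@dataclass(frozen=True)
class CurrentContribution:
    current: str
    window: str          # "early" | "late" | "full"
    mean_density: float  # A/F, outward positive


def _window_mean(time: np.ndarray, series: np.ndarray,
                 t0: float, t1: float) -> float:
    """Trapezoidal time-average of ``series`` over [t0, t1] with linear
    interpolation at the window edges."""
    if t1 <= t0:
        raise ValueError("empty averaging window")
    grid = np.concatenate(([t0], time[(time > t0) & (time < t1)], [t1]))
    vals = np.interp(grid, time, series)
    return float(np.trapezoid(vals, grid) / (t1 - t0))


def mean_current_contributions(
        result: SimulationResult,
        beat: int = -1,
        currents: Sequence[str] = DEFAULT_CURRENTS,
) -> List[CurrentContribution]:
    """Early/late/full-window time-averages of each current over one beat.

    The beat's peak, APD40 and APD90 instants are extracted from the
    recorded voltage.  Raises :class:`UnrepolarizedBeatError` when the beat
    does not pass through 90 % repolarization within its cycle.
    """
    if result.failed:
        raise ValueError("cannot analyze a failed simulation")
    sl = result.beat_slice(beat)
    time = result.time[sl]
    vm = result.vm[sl]
    onset = result.beat_boundaries[beat]
    bm = compute_biomarkers(time, vm, onset)
    if bm.unrepolarized:
        raise UnrepolarizedBeatError("beat does not repolarize through APD90")

    t_peak = onset + bm.vm_time
    # APDs are referenced to the max-upstroke instant; recover the absolute
    # crossing times from that same reference
    t_upstroke = onset + _upstroke_offset(time, vm, onset)
    t40 = t_upstroke + bm.apd40
    t90 = t_upstroke + bm.apd90

    out = []
    for name in currents:
        series = result.currents[name][sl]
        out.append(CurrentContribution(
            name, "early", _window_mean(time, series, t_peak, t40)))
        out.append(CurrentContribution(
            name, "late", _window_mean(time, series, t40, t90)))
        out.append(CurrentContribution(
            name, "full", _window_mean(time, series, t_peak, t90)))
    return out


def _upstroke_offset(time: np.ndarray, vm: np.ndarray, onset: float) -> float:
    """Time of maximum upstroke velocity relative to the stimulus onset."""
    lo = int(np.searchsorted(time, onset))
    hi = int(np.searchsorted(time, onset + 50.0))
    dvdt = np.gradient(vm, time)
    k = lo + int(np.argmax(dvdt[lo:max(hi, lo + 2)]))
    return float(time[k] - onset)


def summarize_contributions(per_model: Sequence[Sequence[CurrentContribution]]
                            ) -> pd.DataFrame:
    """Group mean +- SD of per-model window means.

    ``per_model`` holds one contribution list per model.  Returns a frame
    with columns current, window, mean, sd, n.
    """
    rows = [{"current": c.current, "window": c.window, "value": c.mean_density}
            for contribs in per_model for c in contribs]
    df = pd.DataFrame(rows)
    g = df.groupby(["current", "window"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
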