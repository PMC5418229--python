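"""Conductance-set sampling and experimental calibration of model populations.

A population of candidate myocyte models is built by Latin hypercube sampling
(LHS) of the nine conductance scaling factors over a wide range (0-2 times
baseline by default), so that every conductance's range is covered evenly
while all nine co-vary.  Candidates are then filtered ("calibrated") against
per-biomarker acceptance intervals derived from an experimental (or
synthetic) AP-biomarker dataset: a model is accepted only if all seven of its
control-condition biomarkers fall inside the observed [min, max] interval,
bounds inclusive.  Clear outliers are excluded from the experimental dataset
before the ranges are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import BIOMARKER_NAMES
from .ord_model import ConductanceScaling

__all__ = [
    "CONDUCTANCE_COLUMNS",
    "SamplingSpec",
    "OutlierRule",
    "CalibrationRanges",
    "lhs_sample",
    "compute_experimental_ranges",
    "calibrate",
    "scaling_from_row",
    "save_population",
    "load_population",
]

CONDUCTANCE_COLUMNS = ("g_na", "g_nal", "g_cal", "g_to", "g_kr",
                       "g_ks", "g_k1", "g_ncx", "g_nak")


@dataclass(frozen=True)
class SamplingSpec:
    """Latin hypercube sampling specification.

    ``ranges`` maps conductance name -> (low, high); unnamed conductances use
    ``default_range``.  One master seed drives per-dimension child generators
    keyed by dimension index, so extending the set of dimensions does not
    reshuffle existing ones.
    """

    n_samples: int
    default_range: Tuple[float, float] = (0.0, 2.0)
    ranges: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, (lo, hi) in {**{c: self.default_range
                                  for c in CONDUCTANCE_COLUMNS},
                               **dict(self.ranges)}.items():
            if name not in CONDUCTANCE_COLUMNS:
                raise ValueError(f"unknown conductance {name!r}")
            if not (lo >= 0 and hi > lo):
                raise ValueError(f"invalid range for {name}: [{lo}, {hi}]")

    def range_for(self, name: str) -> Tuple[float, float]:
        return tuple(self.ranges.get(name, self.default_range))


def lhs_sample(spec: SamplingSpec) -> pd.DataFrame:
    """Latin hypercube sample of conductance scaling sets.

    For each conductance independently, exactly one sample falls in each of
    ``n_samples`` equal-width strata of its range, at a uniformly jittered
    position within the stratum (not the stratum center).  Reproducible for a
    fixed seed; dimension d uses the child generator seeded by (seed, d).
    """
    n = spec.n_samples
    data = {}
    for d, name in enumerate(CONDUCTANCE_COLUMNS):
        lo, hi = spec.range_for(name)
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, d)))
        perm = rng.permutation(n)
        jitter = rng.random(n)
        data[name] = lo + (perm + jitter) / n * (hi - lo)
    df = pd.DataFrame(data)
    df.insert(0, "model_id", [f"m{i:05d}" for i in range(n)])
    return df


def scaling_from_row(row) -> ConductanceScaling:
    """ConductanceScaling from one population-table row (Series or mapping)."""
    return ConductanceScaling(**{c: float(row[c]) for c in CONDUCTANCE_COLUMNS})


@dataclass(frozen=True)
class OutlierRule:
    """Deterministic per-biomarker exclusion predicate: exclude a recording
    when any listed biomarker exceeds its cutoff.  The default cutoffs target
    exceptionally long APD90 (> 500 ms) and time-to-peak (> 20 ms)."""

    upper_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {"apd90": 500.0, "vm_time": 20.0})

    def excludes(self, row) -> bool:
        return any(row[name] > cut for name, cut in self.upper_cutoffs.items())


@dataclass
class CalibrationRanges:
    """Per-biomarker [min, max] acceptance intervals."""

    intervals: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if not lo <= hi:
                raise ValueError(f"min > max for {name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, lo, hi) for k, (lo, hi) in self.intervals.items()],
            columns=["biomarker", "min", "max"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationRanges":
        return cls({r.biomarker: (float(r.min), float(r.max))
                    for r in df.itertuples()})

    def save_csv(self, path) -> None:
        # repr keeps the float round-trip exact
        self.to_frame().to_csv(path, index=False,
                               float_format=lambda x: repr(float(x)))

    @classmethod
    def load_csv(cls, path) -> "CalibrationRanges":
        return cls.from_frame(pd.read_csv(path,
                                          float_precision="round_trip"))

    def widened(self, factor: float) -> "CalibrationRanges":
        """Ranges symmetrically widened by ``factor`` times their width."""
        out = {}
        for k, (lo, hi) in self.intervals.items():
            w = (hi - lo) * factor
            out[k] = (lo - w, hi + w)
        return CalibrationRanges(out)


def compute_experimental_ranges(
        data: pd.DataFrame,
        rule: Optional[OutlierRule] = None,
        biomarkers: Sequence[str] = BIOMARKER_NAMES,
) -> Tuple[CalibrationRanges, List]:
    """Min/max acceptance intervals over an AP-biomarker dataset after
    deterministic outlier exclusion.

    ``data`` has one row per recording with a ``recording_id`` column plus
    the biomarker columns.  Returns the ranges and the excluded ids.
    """
    rule = rule or OutlierRule()
    excluded = [row["recording_id"] for _, row in data.iterrows()
                if rule.excludes(row)]
    kept = data[~data["recording_id"].isin(excluded)]
    if len(kept) < 2:
        raise ValueError("fewer than 2 recordings survive outlier exclusion")
    intervals = {b: (float(kept[b].min()), float(kept[b].max()))
                 for b in biomarkers}
    return CalibrationRanges(intervals), excluded


def calibrate(biomarker_table: pd.DataFrame,
              ranges: CalibrationRanges) -> List:
    """Model ids whose biomarkers all lie inside the acceptance intervals.

    ``biomarker_table`` has one row per model: ``model_id`` plus biomarker
    columns.  Bounds are inclusive, so a dataset's own extrema self-calibrate.
    Rows with missing (NaN) biomarkers -- failed simulations, no AP, or
    unrepolarized beats -- are rejected.
    """
    accepted = []
    for _, row in biomarker_table.iterrows():
        ok = True
        for name, (lo, hi) in ranges.intervals.items():
            v = row[name]
            if not np.isfinite(v) or not (lo <= v <= hi):
                ok = False
                break
        if ok:
            accepted.append(row["model_id"])
    return accepted


def save_population(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def load_population(path, column_map: Optional[Mapping[str, str]] = None
                    ) -> pd.DataFrame:
    """Load a population table CSV; ``column_map`` renames foreign headers
    (e.g. a published parameter table) onto the package's schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "model_id" not in df.columns:
        df.insert(0, "model_id", [f"m{i:05d}" for i in range(len(df))])
    missing = [c for c in CONDUCTANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population table missing columns: {missing}")
    return df
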