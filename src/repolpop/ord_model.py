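"""O'Hara-Rudy (ORd 2011) human ventricular cardiomyocyte model.

The ORd model describes the electrophysiology of an isolated human ventricular
myocyte as a 41-variable stiff ODE system: membrane potential, intracellular
and subspace Na+/K+/Ca2+ concentrations, sarcoplasmic-reticulum Ca2+ stores,
Hodgkin-Huxley-style gating variables and a CaMKII trapping variable.  This
module wraps the compiled numerical core (:mod:`repolpop._ord_core`) with a
typed interface that supports the operations needed for population-of-models
work:

* scaling the nine maximal conductances/fluxes that dominate the human AP
  (:class:`ConductanceScaling`),
* fractional channel block, including conversion of a drug concentration to a
  block fraction via the Hill equation (:func:`hill_block`),
* mechanistic perturbations: intracellular Na+/K+ clamps, removal of the
  Na+/K+ pump's electrogenic contribution to dV/dt while leaving its ion
  transport intact, and altered extracellular K+ (:class:`PerturbationConfig`),
* pacing protocols with an optional rate switch (:class:`PacingProtocol`).

The default cell subtype is endocardial, matching the right-ventricular
trabecular/papillary preparations that typical human AP recordings come from;
epicardial and mid-myocardial variants are available through ``celltype``.

Numerics: a fixed-step hybrid integrator (forward Euler for membrane potential,
concentrations and CaMK trap; Rush-Larsen exponential updates for all
relaxation variables) at ``dt`` = 0.005 ms, the scheme used by the original
ORd reference implementation.  Output is sampled on a uniform grid (default
1 ms) for biomarker and detector work.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional, Tuple

import numpy as np

from . import _ord_core
from ._ord_core import N_CURRENT, N_STATE, integrate, ord_rhs

__all__ = [
    "STATE_NAMES",
    "GATE_NAMES",
    "CURRENT_NAMES",
    "SCALABLE_CURRENTS",
    "OrdState",
    "ConductanceScaling",
    "BlockSpec",
    "PerturbationConfig",
    "PacingProtocol",
    "SimulationResult",
    "initial_state",
    "derivatives",
    "apply_block",
    "hill_block",
    "simulate",
    "pace_to_steady_state",
]

GATE_NAMES = (
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp", "nca",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp",
)

STATE_NAMES = (
    "vm", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    *GATE_NAMES, "camk_trap",
)

#: currents reported by :func:`derivatives` and recorded by :func:`simulate`
CURRENT_NAMES = (
    "INa", "INaL", "ICaL", "ICaNa", "ICaK", "Ito", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "ICab", "IKb", "IpCa",
    "Jrel", "Jup",
)

#: currents whose maximal conductance/flux can be scaled or blocked
SCALABLE_CURRENTS = ("INa", "INaL", "ICaL", "Ito", "IKr", "IKs", "IK1",
                     "INCX", "INaK")

_CELLTYPES = {"endo": 0, "epi": 1, "mid": 2}

# Published ORd initial conditions (all cell subtypes).
_Y0 = np.zeros(N_STATE)
_Y0[0] = -87.0       # vm
_Y0[1] = 7.0         # nai
_Y0[2] = 7.0         # nass
_Y0[3] = 145.0       # ki
_Y0[4] = 145.0       # kss
_Y0[5] = 1.0e-4      # cai
_Y0[6] = 1.0e-4      # cass
_Y0[7] = 1.2         # cansr
_Y0[8] = 1.2         # cajsr
for _g, _name in enumerate(GATE_NAMES):
    _Y0[9 + _g] = 1.0 if _name in {
        "hf", "hs", "j", "hsp", "jp", "hL", "hLp", "iF", "iS", "iFp", "iSp",
        "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp", "xk1",
    } else 0.0
_Y0.setflags(write=False)


@dataclass
class OrdState:
    """Full ORd state: membrane potential, ion concentrations, gates, CaMK."""

    vm: float
    nai: float
    nass: float
    ki: float
    kss: float
    cai: float
    cass: float
    cansr: float
    cajsr: float
    gating: np.ndarray  # ordered per GATE_NAMES
    camk_trap: float

    def to_vector(self) -> np.ndarray:
        y = np.empty(N_STATE)
        y[0:9] = (self.vm, self.nai, self.nass, self.ki, self.kss,
                  self.cai, self.cass, self.cansr, self.cajsr)
        y[9:40] = self.gating
        y[40] = self.camk_trap
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "OrdState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATE,):
            raise ValueError(f"state vector must have length {N_STATE}")
        return cls(*y[0:9], gating=y[9:40].copy(), camk_trap=float(y[40]))

    def validate(self) -> None:
        y = self.to_vector()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite value in state")
        conc = y[1:9]
        if np.any(conc <= 0):
            raise ValueError("all concentrations must be positive")


def initial_state() -> OrdState:
    """The published ORd resting initial conditions (pre-pacing)."""
    return OrdState.from_vector(_Y0)


@dataclass(frozen=True)
class ConductanceScaling:
    """Dimensionless multipliers on the nine key maximal conductances/fluxes.

    The baseline ORd model is all ones.  Order matches SCALABLE_CURRENTS:
    INa, INaL, ICaL, Ito, IKr, IKs, IK1, INCX, INaK.
    """

    g_na: float = 1.0
    g_nal: float = 1.0
    g_cal: float = 1.0
    g_to: float = 1.0
    g_kr: float = 1.0
    g_ks: float = 1.0
    g_k1: float = 1.0
    g_ncx: float = 1.0
    g_nak: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"{f.name} must be >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([self.g_na, self.g_nal, self.g_cal, self.g_to,
                         self.g_kr, self.g_ks, self.g_k1, self.g_ncx,
                         self.g_nak])

    @classmethod
    def from_array(cls, arr) -> "ConductanceScaling":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError("expected 9 scaling factors")
        return cls(*arr)


#: map blockable current name -> ConductanceScaling field
_BLOCK_FIELD = {
    "INa": "g_na", "INaL": "g_nal", "ICaL": "g_cal", "Ito": "g_to",
    "IKr": "g_kr", "IKs": "g_ks", "IK1": "g_k1", "INCX": "g_ncx",
    "INaK": "g_nak",
}

#: BlockSpec: mapping current name -> block fraction in [0, 1]
BlockSpec = Mapping[str, float]


def _validate_block(block: Optional[BlockSpec]) -> dict:
    if block is None:
        return {}
    out = {}
    for name, frac in block.items():
        if name not in _BLOCK_FIELD:
            raise ValueError(f"unknown current in block spec: {name!r}")
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"block fraction for {name} outside [0,1]: {frac}")
        out[name] = float(frac)
    return out


def apply_block(scaling: ConductanceScaling,
                block: Optional[BlockSpec]) -> ConductanceScaling:
    """Fold fractional channel block into effective conductance multipliers.

    Each blocked current's multiplier becomes ``scaling * (1 - fraction)``.
    """
    blk = _validate_block(block)
    if not blk:
        return scaling
    updates = {_BLOCK_FIELD[name]: getattr(scaling, _BLOCK_FIELD[name]) * (1.0 - frac)
               for name, frac in blk.items()}
    return replace(scaling, **updates)


def hill_block(concentration: float, ic50: float, hill_coefficient: float) -> float:
    """Fractional single-pore channel block from the Hill occupancy formula.

    block = D^h / (D^h + IC50^h), with drug concentration D and IC50 in the
    same units (conventionally uM).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if ic50 <= 0 or hill_coefficient <= 0:
        raise ValueError("ic50 and hill_coefficient must be > 0")
    if concentration == 0.0:
        return 0.0
    dh = concentration ** hill_coefficient
    return dh / (dh + ic50 ** hill_coefficient)


@dataclass(frozen=True)
class PerturbationConfig:
    """Mechanistic perturbations applied to the cell model.

    nai_clamp / ki_clamp hold the respective intracellular (and subspace)
    concentration fixed at the given value (mM).  With
    ``remove_inak_electrogenicity`` the Na+/K+ pump current is removed from
    the membrane-potential derivative only: ion transport by the pump
    continues to affect Na+ and K+ concentrations exactly as before.
    ``k_o`` sets extracellular K+ (mM); 5.4 is normokalemia.
    """

    nai_clamp: Optional[float] = None
    ki_clamp: Optional[float] = None
    remove_inak_electrogenicity: bool = False
    k_o: float = 5.4

    def __post_init__(self) -> None:
        if self.nai_clamp is not None and self.nai_clamp <= 0:
            raise ValueError("nai_clamp must be > 0")
        if self.ki_clamp is not None and self.ki_clamp <= 0:
            raise ValueError("ki_clamp must be > 0")
        if self.k_o <= 0:
            raise ValueError("k_o must be > 0")


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic current-clamp stimulation.

    ``rate_switch`` optionally appends ``(new_cycle_length, n_extra_beats)``
    after the initial ``n_beats``, e.g. rapid pacing followed by two slow
    beats.  ``record_last`` beats (counted from the very end of the beat
    sequence) are recorded on a uniform ``output_dt`` grid.
    """

    cycle_length: float = 1000.0       # ms
    n_beats: int = 500
    stim_amplitude: float = -80.0      # A/F
    stim_duration: float = 0.5         # ms
    record_last: int = 2
    output_dt: float = 1.0             # ms
    rate_switch: Optional[Tuple[float, int]] = None

    def __post_init__(self) -> None:
        if self.cycle_length <= 0 or self.output_dt <= 0:
            raise ValueError("cycle_length and output_dt must be > 0")
        total = self.n_beats + (self.rate_switch[1] if self.rate_switch else 0)
        if not (total >= self.record_last >= 1):
            raise ValueError("need n_beats >= record_last >= 1")
        if self.rate_switch is not None:
            ncl, nb = self.rate_switch
            if ncl <= 0 or nb < 1:
                raise ValueError("invalid rate_switch")

    def beat_starts(self) -> np.ndarray:
        starts = [i * self.cycle_length for i in range(self.n_beats)]
        t = self.n_beats * self.cycle_length
        if self.rate_switch is not None:
            ncl, nb = self.rate_switch
            starts.extend(t + i * ncl for i in range(nb))
            t += nb * ncl
        return np.asarray(starts, dtype=float)

    def total_duration(self) -> float:
        t = self.n_beats * self.cycle_length
        if self.rate_switch is not None:
            ncl, nb = self.rate_switch
            t += nb * ncl
        return t


@dataclass
class SimulationResult:
    """Recorded tail of a pacing simulation on a uniform time grid."""

    time: np.ndarray                    # ms, absolute simulation time
    vm: np.ndarray                      # mV
    currents: dict                      # name -> A/F series
    concentrations: dict                # name -> mM series (nai, ki, cai)
    beat_boundaries: np.ndarray         # stimulus onsets within recorded span
    failed: bool = False
    final_state: Optional[OrdState] = None

    def beat_slice(self, k: int) -> slice:
        """Index slice of the k-th recorded beat (k=-1 for the last)."""
        bounds = list(self.beat_boundaries) + [self.time[-1] + 1e-9]
        if k < 0:
            k += len(self.beat_boundaries)
        lo = np.searchsorted(self.time, bounds[k] - 1e-9)
        hi = np.searchsorted(self.time, bounds[k + 1] - 1e-9)
        return slice(lo, min(hi + 1, len(self.time)))


def _param_vector(scaling: ConductanceScaling, block: Optional[BlockSpec],
                  perturbation: Optional[PerturbationConfig],
                  celltype: str, stim_to_k: bool) -> np.ndarray:
    pert = perturbation or PerturbationConfig()
    eff = apply_block(scaling, block)
    p = np.zeros(17)
    p[0:9] = eff.to_array()
    p[9] = pert.k_o
    p[10] = 1.0 if pert.nai_clamp is not None else 0.0
    p[11] = pert.nai_clamp or 0.0
    p[12] = 1.0 if pert.ki_clamp is not None else 0.0
    p[13] = pert.ki_clamp or 0.0
    p[14] = 1.0 if pert.remove_inak_electrogenicity else 0.0
    p[15] = 1.0 if stim_to_k else 0.0
    try:
        p[16] = _CELLTYPES[celltype]
    except KeyError:
        raise ValueError(f"unknown celltype {celltype!r}") from None
    return p


def derivatives(state: OrdState, scaling: ConductanceScaling,
                block: Optional[BlockSpec] = None,
                perturbation: Optional[PerturbationConfig] = None,
                stimulus: float = 0.0, celltype: str = "endo",
                stim_to_k: bool = True):
    """Evaluate the ORd right-hand side at one state.

    Returns ``(dy, currents)``: the time derivative of every state variable
    (ordered per STATE_NAMES, units per ms) and a dict of instantaneous
    current densities (A/F) plus SR fluxes (mM/ms).
    """
    state.validate()
    y = state.to_vector()
    p = _param_vector(scaling, block, perturbation, celltype, stim_to_k)
    dy = np.empty(N_STATE)
    ginf = np.empty(_ord_core.N_GATE)
    gtau = np.empty(_ord_core.N_GATE)
    cur = np.empty(N_CURRENT)
    ord_rhs(y, p, float(stimulus), dy, ginf, gtau, cur)
    currents = dict(zip(CURRENT_NAMES, cur))
    currents["INCX"] = currents["INaCa_i"] + currents["INaCa_ss"]
    return dy, currents


def _clamped_initial(y: np.ndarray,
                     perturbation: Optional[PerturbationConfig]) -> np.ndarray:
    y = y.copy()
    if perturbation is not None:
        if perturbation.nai_clamp is not None:
            y[1] = y[2] = perturbation.nai_clamp
        if perturbation.ki_clamp is not None:
            y[3] = y[4] = perturbation.ki_clamp
    return y


def simulate(protocol: PacingProtocol,
             scaling: ConductanceScaling = ConductanceScaling(),
             block: Optional[BlockSpec] = None,
             perturbation: Optional[PerturbationConfig] = None,
             initial: Optional[OrdState] = None,
             celltype: str = "endo",
             dt: float = 0.005,
             stim_to_k: bool = True) -> SimulationResult:
    """Pace the model and record the final ``protocol.record_last`` beats.

    Deterministic for fixed inputs.  A numerical failure (non-finite state,
    runaway voltage, non-physical concentration) is reported through
    ``result.failed`` rather than raised, so population sweeps can tally
    failures and continue.
    """
    p = _param_vector(scaling, block, perturbation, celltype, stim_to_k)
    y = _clamped_initial((initial.to_vector() if initial is not None else _Y0),
                         perturbation)
    beat_starts = protocol.beat_starts()
    t_end = protocol.total_duration()
    rec_start = beat_starts[-protocol.record_last]
    n_out = int(round((t_end - rec_start) / protocol.output_dt)) + 1
    out_vm = np.empty(n_out)
    out_cur = np.empty((n_out, N_CURRENT))
    out_conc = np.empty((n_out, 3))

    status = integrate(y, p, beat_starts, t_end, protocol.stim_amplitude,
                       protocol.stim_duration, dt, rec_start,
                       protocol.output_dt, out_vm, out_cur, out_conc)

    time = rec_start + protocol.output_dt * np.arange(n_out)
    currents = {name: out_cur[:, i].copy() for i, name in enumerate(CURRENT_NAMES)}
    currents["INCX"] = currents["INaCa_i"] + currents["INaCa_ss"]
    result = SimulationResult(
        time=time,
        vm=out_vm,
        currents=currents,
        concentrations={"nai": out_conc[:, 0], "ki": out_conc[:, 1],
                        "cai": out_conc[:, 2]},
        beat_boundaries=beat_starts[-protocol.record_last:],
        failed=(status != 0),
        final_state=OrdState.from_vector(y) if status == 0 else None,
    )
    return result


def pace_to_steady_state(scaling: ConductanceScaling = ConductanceScaling(),
                         block: Optional[BlockSpec] = None,
                         perturbation: Optional[PerturbationConfig] = None,
                         initial: Optional[OrdState] = None,
                         cycle_length: float = 1000.0,
                         n_beats: int = 500,
                         celltype: str = "endo",
                         dt: float = 0.005) -> Optional[OrdState]:
    """Pace for ``n_beats`` and return the end state (None on failure)."""
    proto = PacingProtocol(cycle_length=cycle_length, n_beats=n_beats,
                           record_last=1)
    res = simulate(proto, scaling, block, perturbation, initial=initial,
                   celltype=celltype, dt=dt)
    return res.final_state


def scenario_key(scaling: ConductanceScaling,
                 block: Optional[BlockSpec] = None,
                 perturbation: Optional[PerturbationConfig] = None,
                 celltype: str = "endo",
                 extra: Optional[dict] = None) -> str:
    """Stable hash key for steady-state caching."""
    pert = perturbation or PerturbationConfig()
    payload = {
        "scaling": list(scaling.to_array()),
        "block": sorted((_validate_block(block)).items()),
        "pert": [pert.nai_clamp, pert.ki_clamp,
                 pert.remove_inak_electrogenicity, pert.k_o],
        "celltype": celltype,
        "extra": extra or {},
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()
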