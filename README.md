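# repolpop

Population-of-models analysis of repolarization-abnormality susceptibility in
human ventricular cardiomyocytes.

## The problem

Cardiomyocytes that look perfectly normal under control conditions can differ
widely in how close they sit to the edge of repolarization failure. When a
drug or disease reduces a repolarizing current — classically the rapid
delayed-rectifier K⁺ current I_Kr — some cells develop early
afterdepolarizations (EADs) or fail to repolarize altogether, while most do
not. Which ionic profiles are vulnerable, and why?

`repolpop` packages a mechanistic workflow for that question, aimed at
computational cardiac electrophysiologists:

1. **Cell model.** The O'Hara–Rudy (ORd 2011) human ventricular myocyte ODE
   model (endocardial by default), with nine maximal
   conductances/transporter fluxes (G_Na, G_NaL, G_CaL, G_to, G_Kr, G_Ks,
   G_K1, G_NCX, G_NaK) exposed as dimensionless scaling factors.
2. **Population.** Latin hypercube sampling of the nine scalings over 0–2×
   baseline, then calibration: a candidate model is accepted only if all
   seven AP biomarkers (V_m peak, time to peak, APD40/50/90, triangulation,
   RMP) of its 1 Hz control AP fall inside experimentally observed
   min–max ranges (a synthetic 62-recording cohort generator stands in for
   microelectrode data).
3. **Block study.** All 6 unordered pairs of {I_Kr, I_Ks, I_K1, I_CaL} ×
   16 combinations of 25/50/75/90 % block = 96 scenarios per model. The
   final two beats of every simulation are screened by a gradient detector
   (dV/dt > 0.02 mV/ms later than 100 ms after the upstroke ⇒
   afterdepolarization; end-of-cycle V_m > −40 mV ⇒ repolarization failure).
   Models are classed NS / MS / HS (0 / 1–9 / ≥10 abnormal scenarios).
4. **Mechanism experiments.** Current-budget analysis over early
   (peak→APD40) and late (APD40→APD90) repolarization windows; Na⁺/K⁺-pump
   restoration (G_NaK → 1); intracellular Na⁺/K⁺ clamps; removal of the
   pump's electrogenic term from dV/dt while its ion transport continues;
   hypokalemia (K⁺_o 5.4 → 4.0 mM); rapid pacing (2.5 Hz → 1 Hz).
5. **Statistics.** Mann–Whitney U (exact for small samples), partial
   correlations between conductances via precision-matrix normalization,
   Bonferroni thresholds, and a cross-validated logistic-regression
   classifier of the HS class from z-scored biomarkers.

Drug block is described by the Hill occupancy formula
`block = D^h / (D^h + IC50^h)`; e.g. 0.05 µM of a dofetilide-like
single-pore I_Kr inhibitor (IC50 0.03 µM, h = 1.2) gives 65 % block.

## Worked example

```python
from repolpop.ord_model import (ConductanceScaling, PacingProtocol,
                                hill_block, simulate)
from repolpop.biomarkers import compute_biomarkers, detect_abnormality

# dofetilide-like IKr blocker at 0.05 uM
frac = hill_block(0.05, ic50=0.03, hill_coefficient=1.2)
print(f"IKr block fraction: {frac:.3f}")

# a low-pump, high-ICaL myocyte: normal AP in control conditions
scal = ConductanceScaling(g_nak=0.2, g_cal=1.2)
control = simulate(PacingProtocol(n_beats=100, record_last=2), scal)
bm = compute_biomarkers(control.time, control.vm, control.beat_boundaries[-1])
print(f"control APD90: {bm.apd90:.0f} ms, RMP: {bm.rmp:.1f} mV")

for frac_blk in (frac, 0.9):
    blocked = simulate(PacingProtocol(n_beats=100, record_last=2), scal,
                       block={"IKr": frac_blk}, initial=control.final_state)
    rep = detect_abnormality(blocked.time, blocked.vm,
                             blocked.beat_boundaries)
    print(f"under {100 * frac_blk:.0f}% IKr block: "
          f"abnormal={rep.abnormal} ({rep.subtype})")
```

prints

```
IKr block fraction: 0.649
control APD90: 294 ms, RMP: -87.4 mV
under 65% IKr block: abnormal=False (none)
under 90% IKr block: abnormal=True (repolarization_failure)
```

The cell's control AP is unremarkable (APD90 294 ms), 65 % I_Kr block only
prolongs it (APD90 grows to ~500 ms), but at 90 % block the weak Na⁺/K⁺ pump
(G_NaK = 0.2) can no longer cover the lost repolarization reserve and the
cell fails to repolarize. Restoring `g_nak=1.0` and re-equilibrating makes
the same 90 % block benign (see
`tests/test_acceptance.py::test_gnak_restoration_abolishes_abnormality`).

A CLI mirrors the stages: `repolpop sample | synth | block-scan | perturb |
rate-study | run` (see `repolpop --help`); `repolpop run` executes the whole
resumable pipeline from a YAML config.

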