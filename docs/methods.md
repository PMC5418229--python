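# Methods

## Cell model

The cell model is a transcription of the O'Hara–Rudy (ORd 2011) human
ventricular myocyte formulation: 41 state variables (membrane potential;
myoplasmic and subspace Na⁺, K⁺ and Ca²⁺; SR Ca²⁺ stores; Hodgkin–Huxley
gates for I_Na, I_NaL, I_to, I_CaL, I_Kr, I_Ks, I_K1; CaMKII trapping), with
the Markov-free gating structure of the original model. The endocardial
parameterization is the default, because human AP recordings used for
calibration in this kind of study come from right-ventricular
trabecular/papillary preparations; epicardial and mid-myocardial variants
are selected with `celltype`.

Nine maximal conductances/fluxes are exposed as dimensionless scaling
factors (`ConductanceScaling`; baseline = all ones): G_Na, G_NaL, G_CaL,
G_to, G_Kr, G_Ks, G_K1, G_NCX (the Na⁺/Ca²⁺-exchanger flux multiplier) and
G_NaK (the Na⁺/K⁺-pump flux multiplier). Channel block by fraction *b*
multiplies the corresponding scaling by (1 − *b*); a drug concentration is
converted to a fraction via the Hill occupancy formula
`D^h / (D^h + IC50^h)`. With the dofetilide-like parameters IC50 = 0.03 µM
and h = 1.2, a 0.05 µM dose gives 65 % I_Kr block; note that 0.5 µM would
give ≈ 92 % block, so a report of "65 %" pins the concentration to 0.05 µM.

### Perturbation hooks

* **Ion clamps.** `nai_clamp` / `ki_clamp` zero the time-derivatives of the
  myoplasmic *and* subspace Na⁺ (respectively K⁺) pools and pin them to the
  clamp value; everything else evolves normally.
* **Electrogenic decoupling.** `remove_inak_electrogenicity` removes I_NaK
  from the dV/dt sum only. The pump's 3 Na⁺-out / 2 K⁺-in transport still
  enters the concentration derivatives unchanged, isolating the pump's
  direct contribution to repolarizing current from its homeostatic role.
* **Extracellular K⁺.** `k_o` (default 5.4 mM) feeds E_K, I_K1 and I_Kr
  conductance scaling and the pump kinetics; 4.0 mM models mild hypokalemia.

### Numerics

The integrator is a fixed-step hybrid: forward Euler for membrane potential,
concentrations and the CaMK trap, and Rush–Larsen exponential updates for
all 31 relaxation variables, at dt = 0.005 ms — the scheme and step of the
original ORd reference implementation. Output is resampled on a uniform
grid (default 1 ms) for biomarker and detector work. The integrator runs as
compiled (numba) code; two runs with identical inputs are bit-identical. A
simulation is flagged `failed` (never raised) when the state leaves the
physical domain (non-finite values, |V_m| beyond ±150/90 mV, non-positive
concentrations), so population sweeps tally failures and continue.

Transcription checks against published ORd behavior (endocardial, 1 Hz,
reference stimulus −80 A/F × 0.5 ms): maximum upstroke velocity ≈ 257 mV/ms
(published ≈ 254), steady-state APD90 ≈ 266–271 ms, diastolic V_m ≈
−88.0 mV, diastolic Na⁺ ≈ 7.25 mM.

**Stimulus convention and peak V_m.** The default stimulus is the ORd
reference convention: −80 A/F for 0.5 ms, assigned to the K⁺ flux
(toggleable via `stim_to_k`) so long runs conserve charge. Under this
convention the baseline model's steady-state peak V_m is 40.2 mV. Peak V_m
is *extremely* sensitive to stimulus overlap with the I_Na upstroke: at
−80 A/F, lengthening the pulse from 0.9 to 1.0 ms moves the peak from 43.1
to 46.7 mV, and values near 45–46 mV are only reached when the stimulus is
still on during the upstroke. Published baseline peak values in the
mid-forties therefore reflect a longer-than-reference stimulus; since no
standard convention (2× diastolic threshold at 1 or 2 ms; −80 A/F × 1 ms)
reproduces them exactly, the package keeps the reference convention and
documents the sensitivity rather than fitting a non-standard pulse width.

**Pacing and equilibration.** Production defaults pace 500 beats to control
steady state, apply a block or perturbation to the equilibrated cell, pace
500 further beats, and analyze the final two (perturb → equilibrate →
block → equilibrate → analyze). Rapid-pacing runs use 2.5 Hz followed by
exactly two 1 Hz beats; Ca²⁺ loading is the beat-averaged cytosolic Ca²⁺ of
the final rapid beat relative to the final beat of a 1 Hz control run of
equal total length.

## Biomarkers and the abnormality detector

APDs are measured from the instant of maximum upstroke velocity (within
50 ms of stimulus onset), with repolarization levels relative to the
peak-to-RMP amplitude and crossing times linearly interpolated. RMP is the
sample immediately before stimulus onset; V_m time is stimulus onset → peak.
Triangulation is APD90 − APD40 by default (APD90 − APD50 selectable): it
uses only quantities the pipeline already computes and captures late-phase
slowing. A voltage excursion under 30 mV raises a distinct "no-AP" error; a
beat that never reaches 90 % repolarization is returned flagged
`unrepolarized` with NaN durations (and is auto-rejected by calibration).

The detector computes dV/dt by central differences on the uniform grid
(one-sided at the ends). A cycle is abnormal when dV/dt strictly exceeds
0.02 mV/ms at any sample more than 100 ms after that cycle's initial
upstroke — the dead time keeps delayed upstrokes and spike-and-dome
morphologies from being misread. A cycle ending above −40 mV is classed
`repolarization_failure` and counts as abnormal even without a
positive-gradient event, because a monotone failure to repolarize produces
none; this end-of-cycle rule is an interpretation the pure gradient rule
cannot supply. Susceptibility classes: NS = 0 abnormal scenarios, MS = 1–9,
HS ≥ 10.

## Population and calibration

Latin hypercube sampling covers each scaling's range (default 0–2×) with
exactly one draw per equal-width stratum, uniformly jittered within the
stratum (not stratum centers). Each dimension uses a child generator keyed
by (master seed, dimension index), so adding or re-ranging one dimension
never reshuffles another — useful when extending the sampled parameter set.

Calibration intervals are per-biomarker min/max over the (outlier-cleaned)
reference dataset, bounds inclusive so observed extrema self-calibrate. The
default outlier rule excludes recordings with APD90 > 500 ms or
time-to-peak > 20 ms. Widening any interval can only grow the accepted set.

## Synthetic data

The cohort generator emulates a 62-recording human right-ventricular
biomarker dataset: APD90 ~ 293 ± 66 ms and time-to-peak ~ 6.7 ± 5.4 ms
(truncated normals), plus three planted outliers (APD90 543 ms;
times-to-peak 26 and 38 ms) appended after the regular rows so the default
outlier rule excludes exactly them. Moments for the remaining biomarkers
(V_m peak 33 ± 3 mV in 25–42; RMP −85 ± 2.5 mV in −92…−78) are **stand-ins**
chosen around baseline-ORd simulated values, not measured statistics, and
are configurable. APD40/APD50 are drawn as fractions of each row's APD90
(0.74 ± 0.05 and 0.84 ± 0.03, truncated) so the APD ordering holds row-wise;
triangulation is computed, not drawn. The generator does not emulate raw
voltage waveforms, electrode noise spectra, or inter-heart structure — a
calibration test passing against this cohort shows the pipeline's logic,
not agreement with any particular laboratory's ranges.

Synthetic AP traces are piecewise-linear pulses whose 40/50/90 % crossing
times equal the requested APDs exactly (anchor points at the exact levels),
with an optional Gaussian "EAD bump" whose maximum upward gradient is
amplitude/(width·√e); the nominal stimulus onset sits two samples before the
upstroke so the preceding sample is diastolic.

Fixture archetypes encode known susceptibility structure: `hs_like`
(G_NaK = 0.2, G_CaL = 1.2 — pump below half baseline, I_CaL above ~0.78×,
the regime of highly susceptible profiles), `hs_representative`
(G_NaK = 0.1675, used in pump-restoration experiments), `robust`
(baseline-like; G_Na = 0.8 because the unmodified model's AP peak sits just
above recorded maxima, as most calibrated profiles do), and
`low_reserve_ns` (G_Ks = 0.2 with a normal pump).

## Current-budget analysis

Early repolarization is peak → APD40, late is APD40 → APD90; window means
are trapezoidal time-averages with edge interpolation, in the ORd sign
convention (outward positive). Group values are mean ± SD of per-model
means. One caveat found while validating: with a *full-conductance* G_Kr,
the residual I_Kr under 75 % block (~0.16 A/F) still exceeds a 0.2× pump's
I_NaK even after long equilibration; the pump-dominance ordering reported
for highly susceptible cells presumes their typically below-baseline I_Kr
density. The qualitative pump-dominance test therefore uses an HS-regime
fixture with G_Kr = 0.5.

## Statistics

Mann–Whitney U is two-sided; for combined n ≤ 12 the permutation
distribution of U is enumerated exactly (ties permute naturally), otherwise
the tie-corrected normal approximation is used. Partial correlations come
from precision-matrix normalization, pcc(i,j|rest) = −P_ij/√(P_ii·P_jj),
which equals the residual-regression correlation (asserted against that
oracle in the tests). Bonferroni thresholds are α/m. The HS classifier is
an unpenalized logistic regression on the seven z-scored biomarkers
(z-scoring fit on training folds only), evaluated by repeated stratified
10-fold cross-validation at a 0.5 probability cutoff; sensitivity (HS
recall) is the headline metric. Stratified folds and the 0.5 cutoff are
declared choices; no class re-weighting is applied because plain
sensitivity of an unweighted model is the quantity of interest.

## Problem sizes used by the tests

Simulation-backed tests use scaled-down study conditions chosen as the
smallest sizes at which the asserted behaviors are stable: 100-beat control
equilibration and 100-beat block re-equilibration for the emergent-behavior
checks (150 + 100 for the current-budget ordering, which needs more Na⁺
accumulation), 30–60 beats for monotonicity and window checks, and a
250-model LHS sample for the low-G_Kr calibration check (only the
low-G_Kr candidates are simulated, since the assertion concerns them
alone). The full-scale protocol (10,000-model sampling, 500-beat
equilibrations, the complete 96-scenario grid) runs through the same code
paths via `RunConfig` defaults.

## Known limitations

* Single-cell only: no electrotonic coupling, so complete repolarization
  failure that tissue would suppress is reported as-is.
* Conductance variability only; channel kinetics are fixed at ORd values.
* No delayed-afterdepolarization detection; the detector targets EADs and
  repolarization failure during the paced cycle.
* The calibration cohort is synthetic unless a measured biomarker table is
  supplied; exact acceptance counts depend on the ranges used.
* Fixed-step integration trades some stiffness robustness for determinism
  and speed; failures are flagged per cell rather than resolved by step
  control.
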