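# Methods

`cardioem` quantifies how myocardial conduction velocity (MCV) shapes
cardiac pumping efficacy, at desk scale: a ventricular ionic model is
propagated through monodomain tissue whose resistivity is calibrated to a
target conduction velocity; the resulting electrical activation times (EAT)
drive a cross-bridge myofilament model one-way; the ensemble tension loads
a lumped two-ventricle / four-Windkessel circulation; and the experiment is
a sweep over MCV = 30, 40, 50, 60, 70 cm/s under sinus pacing at a 600 ms
cycle length.

## Electrophysiology

**Cell model.** The ten Tusscher–Panfilov (2006) human ventricular model:
`dV/dt = −(I_ion + I_stim)` with currents Cm-normalized (pA/pF ≡ mV/ms) and

```
I_ion = I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaCa + I_NaK
      + I_pCa + I_pK + I_bCa + I_bNa
```

plus calcium cycling between cytosol, dyadic subspace and SR
(`dCa_SR/dt ∝ I_up − I_rel − I_leak`; the SERCA pump I_up loads the SR,
release and leak drain it). Three transmural variants — endo, mid, epi —
differ in g_to, g_Ks and the s-gate kinetics; the M cell (smallest g_Ks)
has the longest action potential, so repolarization ends mid-wall. All
constants are tabulated in `docs/constants.md` and overridable through the
`cell:` config block.

**Numerics.** Rush–Larsen exponential updates for the 13 gates (gates stay
in [0,1] by construction), forward Euler for V and the five concentrations;
dt = 0.02 ms with a hard 0.05 ms limit. Tissue runs use a tabulated
voltage dependence (0.05 mV grid, linear interpolation) for the gate rates
and current prefactors; the test suite asserts agreement with the exact
per-step path (max |ΔV| < 0.05 mV over a full upstroke). An adaptive
LSODA integration of the identical right-hand side serves as the reference
for APD90 and Ca-transient checks (agreement ~0.1%, tested at 2%).

**Tissue.** Monodomain reaction–diffusion on regular grids:
`dV/dt = −(I_ion+I_stim) + Σ_a D_a ∂²V/∂x_a²` with
`D_a = 1/(ρ_a S_a Cm)`; ρ = 162 Ω·cm, S = 2000 cm⁻¹, Cm = 2 µF/cm² give
D = 1.54·10⁻³ cm²/ms and a planar cable velocity of ~71 cm/s — the
70 cm/s normal-conduction validation point. Diffusion is an explicit
second-order stencil with mirror (zero-flux) boundaries; the stencil is
conservative to round-off. Operator order is reaction then diffusion each
step.

Conduction velocity is measured between the 25% and 75% positions of a
2 cm epicardial cable (distance over activation-time difference), away from
stimulus and boundary artifacts. Resistivity for each MCV condition is
calibrated by bisection in log ρ on that cable (CV is strictly decreasing
in ρ; tolerance 1%). In the continuum limit planar CV ∝ 1/√ρ (a 5.4×
multiplier for the 30 cm/s condition); at the working resolution the
calibrated multiplier comes out ≈3.9×. Both exceed the 3.3× multiplier
quoted for full-ventricle geometries, where the measurement convention
differs; the quoted multipliers ship as a documented preset but are not
used for calibration.

**Grid bias.** At the working resolution (dx = 0.025 cm) the measured CV
sits ~7% below the dx→0 limit — the familiar coarse-grid CV bias of this
model family; the 70 cm/s convention itself is quoted at such working
resolutions. The <3% convergence-under-refinement property therefore holds
one refinement level down (0.0125 vs 0.00625 cm, 2.1%) and is tested
there; the 1/√ρ scaling oracle is also evaluated on the refined cable
(1.9% deviation, tested at 5%).

## Fixtures and pacing

Fixtures are generated, not loaded: a 2 cm cable (dx = 0.025 cm, 81
nodes) for conduction-velocity work, and an annular shell
(r = 0.55–0.80 cm, dx = 0.025 cm, 1696 nodes, endo/mid/epi thickness
fractions 0.3/0.4/0.3) standing in for a ventricular short-axis section.
These sizes were chosen once as the desk-scale study conditions; the
methods and trends do not depend on them qualitatively, but absolute EAT
durations scale with the fixture size (maximum path ~2.4 cm here versus
~8 cm in a canine ventricle, so EAT durations are ~40–65 ms rather than
120–220 ms).

The Purkinje surrogate samples terminal sites on the endocardial surface
(seeded, default 2 sites) and assigns onsets
`onset_i = 20 ms + d_i / (200 cm/s)`, where d_i is the lattice-geodesic
path distance from the earliest site (exact shortest path on the grid
graph; the annulus is non-convex, so straight-line distances would cut
through the cavity). Each terminal is stimulated as a small patch
(radius 0.05 cm, −52 pA/pF for 2 ms) — a point source is drained by its
neighbors and fails to capture. Stimulated nodes take their onset as their
activation time (the conduction system fires them directly); all other
nodes activate at their first upward crossing of 0 mV, linearly
interpolated between samples. The minimum EAT of any sinus run therefore
equals the 20 ms terminal onset exactly, and the activation duration is
reported as max(EAT) from cycle onset (a tissue fully depolarized at
120 ms has EAT duration 120 ms).

Electrical runs last 3 s (five cycles); the activation map of the final
cycle (2.4–3.0 s) is the electro-mechanics handoff.

## Excitation–contraction coupling and energetics

A Rice-style mean-field myofilament model: regulatory units are
non-permissive (N) or permissive (P); permissive units bind myosin into a
pre-rotation state (XB_PreR) that isomerizes to the force-bearing
post-rotation state (XB_PostR); detachment from XB_PostR (rate g_xbT)
consumes one ATP. N + P + XB_PreR + XB_PostR is conserved (tested to
10⁻⁸ over 10⁵ steps). Thin-filament activation is a steep Hill function of
the Ca-bound regulatory troponin fraction. The contractile ATP
consumption rate is

```
rate = g_xbT × SOVF_Thick × XB_PostR     (1/s)
```

the detachment flux through the thick-filament single-overlap fraction
SOVF_Thick(SL); the XB_PostR weighting (the attached fraction actually
detaching) is the documented flux convention and can be disabled.

**Calibration.** The published regulatory-Ca constants are tuned to that
model's own Ca input; under the TP06 transient (diastolic ~0.13 µM, peak
~1.2 µM) they leave the thin filament essentially inactive. The troponin
affinity and half-activation were therefore recalibrated once
(Kd = 1.67 µM, perm50 = 0.5) so the transient spans the activation range,
producing a peaked twitch (time-to-peak ~70 ms, half-width ~110 ms,
relaxed by ~250 ms). A peaked twitch matters structurally: with a long
quasi-static tension plateau, end-systole is set by the plateau, which is
insensitive to activation dispersion, and the volume trends of the sweep
degenerate. Absolute tension/ATP magnitudes are calibrated quantities and
are not compared against the source study.

**Drive.** Each mechanics node receives its transmural region's Ca
template — the final beat of a 21-beat converged single-cell run
(convergence gate: diastolic drift < 2%/beat) — shifted by its activation
time, with the diastolic level before first activation. Coupling is
strictly one-way.

## Ventricle surrogate and circulation

The finite-element mechanics of the source study is replaced by a lumped
thin-wall surrogate; in consequence hemodynamic *magnitudes are
calibrated, not emergent*, and only trends across MCV conditions carry
scientific meaning. Cavity pressure is

```
P(V) = B (e^{κ(V − V_rest)} − 1) + α · T̄ · (V/V_ref)^{−2/3}
```

(passive exponential plus Laplace-scaled active wall stress). Ensemble
tension T̄ is evaluated at the ventricle's fiber length
`SL = SL_ref (V/V_SLref)^{1/3}` and includes the force–length relation:
thick-filament overlap times a steep ascending-limb cutoff (zero active
force below 1.55 µm). Without the cutoff the Laplace factor is a positive
feedback on ejection and the cavity collapses; with it, end-systole is a
stable force balance. A wall-contact floor (5 mL) gates outflow
conservatively.

**Mechanics ensemble.** 128 wall segments sampled from the activation map
by a fixed spatial stratification (region × angle, even strides) — the
same segments for every MCV condition, so conditions differ only through
their activation times. Segments act in series: each carries a
sarcomere-length offset that relaxes toward tension equality
(`dδ_k/dt = −k_r (T_k − T̄) − k_rec δ_k`, Σδ preserved), so early-activated
segments shorten at the expense of late ones. This series redistribution
is the lumped analogue of dyssynchronous regional stretch — the mechanism
by which activation dispersion wastes contractile work — and is what makes
end-systolic volume respond to dispersion in a 0-D model. Per-segment ATP
uses the segment's own overlap fraction, which couples Eq.-(1) energetics
to the shared volume and length signals.

The right ventricle shares the surrogate form (scaled gain) but is driven
by a synchronous twitch at the ensemble-mean activation time: the fixture
is an LV section, and RV function is far less sensitive to dyssynchrony;
giving the RV the LV's dispersion gain pushes the synchrony benefit into
the pulmonary veins and inverts the preload trends.

**Circulation.** Each of the systemic and pulmonic circulations is two
Windkessel compartments in series (arterial+capillary, venous), linear
P = (V − V0)/C, flows Q = ΔP/R, ideal-diode valves with small series
resistance, no inertance. Volume updates are inflow − outflow, so total
blood volume is conserved to round-off (tested to 10⁻⁶ relative over a
full run). The failing preset multiplies every vascular compliance by 0.9
and is guarded against re-application; it is on by default (the study
models a failing, hypertensive ventricle). R/C constants and the
surrogate gains were tuned once (script `analysis/00_tune_circulation.py`)
so the 70 cm/s baseline lands near the reported operating range
(EDV ≈ 88 mL, ESV ≈ 54 mL, SV ≈ 33–34 mL, EF ≈ 38%, MAP ≈ 132 mmHg) and
then frozen. The venous compliances (C_sv = 8, C_pv = 12 mL/mmHg) are at
the stiff end of their physiological range so that the closed loop reaches
its periodic state within the prescribed 32 mechanical cycles (verified:
32- vs 64-cycle EDV agree to 0.001 mL); the mechanical step is 0.1 ms,
synchronized with the myofilament stepping.

## The sweep and its metrics

Per condition: calibrate ρ on the cable → 3 s paced shell run → final
cycle activation map → 32 mechanical cycles → final-cycle metrics:

* EAT duration = max activation time (ms);
* systolic pressure = max P_LV; MAP = time-average systemic arterial
  pressure over the final cycle;
* EDV/ESV = extremes of V_LV; SV = EDV − ESV and EF = 100·SV/EDV hold
  exactly by construction;
* SW = PV-loop area (shoelace on the closed polygon; agrees with refined
  quadrature to <0.5%);
* ATP = node-summed, cycle-averaged consumption rate of the ensemble (1/s;
  the source study does not state summed vs averaged — summed is
  implemented and documented);
* SW/ATP, the pumping-efficiency index.

Expected directions for increasing MCV: EAT↓, EDV↓, ESV↓, systolic P↑,
SV↑, EF↑, SW↑, ATP↓, SW/ATP↑. The default sweep reproduces all nine
strictly monotonically. The whole pipeline is deterministic: repeated runs
are byte-identical.

## What the synthetic fixtures do and do not show

The generators emulate transmural heterogeneity, endocardial-first
activation with a fast conduction-system surrogate, conduction slowing via
cellular resistivity, dispersion-dependent contraction and energetics, and
a failing, hypertensive circulation. They do not emulate anatomical fiber
architecture, the real Purkinje tree, 3-D wall mechanics (strain fields,
torsion), mechano-electric feedback, or absolute organ scale. Passing
tests therefore demonstrate the *mechanistic chain and its directions*,
not magnitude transfer to a real ventricle: desk-scale EAT dispersions are
several-fold smaller than organ-scale ones, so the metric separations
between conditions are correspondingly small (e.g. ΔSV ~0.2 mL across the
sweep rather than ~2 mL).

## Degenerate inputs and tie-breaks

Non-finite cell states are rejected naming the offending field; dt above
the stability or CFL limit is rejected with the computed limit; empty
activation maps, equal activation times in a CV measurement, and targets
outside the conducting range are errors; nodes that never activate are
flagged absent and excluded from statistics (and from the mechanics
ensemble, logged); a non-closed PV loop or an unconverged end-diastolic
volume attaches a warning, never an abort; conduction failure of one sweep
condition flags and excludes that condition while the sweep continues.
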