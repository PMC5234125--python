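# Model constant tables

All values below are the package defaults; every one can be overridden
through the configuration (`cell.overrides`, `mechanics.myofilament`,
`circulation.*`) without code changes.

## Ventricular ionic model (ten Tusscher–Panfilov 2006 parameterization)

Physical constants and geometry

| name | value | units | meaning |
|---|---|---|---|
| R | 8314.472 | J/(kmol·K) | gas constant |
| T | 310 | K | temperature |
| F | 96485.3415 | C/mol | Faraday constant |
| Cm_cap | 0.185 | µF | capacitance factor in concentration balances |
| V_c | 0.016404 | (volume units of the source model) | cytoplasmic volume |
| V_sr | 0.001094 | 〃 | SR volume |
| V_ss | 5.468e-5 | 〃 | dyadic subspace volume |
| K_o / Na_o / Ca_o | 5.4 / 140 / 2 | mM | extracellular concentrations |

Maximal conductances / permeabilities (nS/pF unless noted)

| name | value | current |
|---|---|---|
| g_Na | 14.838 | fast Na⁺ |
| g_K1 | 5.405 | inward rectifier |
| g_Kr | 0.153 | rapid delayed rectifier |
| g_Ks | 0.392 (endo, epi), 0.098 (mid) | slow delayed rectifier |
| g_to | 0.294 (mid, epi), 0.073 (endo) | transient outward |
| g_CaL | 3.98e-5 (cm³/(µF·s)-scaled) | L-type Ca²⁺ |
| g_bNa / g_bCa | 2.9e-4 / 5.92e-4 | background |
| g_pCa / K_pCa | 0.1238 / 5e-4 mM | sarcolemmal Ca²⁺ pump |
| g_pK | 0.0146 | K⁺ pump |
| P_NaK / K_mk / K_mNa | 2.724 / 1 mM / 40 mM | Na⁺-K⁺ pump |
| k_NaCa, γ, K_mCa, K_mNai, K_sat, α | 1000, 0.35, 1.38, 87.5, 0.1, 2.5 | Na⁺-Ca²⁺ exchanger |
| P_kna | 0.03 | Na⁺ permeability of I_Ks |

SR calcium handling and buffering

| name | value | units |
|---|---|---|
| V_maxup / K_up | 0.006375 / 2.5e-4 | mM/ms, mM |
| V_rel | 0.102 | mM/ms |
| k1' / k2' / k3 / k4 | 0.15 / 0.045 / 0.06 / 0.005 | release-gate rates |
| EC / max_sr / min_sr | 1.5 mM / 2.5 / 1.0 | SR-load dependence |
| V_leak / V_xfer | 3.6e-4 / 3.8e-3 | mM/ms |
| Buf_c / K_buf_c | 0.2 / 0.001 | mM |
| Buf_sr / K_buf_sr | 10 / 0.3 | mM |
| Buf_ss / K_buf_ss | 0.4 / 2.5e-4 | mM |

## Tissue conduction

| name | value | units | note |
|---|---|---|---|
| ρ | 162 | Ω·cm | 70 cm/s preset; per-condition values calibrated |
| S | 2000 | cm⁻¹ | surface-to-volume ratio |
| Cm | 2.0 | µF/cm² | membrane capacitance per area |
| dt | 0.02 | ms | stability limit 0.05 ms; CFL enforced |
| threshold | 0 | mV | activation detection |

## Myofilament (Rice-style cross-bridge model)

Rates per millisecond; the regulatory-Ca affinity and half-activation are
calibrated to the ionic model's Ca transient (see docs/methods.md).

| name | value | meaning |
|---|---|---|
| kon | 150 /(mM·ms) | Ca on-rate to troponin |
| koffL | 0.25 /ms | regulatory (low-affinity) off-rate → Kd 1.67 µM |
| koffH | 0.015 /ms | high-affinity off-rate |
| perm50 / nperm | 0.5 / 10 | half-activation and steepness |
| knp / kpn | 0.5 / 0.05 /ms | N↔P base rates (kpn × min(1/permtot, 100)) |
| fapp / gapp | 0.5 / 0.07 /ms | attachment / pre-rotation detachment |
| hf / hb | 2.0 / 0.4 /ms | rotation forward / backward |
| gxb | 0.07 /ms | ATP-consuming detachment (g_xbT = 70 s⁻¹) |
| len_thick / len_hbare / len_thin | 1.65 / 0.1 / 1.2 µm | filament geometry |
| SL_ref | 2.2 µm | tension normalization length |

## Circulation and ventricle surrogates (tuned once, then frozen)

Windkessel compartments (R in mmHg·ms/mL, C in mL/mmHg, volumes mL);
compliances are further ×0.9 under the failing preset (default on).

| compartment | R | C | V_init | V0 |
|---|---|---|---|---|
| systemic arterial+capillary | 5 (characteristic) | 3.0 | 650 | 350 |
| systemic venous | 2300 (systemic resistance) | 8.0 | 2255 | 2200 |
| pulmonic arterial+capillary | 10 (characteristic) | 5.0 | 150 | 60 |
| pulmonic venous | 180 (pulmonary resistance) | 12.0 | 115 | 60 |

Valves: R_av 5, R_mv 8, R_tv 8, R_pvalve 10 mmHg·ms/mL (diodes).

| ventricle | B (mmHg) | κ (1/mL) | V_rest | α (mmHg) | V_ref |
|---|---|---|---|---|---|
| LV | 0.55 | 0.055 | 38 | 220 | 88 |
| RV | 0.30 | 0.040 | 38 | 32 | 110 |

Mechanics: ensemble 128 segments; SL_ref 2.15 µm at V = 89 mL (LV) /
110 mL (RV); force–length cutoff 1.55–1.95 µm; series redistribution rate
0.03 µm/(ms·unit tension), recoil 0.02 /ms; wall-contact floor 5 mL;
step 0.1 ms.
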