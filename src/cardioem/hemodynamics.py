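"""Lumped ventricles and closed-loop Windkessel circulation.

The imaging-based finite-element ventricle is replaced by a documented
thin-wall surrogate: cavity pressure is the sum of an exponential passive
term  P_pass = B (exp(k (V - V_rest)) - 1)  and an active term
P_act = alpha * T_bar * (V / V_ref)^(-2/3)  (Laplace scaling of wall stress
to cavity pressure), where T_bar is the ensemble-mean normalized active
tension of the myofilament nodes.  Consequence: hemodynamic magnitudes are
calibrated, not emergent, and only trends across conduction-velocity
conditions are scientifically meaningful.

Each circulation (systemic, pulmonic) is two Windkessel compartments in
series -- arterial+capillary and venous -- each a resistance into a linear
pressure-volume capacitor P = (V - V0)/C.  Valves are ideal diodes with a
small series resistance.  Volume change is inflow minus outflow, so total
blood volume is conserved to roundoff.  The failing preset multiplies every
vascular compliance by 0.9 (hypertensive stiffening).

Mechanics ensemble: a fixed spatial subsample of the activation map (the
same wall segments whatever the condition), each segment driven by its
region's Ca-transient template shifted by its activation time.  Sarcomere
length follows cavity volume, SL = SL_ref (V/V_SL_ref)^(1/3), and segments
act in series: per-segment length offsets relax toward tension equality
with an elastic recoil, so early-activated segments shorten at the expense
of late ones -- the lumped analogue of dyssynchronous regional stretch.
This is what lets activation dispersion reach both ejection and the
overlap factor of the ATP-rate product.  The RV surrogate is driven by a
synchronous twitch at the ensemble-mean activation time (the fixture is an
LV section).  Coupling is strictly one-way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .myofilament import (MyoParams, MyoState, _myo_step, _sovf_thick_nb,
                          SL_MIN, SL_MAX)

__all__ = [
    "WindkesselCompartment", "CirculationParams", "VentricleSurrogate",
    "HemoState", "HemoTrace", "ventricle_pressure", "step_circulation",
    "apply_failing_condition", "run_cardiac_cycles", "steady_state_check",
    "default_circulation", "default_ventricles",
]


@dataclass
class WindkesselCompartment:
    """One lumped vascular segment: inflow resistance + linear capacitor."""

    R: float     # mmHg ms / mL (inflow resistance)
    C: float     # mL / mmHg
    V: float     # mL
    V0: float    # mL, unstressed volume

    def __post_init__(self):
        if self.R <= 0 or self.C <= 0 or self.V < 0:
            raise ValueError("need R > 0, C > 0, V >= 0")

    @property
    def P(self) -> float:
        return (self.V - self.V0) / self.C


@dataclass
class VentricleSurrogate:
    """Thin-wall lumped ventricle (stand-in for the FEM mechanics)."""

    B: float          # mmHg, passive stiffness scale
    kappa: float      # 1/mL, passive exponential constant
    V_rest: float     # mL, zero-pressure volume
    alpha: float      # mmHg per unit normalized tension
    V_ref: float      # mL, Laplace reference volume
    wall_volume: float = 150.0  # mL


@dataclass
class CirculationParams:
    """Four Windkessel compartments, valves, and the failing preset flag."""

    sa: WindkesselCompartment   # systemic arterial + capillary
    sv: WindkesselCompartment   # systemic venous
    pa: WindkesselCompartment   # pulmonic arterial + capillary
    pv: WindkesselCompartment   # pulmonic venous
    R_av: float = 8.0           # aortic valve, mmHg ms/mL
    R_mv: float = 8.0           # mitral valve
    R_tv: float = 8.0           # venous -> RV (tricuspid; no atria)
    R_pvalve: float = 8.0       # pulmonic valve
    failing: bool = False

    def compartments(self):
        return (self.sa, self.sv, self.pa, self.pv)

    def total_volume(self, V_lv: float, V_rv: float) -> float:
        return sum(c.V for c in self.compartments()) + V_lv + V_rv


def default_circulation() -> CirculationParams:
    """Baseline circulation constants (tuned once; see analysis/00 script).

    Compartment ``R`` is the inflow resistance from the upstream element:
    characteristic arterial resistance for sa/pa (in series with the
    valves), systemic and pulmonary vascular resistance for sv/pv.
    """
    return CirculationParams(
        sa=WindkesselCompartment(R=5.0, C=3.0, V=650.0, V0=350.0),
        sv=WindkesselCompartment(R=2300.0, C=8.0, V=2255.0, V0=2200.0),
        pa=WindkesselCompartment(R=10.0, C=5.0, V=150.0, V0=60.0),
        pv=WindkesselCompartment(R=180.0, C=12.0, V=115.0, V0=60.0),
    )


def default_ventricles() -> tuple:
    lv = VentricleSurrogate(B=0.55, kappa=0.055, V_rest=38.0, alpha=220.0,
                            V_ref=88.0)
    rv = VentricleSurrogate(B=0.30, kappa=0.040, V_rest=38.0, alpha=32.0,
                            V_ref=110.0, wall_volume=70.0)
    return lv, rv


def apply_failing_condition(params: CirculationParams) -> CirculationParams:
    """Failing-ventricle preset: every vascular compliance x 0.9.

    Resistances and volumes are untouched.  Guarded: re-application raises
    (the preset is a condition, not a cumulative operation).
    """
    if params.failing:
        raise ValueError("failing condition already applied")
    def scaled(c):
        return WindkesselCompartment(R=c.R, C=0.9 * c.C, V=c.V, V0=c.V0)
    return CirculationParams(
        sa=scaled(params.sa), sv=scaled(params.sv), pa=scaled(params.pa),
        pv=scaled(params.pv), R_av=params.R_av, R_mv=params.R_mv,
        R_tv=params.R_tv, R_pvalve=params.R_pvalve, failing=True)


def ventricle_pressure(vent: VentricleSurrogate, ensemble_tension: float,
                       V: float) -> float:
    """Cavity pressure (mmHg) at volume V under mean active tension."""
    if V <= 0:
        raise ValueError("cavity volume must be positive")
    p_pass = vent.B * (np.exp(vent.kappa * (V - vent.V_rest)) - 1.0)
    p_act = vent.alpha * ensemble_tension * (V / vent.V_ref) ** (-2.0 / 3.0)
    return p_pass + p_act


@dataclass
class HemoState:
    """Volumes, pressures and valve states of one instant."""

    V_lv: float
    V_rv: float
    params: CirculationParams
    P_lv: float = 0.0
    P_rv: float = 0.0
    t: float = 0.0
    valves: dict = field(default_factory=lambda: {
        "aortic": False, "mitral": False, "tricuspid": False,
        "pulmonic": False})

    @property
    def total_volume(self) -> float:
        return self.params.total_volume(self.V_lv, self.V_rv)


def step_circulation(state: HemoState, params: CirculationParams,
                     P_lv: float, P_rv: float, dt: float) -> HemoState:
    """One explicit step of the vascular loop given ventricular pressures.

    Flows are Q = dP/R, gated to Q >= 0 through the four valves; volume
    updates are inflow minus outflow (exact conservation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sa, sv, pa, pv = (replace(c) for c in params.compartments())
    q_av = max(P_lv - sa.P, 0.0) / (params.R_av + sa.R)
    q_sys = (sa.P - sv.P) / sv.R
    q_tv = max(sv.P - P_rv, 0.0) / params.R_tv
    q_pv = max(P_rv - pa.P, 0.0) / (params.R_pvalve + pa.R)
    q_pul = (pa.P - pv.P) / pv.R
    q_mv = max(pv.P - P_lv, 0.0) / params.R_mv

    V_lv = state.V_lv + dt * (q_mv - q_av)
    sa.V += dt * (q_av - q_sys)
    sv.V += dt * (q_sys - q_tv)
    V_rv = state.V_rv + dt * (q_tv - q_pv)
    pa.V += dt * (q_pv - q_pul)
    pv.V += dt * (q_pul - q_mv)
    for name, comp in (("sa", sa), ("sv", sv), ("pa", pa), ("pv", pv)):
        if comp.V < 0:
            raise FloatingPointError(f"negative volume in compartment {name}")
    new_params = CirculationParams(sa=sa, sv=sv, pa=pa, pv=pv,
                                   R_av=params.R_av, R_mv=params.R_mv,
                                   R_tv=params.R_tv,
                                   R_pvalve=params.R_pvalve,
                                   failing=params.failing)
    return HemoState(V_lv=V_lv, V_rv=V_rv, params=new_params, P_lv=P_lv,
                     P_rv=P_rv, t=state.t + dt,
                     valves={"aortic": q_av > 0, "mitral": q_mv > 0,
                             "tricuspid": q_tv > 0, "pulmonic": q_pv > 0})


# ---------------------------------------------------------------------------
# coupled mechanics + circulation loop
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fiber_length(V, sl_ref, v_ref, floor):
    """Lumped fiber-length map SL = SL_ref (V/V_ref)^(1/3), clipped."""
    vc = V if V > floor else floor
    sl = sl_ref * (vc / v_ref) ** (1.0 / 3.0)
    if sl < SL_MIN:
        sl = SL_MIN
    elif sl > SL_MAX:
        sl = SL_MAX
    return sl


@njit(cache=True, fastmath=True)
def _flen(sl, mc, lo, hi):
    """Tension-length factor: thick-filament overlap times the steep
    ascending-limb cutoff (no active force below ``lo`` um)."""
    ramp = (sl - lo) / (hi - lo)
    if ramp < 0.0:
        ramp = 0.0
    elif ramp > 1.0:
        ramp = 1.0
    return _sovf_thick_nb(sl, mc[13], mc[14], mc[15]) * ramp


@njit(cache=True, fastmath=True)
def _run_mech_circ(my, eat, reg, my_rv, eat_rv, delta, tmpl_ca, tmpl_dt,
                   cl, mc, dt, n_steps, hc, vols, sample_every, out,
                   atp_last, tens_last, last_cycle_start, norm, gxbs):
    """Fixed-step loop over myofilament ensemble + ventricles + Windkessels.

    ``my``  (K,6) myofilament states; ``eat`` (K,) activation times (ms);
    ``reg`` (K,) region index into ``tmpl_ca`` (3, M) Ca templates sampled
    at ``tmpl_dt``; ``vols`` = [V_lv, V_rv, V_sa, V_sv, V_pa, V_pv];
    ``hc`` the packed hemodynamic constants (see run_cardiac_cycles).
    Records ``out`` every ``sample_every`` steps and per-node ATP rate /
    tension for t >= last_cycle_start.
    """
    K = my.shape[0]
    M = tmpl_ca.shape[1]
    dy = np.empty(6)
    Tk = np.empty(K)
    ks = 0
    kl = 0
    floor = hc[30]
    kr = hc[31]     # series redistribution rate (um/ms per unit tension)
    krec = hc[32]   # elastic recoil of the length offsets (1/ms)
    for step in range(n_steps):
        t = step * dt
        V_lv = vols[0]; V_rv = vols[1]
        # per-ventricle fiber length from cavity volume
        if hc[26] > 0.5:
            sl_lv = _fiber_length(V_lv, hc[24], hc[25], floor)
            sl_rv = _fiber_length(V_rv, hc[24], hc[27], floor)
        else:
            sl_lv = hc[24]
            sl_rv = hc[24]
        # myofilament ensemble (LV wall segments in series) under shifted
        # Ca drives; each segment's length is the volume-derived fiber
        # length plus its series-redistribution offset
        tsum = 0.0
        for k in range(K):
            if t < eat[k]:
                ca = tmpl_ca[reg[k], 0]
            else:
                tau = (t - eat[k]) % cl
                fi = tau / tmpl_dt
                i0 = int(fi)
                wi = fi - i0
                i1 = i0 + 1
                if i1 >= M:
                    i1 = 0
                ca = tmpl_ca[reg[k], i0] + wi * (tmpl_ca[reg[k], i1]
                                                 - tmpl_ca[reg[k], i0])
            _myo_step(my[k], ca, dt, mc, dy)
            sl_k = sl_lv + delta[k]
            if sl_k < SL_MIN:
                sl_k = SL_MIN
            elif sl_k > SL_MAX:
                sl_k = SL_MAX
            Tk[k] = _flen(sl_k, mc, hc[28], hc[29]) * my[k, 3] / norm
            tsum += Tk[k]
            if t >= last_cycle_start and (step + 1) % sample_every == 0:
                sovf_k = _sovf_thick_nb(sl_k, mc[13], mc[14], mc[15])
                atp_last[kl, k] = gxbs * sovf_k * my[k, 3]
                tens_last[kl, k] = sovf_k * my[k, 3] / norm
        xbn = tsum / K
        # series redistribution: segments above mean tension shorten at the
        # expense of the others (sum of offsets stays zero); elastic recoil
        # returns offsets to zero when tension is uniform
        for k in range(K):
            delta[k] += dt * (-kr * (Tk[k] - xbn) - krec * delta[k])
        # RV surrogate: synchronous twitch at the ensemble-mean activation
        # time (the fixture is an LV section; LV dispersion is not imposed
        # on the RV, which is far less sensitive to dyssynchrony)
        if t < eat_rv:
            ca_rv = tmpl_ca[2, 0]
        else:
            tau = (t - eat_rv) % cl
            fi = tau / tmpl_dt
            i0 = int(fi)
            wi = fi - i0
            i1 = i0 + 1
            if i1 >= M:
                i1 = 0
            ca_rv = tmpl_ca[2, i0] + wi * (tmpl_ca[2, i1] - tmpl_ca[2, i0])
        _myo_step(my_rv, ca_rv, dt, mc, dy)
        # ensemble tension: mean segment tension for the LV, synchronous
        # twitch at the RV's fiber length for the RV
        tbar = xbn
        tbar_rv = _flen(sl_rv, mc, hc[28], hc[29]) * my_rv[3] / norm

        # ventricular pressures (passive exponential + Laplace-scaled active)
        p_lv = hc[14] * (np.exp(hc[15] * (V_lv - hc[16])) - 1.0) \
            + hc[17] * tbar * (max(V_lv, floor) / hc[18]) ** (-2.0 / 3.0)
        p_rv = hc[19] * (np.exp(hc[20] * (V_rv - hc[21])) - 1.0) \
            + hc[22] * tbar_rv * (max(V_rv, floor) / hc[23]) ** (-2.0 / 3.0)

        p_sa = (vols[2] - hc[10]) / hc[6]
        p_sv = (vols[3] - hc[11]) / hc[7]
        p_pa = (vols[4] - hc[12]) / hc[8]
        p_pv = (vols[5] - hc[13]) / hc[9]

        q_av = (p_lv - p_sa) / hc[0] if p_lv > p_sa else 0.0
        q_sys = (p_sa - p_sv) / hc[4]
        q_tv = (p_sv - p_rv) / hc[2] if p_sv > p_rv else 0.0
        q_pv = (p_rv - p_pa) / hc[3] if p_rv > p_pa else 0.0
        q_pul = (p_pa - p_pv) / hc[5]
        q_mv = (p_pv - p_lv) / hc[1] if p_pv > p_lv else 0.0

        # wall-contact floor: outflow cannot push a cavity below ``floor``
        max_av = (vols[0] - floor) / dt + q_mv
        if q_av > max_av:
            q_av = max_av if max_av > 0.0 else 0.0
        max_pv = (vols[1] - floor) / dt + q_tv
        if q_pv > max_pv:
            q_pv = max_pv if max_pv > 0.0 else 0.0

        vols[0] += dt * (q_mv - q_av)
        vols[1] += dt * (q_tv - q_pv)
        vols[2] += dt * (q_av - q_sys)
        vols[3] += dt * (q_sys - q_tv)
        vols[4] += dt * (q_pv - q_pul)
        vols[5] += dt * (q_pul - q_mv)

        if (step + 1) % sample_every == 0:
            out[ks, 0] = (step + 1) * dt
            out[ks, 1] = p_lv
            out[ks, 2] = vols[0]
            out[ks, 3] = p_rv
            out[ks, 4] = vols[1]
            out[ks, 5] = p_sa
            out[ks, 6] = p_sv
            out[ks, 7] = p_pa
            out[ks, 8] = p_pv
            out[ks, 9] = tbar
            out[ks, 10] = sl_lv
            out[ks, 11] = 1.0 if q_av > 0 else 0.0
            out[ks, 12] = 1.0 if q_mv > 0 else 0.0
            if t >= last_cycle_start:
                kl += 1
            ks += 1
    return 0


@dataclass
class HemoTrace:
    """Sampled closed-loop run with cycle boundaries and last-cycle detail."""

    t: np.ndarray
    P_lv: np.ndarray
    V_lv: np.ndarray
    P_rv: np.ndarray
    V_rv: np.ndarray
    P_sa: np.ndarray
    P_sv: np.ndarray
    P_pa: np.ndarray
    P_pv: np.ndarray
    tension: np.ndarray
    SL: np.ndarray
    valve_av: np.ndarray
    valve_mv: np.ndarray
    cycle_length: float
    n_cycles: int
    atp_last: np.ndarray          # (samples, K) per-node ATP rate, 1/s
    tension_last: np.ndarray
    eat_nodes: np.ndarray         # (K,) EATs of the ensemble
    total_volume: tuple           # (initial, final) mL

    def cycle_slice(self, cycle: int) -> slice:
        a = cycle * self.cycle_length
        i0 = int(np.searchsorted(self.t, a + 1e-9))
        i1 = int(np.searchsorted(self.t, a + self.cycle_length + 1e-9))
        return slice(i0, i1)

    def final_cycle(self) -> dict:
        s = self.cycle_slice(self.n_cycles - 1)
        return {k: getattr(self, k)[s] for k in
                ("t", "P_lv", "V_lv", "P_rv", "V_rv", "P_sa", "P_sv",
                 "P_pa", "P_pv", "tension")}

    def edv_per_cycle(self) -> np.ndarray:
        return np.array([self.V_lv[self.cycle_slice(c)].max()
                         for c in range(self.n_cycles)])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_ms": self.t, "P_lv": self.P_lv, "V_lv": self.V_lv,
            "P_rv": self.P_rv, "V_rv": self.V_rv, "P_sa": self.P_sa,
            "P_sv": self.P_sv, "P_pa": self.P_pa, "P_pv": self.P_pv,
            "tension": self.tension, "SL": self.SL,
            "valve_av": self.valve_av, "valve_mv": self.valve_mv,
        })


def _stratified_ensemble(eat: np.ndarray, geom, size: int):
    """Fixed spatial subsample of the geometry (same nodes whatever the
    activation map, so conditions differ only through their EATs).

    Activated nodes are ordered by transmural region and in-plane angle and
    sampled at even strides -- deterministic and condition-independent.
    """
    ok = np.flatnonzero(~np.isnan(eat))
    if ok.size == 0:
        raise ValueError("EAT map has no activated nodes")
    if ok.size <= size:
        return ok
    if geom is not None:
        ang = np.arctan2(geom.coords[ok, 1], geom.coords[ok, 0])
        order = ok[np.lexsort((ang, geom.region[ok]))]
    else:
        order = ok
    edges = np.linspace(0, order.size - 1, size).round().astype(int)
    return order[edges]


def run_cardiac_cycles(eat_map, n_cycles: int = 32, config=None,
                       sample_dt: float = 1.0) -> HemoTrace:
    """Closed-loop mechanics for ``n_cycles`` beats driven by an EAT map.

    Subsamples the map to the configured ensemble size (stratified by EAT
    quantile), builds per-region Ca templates, and integrates myofilament +
    ventricle surrogates + Windkessel loop at a fixed 0.1 ms step.
    Warns (never aborts) if the end-diastolic volume has not converged.
    """
    import warnings
    from .config import RunConfig
    from .fixtures import make_ca_template

    cfg = config or RunConfig()
    cc = cfg.circulation
    mech = cfg.mechanics
    cl = float(cfg.cell["cycle_length"])

    circ = default_circulation()
    for name in ("sa", "sv", "pa", "pv"):
        blk = cc.get(name, {})
        comp = getattr(circ, name)
        for f in ("R", "C", "V", "V0"):
            if f in blk:
                setattr(comp, f, float(blk[f]))
    if cc.get("failing", True):
        circ = apply_failing_condition(circ)
    lv, rv = default_ventricles()
    for vent, key in ((lv, "lv"), (rv, "rv")):
        for f, v in cc.get(key, {}).items():
            setattr(vent, f, float(v))

    myop = MyoParams(overrides=mech.get("myofilament", {}))
    mc = myop.constants()
    norm = _sovf_thick_nb(mc[16], mc[13], mc[14], mc[15]) * myop.postr_max()

    K = int(mech.get("ensemble_size", 128))
    idx = _stratified_ensemble(eat_map.eat, eat_map.geom, K)
    eat = eat_map.eat[idx].astype(np.float64)
    reg = (eat_map.geom.region[idx].astype(np.int64)
           if eat_map.geom is not None else np.full(idx.size, 2, np.int64))

    tmpl_dt = 1.0
    tmpls = [make_ca_template(r, cl, sample_dt=tmpl_dt) for r in
             ("endo", "mid", "epi")]
    M = len(tmpls[0].ca)
    tmpl_ca = np.stack([np.asarray(t.ca) for t in tmpls])

    dt = float(mech.get("dt", 0.1))
    n_steps = int(round(n_cycles * cl / dt))
    sample_every = max(1, int(round(sample_dt / dt)))
    n_samples = n_steps // sample_every
    out = np.empty((n_samples, 13))
    per_cycle = int(round(cl / sample_dt))
    atp_last = np.zeros((per_cycle, idx.size))
    tens_last = np.zeros((per_cycle, idx.size))

    circ.R_av = float(cc.get("R_av", circ.R_av))
    circ.R_mv = float(cc.get("R_mv", circ.R_mv))
    circ.R_tv = float(cc.get("R_tv", circ.R_tv))
    circ.R_pvalve = float(cc.get("R_pvalve", circ.R_pvalve))
    hc = np.array([
        circ.R_av + circ.sa.R, circ.R_mv, circ.R_tv,
        circ.R_pvalve + circ.pa.R, circ.sv.R, circ.pv.R,
        circ.sa.C, circ.sv.C, circ.pa.C, circ.pv.C,
        circ.sa.V0, circ.sv.V0, circ.pa.V0, circ.pv.V0,
        lv.B, lv.kappa, lv.V_rest, lv.alpha, lv.V_ref,
        rv.B, rv.kappa, rv.V_rest, rv.alpha, rv.V_ref,
        float(mech.get("SL_ref", 2.15)), float(mech.get("V_SL_ref", 89.0)),
        1.0 if mech.get("sl_feedback", True) else 0.0,
        float(mech.get("V_SL_ref_rv", 110.0)),
        float(mech.get("force_len_lo", 1.55)),
        float(mech.get("force_len_hi", 1.95)),
        float(mech.get("V_floor", 5.0)),
        float(mech.get("series_rate", 0.03)),
        float(mech.get("series_recoil", 0.02)),
    ])
    vols = np.array([float(mech.get("V_lv_init", 120.0)),
                     float(mech.get("V_rv_init", 120.0)),
                     circ.sa.V, circ.sv.V, circ.pa.V, circ.pv.V])
    v_init = vols.sum()
    my = np.tile(MyoState().vector(), (idx.size, 1))
    my_rv = MyoState().vector()
    eat_rv = float(np.mean(eat))
    delta = np.zeros(idx.size)
    _run_mech_circ(my, eat, reg, my_rv, eat_rv, delta, tmpl_ca, tmpl_dt,
                   cl, mc, dt, n_steps, hc, vols, sample_every, out,
                   atp_last, tens_last, (n_cycles - 1) * cl, norm,
                   myop.g_xbT)
    v_final = vols.sum()

    trace = HemoTrace(
        t=out[:, 0], P_lv=out[:, 1], V_lv=out[:, 2], P_rv=out[:, 3],
        V_rv=out[:, 4], P_sa=out[:, 5], P_sv=out[:, 6], P_pa=out[:, 7],
        P_pv=out[:, 8], tension=out[:, 9], SL=out[:, 10],
        valve_av=out[:, 11].astype(bool), valve_mv=out[:, 12].astype(bool),
        cycle_length=cl, n_cycles=n_cycles, atp_last=atp_last,
        tension_last=tens_last, eat_nodes=eat,
        total_volume=(float(v_init), float(v_final)))
    chk = steady_state_check(trace)
    if not chk["converged"]:
        warnings.warn(f"EDV not converged after {n_cycles} cycles "
                      f"(drift {chk['drift']:.3f}%)")
    return trace


def steady_state_check(trace: HemoTrace) -> dict:
    """Cycle-to-cycle end-diastolic-volume drift of the last two cycles."""
    if trace.n_cycles < 3:
        raise ValueError("need at least 3 cycles")
    edv = trace.edv_per_cycle()
    drift = abs(edv[-1] - edv[-2]) / edv[-2] * 100.0
    return {"converged": bool(drift < 0.1), "drift": float(drift)}
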