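"""Cross-bridge myofilament dynamics, active tension and contractile ATP rate.

Rice-style mean-field model of cooperative thin-filament activation and
cross-bridge cycling.  Regulatory units are non-permissive (N) or permissive
(P); permissive units bind myosin into a pre-rotation state (XB_PreR) that
isomerizes to the force-bearing post-rotation state (XB_PostR); detachment
from XB_PostR (rate g_xbT) hydrolyses one ATP.  The regulatory pool
N + P + XB_PreR + XB_PostR is conserved.

Sarcomere geometry enters through the thick-filament single-overlap fraction
SOVF_Thick(SL); the contractile ATP consumption rate is the detachment flux
through the overlap:  rate = g_xbT * SOVF_Thick (scaled by the attached
post-rotation fraction; the flux convention is configurable).

Calcium activates the thin filament by binding troponin (low-affinity
regulatory site TropCaL, high-affinity site TropCaH); the permissive
transition rate is a steep Hill-type function of TropCaL.  The troponin
affinity and half-activation are calibrated so that the ventricular ionic
model's Ca transient (diastolic ~0.1 uM, peak ~1 uM) spans the activation
range; see docs/constants.md.

Driving is one-way: Ca_i(t) is prescribed (an activation-time-shifted
template extracted from a converged single-cell run); mechanics never feeds
back into the electrophysiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MyoParams", "MyoState", "CaTransientTemplate", "TensionTrace",
    "sovf_thick", "step_myofilament", "active_tension", "atp_rate",
    "shifted_ca_drive", "integrate_atp", "run_twitch",
]

SL_MIN, SL_MAX = 1.4, 2.4  # um, physiological sarcomere-length range

# constants vector layout (rates in 1/ms, Ca in mM, lengths in um)
MC_NAMES = (
    "kon", "koffL", "koffH", "perm50", "nperm", "knp", "kpn", "inprmt_cap",
    "fapp", "gapp", "hf", "hb", "gxb",
    "len_thick", "len_hbare", "len_thin", "SL_ref",
)
_DEFAULT_MC = {
    "kon": 150.0,        # 1/(mM ms): Kd_L = koffL/kon = 1.67 uM
    "koffL": 0.25,       # 1/ms, low-affinity (regulatory) troponin off-rate
    "koffH": 0.015,      # 1/ms, high-affinity troponin off-rate
    "perm50": 0.5,       # TropCaL fraction at half-permissiveness
    "nperm": 10.0,       # Hill steepness of cooperative activation
    "knp": 0.5,          # 1/ms, base non-permissive -> permissive rate
    "kpn": 0.05,         # 1/ms, base permissive -> non-permissive rate
    "inprmt_cap": 100.0, # cap on the 1/permtot factor multiplying kpn
    "fapp": 0.5,         # 1/ms, attachment P -> XB_PreR
    "gapp": 0.07,        # 1/ms, detachment XB_PreR -> P
    "hf": 2.0,           # 1/ms, rotation XB_PreR -> XB_PostR
    "hb": 0.4,           # 1/ms, reverse rotation
    "gxb": 0.07,         # 1/ms, ATP-consuming detachment XB_PostR -> P
    "len_thick": 1.65,   # um thick filament
    "len_hbare": 0.1,    # um bare zone
    "len_thin": 1.2,     # um thin filament
    "SL_ref": 2.2,       # um, tension normalization length
}


@dataclass(frozen=True)
class MyoParams:
    overrides: dict = field(default_factory=dict)
    weight_attached: bool = True  # ATP flux weighted by XB_PostR (documented)

    def __post_init__(self):
        for k in self.overrides:
            if k not in MC_NAMES:
                raise KeyError(f"unknown myofilament constant {k!r}")

    def constants(self) -> np.ndarray:
        d = dict(_DEFAULT_MC, **self.overrides)
        return np.array([d[k] for k in MC_NAMES], dtype=np.float64)

    @property
    def g_xbT(self) -> float:
        """Cross-bridge detachment rate in 1/s (the Eq-6 kinetic factor)."""
        return float(dict(_DEFAULT_MC, **self.overrides)["gxb"]) * 1000.0

    def postr_max(self) -> float:
        """Steady post-rotation fraction of a fully permissive filament
        (closed-form solution of the 3-state cycle); tension normalization."""
        c = dict(_DEFAULT_MC, **self.overrides)
        f, g, hf, hb, gxb = c["fapp"], c["gapp"], c["hf"], c["hb"], c["gxb"]
        post_per_pre = hf / (hb + gxb)
        pre_per_p = f / (g + hf - hb * post_per_pre)
        post_per_p = post_per_pre * pre_per_p
        return post_per_p / (1.0 + pre_per_p + post_per_p)


@dataclass
class MyoState:
    """Regulatory / cross-bridge state of one myofilament node."""

    N_xB: float = 1.0
    P_xB: float = 0.0
    XB_PreR: float = 0.0
    XB_PostR: float = 0.0
    trop_ca_L: float = 0.0
    trop_ca_H: float = 0.0
    SL: float = 2.0                      # um

    def vector(self) -> np.ndarray:
        return np.array([self.N_xB, self.P_xB, self.XB_PreR, self.XB_PostR,
                         self.trop_ca_L, self.trop_ca_H])

    @classmethod
    def from_vector(cls, y: np.ndarray, SL: float) -> "MyoState":
        return cls(N_xB=y[0], P_xB=y[1], XB_PreR=y[2], XB_PostR=y[3],
                   trop_ca_L=y[4], trop_ca_H=y[5], SL=SL)

    @property
    def pool(self) -> float:
        return self.N_xB + self.P_xB + self.XB_PreR + self.XB_PostR

    def sovf_thick(self, params: MyoParams | None = None) -> float:
        return sovf_thick(self.SL, params or MyoParams())

    # Eq-6 field aliases
    @property
    def SOVF_Thick(self) -> float:
        return self.sovf_thick()

    def g_xbT(self, params: MyoParams | None = None) -> float:
        return (params or MyoParams()).g_xbT


def sovf_thick(SL: float, params: MyoParams | None = None) -> float:
    """Single-overlap fraction of the thick filament at sarcomere length SL."""
    c = (params or MyoParams()).constants()
    lt, hb, ln = c[13], c[14], c[15]
    sovr_ze = min(lt / 2.0, SL / 2.0)
    sovr_cle = max(SL / 2.0 - (SL - ln), hb / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    return 2.0 * len_sovr / (lt - hb)


@njit(cache=True, fastmath=True)
def _sovf_thick_nb(SL, lt, hb, ln):
    sovr_ze = min(lt / 2.0, SL / 2.0)
    sovr_cle = max(SL / 2.0 - (SL - ln), hb / 2.0)
    d = sovr_ze - sovr_cle
    if d < 0.0:
        d = 0.0
    return 2.0 * d / (lt - hb)


@njit(cache=True, fastmath=True)
def _myo_rhs(y, ca, mc, dy):
    """Right-hand side of the 6-state myofilament ODE (rates 1/ms)."""
    N = y[0]; P = y[1]; pre = y[2]; post = y[3]
    tl = y[4]; th = y[5]

    dy[4] = mc[0] * ca * (1.0 - tl) - mc[1] * tl
    dy[5] = mc[0] * ca * (1.0 - th) - mc[2] * th

    ratio = tl / mc[3] if tl > 1e-12 else 1e-12 / mc[3]
    permtot = np.sqrt(1.0 / (1.0 + ratio ** (-mc[4])))
    inprmt = 1.0 / permtot
    if inprmt > mc[7]:
        inprmt = mc[7]
    knpT = mc[5] * permtot
    kpnT = mc[6] * inprmt

    fapp = mc[8]; gapp = mc[9]; hf = mc[10]; hb = mc[11]; gxb = mc[12]
    dy[0] = kpnT * P - knpT * N
    dy[1] = knpT * N - kpnT * P + gapp * pre + gxb * post - fapp * P
    dy[2] = fapp * P + hb * post - (gapp + hf) * pre
    dy[3] = hf * pre - (hb + gxb) * post


@njit(cache=True, fastmath=True)
def _myo_step(y, ca, dt, mc, dy):
    # plain Euler: the four pool fluxes cancel pairwise, so the update
    # conserves N + P + XB_PreR + XB_PostR to roundoff (no clamping)
    _myo_rhs(y, ca, mc, dy)
    for k in range(6):
        y[k] += dt * dy[k]


def step_myofilament(state: MyoState, Ca_i: float, SL: float | None = None,
                     dt: float = 0.1, params: MyoParams | None = None) -> MyoState:
    """Advance one myofilament node by ``dt`` ms under cytosolic ``Ca_i`` (mM)."""
    params = params or MyoParams()
    SL = state.SL if SL is None else SL
    if not (SL_MIN <= SL <= SL_MAX):
        raise ValueError(f"SL={SL} um outside [{SL_MIN}, {SL_MAX}]")
    if Ca_i < 0:
        raise ValueError("Ca_i must be >= 0")
    y = state.vector()
    dy = np.empty(6)
    _myo_step(y, Ca_i, dt, params.constants(), dy)
    return MyoState.from_vector(y, SL)


def active_tension(state: MyoState, params: MyoParams | None = None) -> float:
    """Normalized active tension: overlap-weighted post-rotation fraction.

    Pre-rotation bridges carry zero mean strain at fixed length, so tension
    reduces to SOVF_Thick(SL) * XB_PostR, normalized by the fully permissive
    steady state at the reference length.
    """
    params = params or MyoParams()
    c = params.constants()
    norm = _sovf_thick_nb(c[16], c[13], c[14], c[15]) * params.postr_max()
    return sovf_thick(state.SL, params) * state.XB_PostR / norm


def atp_rate(state: MyoState, params: MyoParams | None = None) -> float:
    """Contractile ATP consumption rate (1/s): g_xbT * SOVF_Thick.

    With ``params.weight_attached`` (default) the product is scaled by the
    attached post-rotation fraction, i.e. the actual detachment flux through
    the single-overlap region; without it the bare product is returned.
    """
    params = params or MyoParams()
    rate = params.g_xbT * sovf_thick(state.SL, params)
    if params.weight_attached:
        rate *= state.XB_PostR
    return rate


@dataclass
class CaTransientTemplate:
    """One cycle of the cytosolic Ca transient (mM vs ms) for one region."""

    t: np.ndarray
    ca: np.ndarray
    cycle_length: float
    region: str = "epi"

    def __post_init__(self):
        if np.any(self.ca < 0):
            raise ValueError("Ca template must be nonnegative")
        amp = self.ca.max() - self.ca.min()
        if amp > 0 and abs(self.ca[-1] - self.ca[0]) > 0.05 * amp:
            raise ValueError("Ca template does not return to diastolic level "
                             "within 5% by cycle end")

    @property
    def diastolic(self) -> float:
        return float(self.ca[0])

    def __call__(self, tau):
        return np.interp(np.mod(tau, self.cycle_length), self.t, self.ca)


def shifted_ca_drive(template: CaTransientTemplate, eat: float, t):
    """Ca_i at absolute time ``t`` for a node activated at ``eat`` (ms).

    Before its first activation the node sits at the diastolic level; after
    that the template repeats with period ``cycle_length``.
    """
    if np.isnan(eat):
        raise ValueError("node has no activation time (absent EAT)")
    t = np.asarray(t, dtype=float)
    out = np.where(t < eat, template.diastolic, template(t - eat))
    return float(out) if out.ndim == 0 else out


@dataclass
class TensionTrace:
    """Active tension and ATP rate of one node over time."""

    t: np.ndarray
    tension: np.ndarray      # normalized
    atp: np.ndarray          # 1/s

    def __post_init__(self):
        if np.any(self.tension < -1e-12) or np.any(self.atp < -1e-12):
            raise ValueError("tension and ATP rate must be nonnegative")


def integrate_atp(traces, cycle_length: float) -> float:
    """Cycle-averaged, node-summed ATP rate (1/s).

    Each trace's rate is integrated over the final ``cycle_length`` ms by
    trapezoid and divided by the cycle duration; node contributions add.
    """
    total = 0.0
    for tr in traces:
        t, a = np.asarray(tr.t, float), np.asarray(tr.atp, float)
        if t[-1] - t[0] < cycle_length - 1e-9:
            raise ValueError("trace shorter than one cycle")
        sel = t >= t[-1] - cycle_length
        total += np.trapezoid(a[sel], t[sel]) / cycle_length
    return float(total)


def run_twitch(template: CaTransientTemplate, eat: float = 0.0,
               n_cycles: int = 2, dt: float = 0.1, SL: float = 2.0,
               params: MyoParams | None = None, sample_dt: float = 1.0
               ) -> TensionTrace:
    """Drive one node with the shifted Ca template for ``n_cycles`` cycles."""
    params = params or MyoParams()
    mc = params.constants()
    cl = template.cycle_length
    n_steps = int(round(n_cycles * cl / dt))
    every = max(1, int(round(sample_dt / dt)))
    y = MyoState(SL=SL).vector()
    dy = np.empty(6)
    ts, tens, atps = [], [], []
    sv = sovf_thick(SL, params)
    norm = _sovf_thick_nb(mc[16], mc[13], mc[14], mc[15]) * params.postr_max()
    gxbs = params.g_xbT
    for step in range(n_steps):
        t = step * dt
        ca = template.diastolic if t < eat else float(template(t - eat))
        _myo_step(y, ca, dt, mc, dy)
        if (step + 1) % every == 0:
            ts.append(t + dt)
            tens.append(sv * y[3] / norm)
            atps.append(gxbs * sv * y[3])
    return TensionTrace(t=np.array(ts), tension=np.array(tens),
                        atp=np.array(atps))


@njit(cache=True)
def _myo_ode_rhs(t, y, ca_t, ca_v, cl, mc):
    """Adaptive-integrator RHS with interpolated Ca drive (oracle path)."""
    dy = np.empty(6)
    ca = np.interp(t % cl, ca_t, ca_v)
    _myo_rhs(y, ca, mc, dy)
    return dy


def run_twitch_reference(template: CaTransientTemplate, n_cycles: int = 2,
                         SL: float = 2.0, params: MyoParams | None = None,
                         rtol: float = 1e-9, atol: float = 1e-12,
                         sample_dt: float = 1.0) -> TensionTrace:
    """Reference twitch via scipy's adaptive LSODA on the same equations."""
    from scipy.integrate import solve_ivp
    params = params or MyoParams()
    mc = params.constants()
    cl = template.cycle_length
    tmax = n_cycles * cl
    y0 = MyoState(SL=SL).vector()
    sol = solve_ivp(_myo_ode_rhs, (0.0, tmax), y0, method="LSODA",
                    args=(template.t, template.ca, cl, mc),
                    rtol=rtol, atol=atol, max_step=1.0,
                    t_eval=np.arange(sample_dt, tmax + 1e-9, sample_dt))
    if not sol.success:
        raise RuntimeError(sol.message)
    sv = sovf_thick(SL, params)
    norm = sovf_thick(mc[16], params) * params.postr_max()
    return TensionTrace(t=sol.t, tension=sv * sol.y[3] / norm,
                        atp=params.g_xbT * sv * sol.y[3])
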