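"""Monodomain action-potential propagation on regular-grid fixtures.

Tissue potential obeys dV/dt = -(I_ion + I_stim) + sum_a D_a d2V/dxa2 with
per-axis diffusion coefficients D_a = 1/(rho_a * S_a * Cm): cellular
resistivity rho (Ohm cm), surface-to-volume ratio S (1/cm), membrane
capacitance Cm (uF/cm^2); Ohm * F = s, so D carries cm^2/ms after the ms
conversion.  Integration is operator-split per step (reaction via the ionic
model's Rush-Larsen step, then an explicit second-order Laplacian with
zero-flux boundaries implemented by mirror neighbors).

Conduction velocity is measured as distance over activation-time difference
between two activated points, and resistivity is calibrated to a target
velocity by bisection (planar-wave CV is strictly decreasing in rho).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .ionic import (
    _step_node, _step_node_tab, build_voltage_tables,
    CellParams, CellState, N_STATES, _INITIAL_STATE,
    _REGION_GTO, _REGION_GKS, _REGION_SVAR, REGIONS, DT_STABILITY_LIMIT,
)

__all__ = [
    "TissueParams", "TissueGeometry", "FieldState", "EATMap", "TissueRun",
    "diffusion_coefficients", "step_tissue", "run_tissue_paced",
    "activation_map", "eat_duration", "measure_cv", "cable_cv",
    "calibrate_resistivity",
]

REGION_CODES = {name: i for i, name in enumerate(REGIONS)}


@dataclass(frozen=True)
class TissueParams:
    """Monodomain conductivity parameters (per-axis)."""

    rho: tuple = (162.0, 162.0, 162.0)   # Ohm cm
    S: tuple = (2000.0, 2000.0, 2000.0)  # 1/cm
    Cm: float = 2.0                      # uF/cm^2
    dt: float = 0.02                     # ms
    threshold: float = 0.0               # mV, activation threshold

    def __post_init__(self):
        if self.Cm <= 0 or any(r <= 0 for r in self.rho) or any(s <= 0 for s in self.S):
            raise ValueError("rho, S and Cm must all be positive")

    def with_rho(self, rho: float | tuple) -> "TissueParams":
        r = (rho,) * 3 if np.isscalar(rho) else tuple(rho)
        return TissueParams(rho=r, S=self.S, Cm=self.Cm, dt=self.dt,
                            threshold=self.threshold)


def diffusion_coefficients(params: TissueParams) -> np.ndarray:
    """Per-axis D_a = 1/(rho_a S_a Cm) in cm^2/ms.

    rho [Ohm cm] * S [1/cm] * Cm [uF/cm^2] = 1e-6 s/cm^2, hence
    D = 1e6 / (rho S Cm) cm^2/s = 1e3 / (rho S Cm) cm^2/ms.
    """
    D = np.array([1e3 / (r * s * params.Cm)
                  for r, s in zip(params.rho, params.S)])
    if not np.all(np.isfinite(D)) or np.any(D <= 0):
        raise ValueError("diffusion coefficients must be positive and finite")
    return D


@dataclass
class TissueGeometry:
    """Nodes of a regular Cartesian grid fixture with transmural labels."""

    coords: np.ndarray          # (n, 3) cm
    dx: float                   # cm, uniform per axis
    ndim: int
    region: np.ndarray          # (n,) int8 codes into REGIONS
    nbr: np.ndarray             # (n, 2*ndim) int32, -1 = boundary (no-flux)
    kind: str = "custom"
    endocardial: np.ndarray | None = None  # bool mask of endocardial surface

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def region_names(self) -> np.ndarray:
        return np.array(REGIONS)[self.region]

    def adjacency(self):
        """Sparse lattice adjacency with edge length dx (for geodesics)."""
        from scipy import sparse
        rows, cols = [], []
        for a in range(self.nbr.shape[1]):
            m = self.nbr[:, a] >= 0
            rows.append(np.flatnonzero(m))
            cols.append(self.nbr[m, a])
        rows = np.concatenate(rows); cols = np.concatenate(cols)
        w = np.full(len(rows), self.dx)
        return sparse.csr_matrix((w, (rows, cols)),
                                 shape=(self.n_nodes, self.n_nodes))


@dataclass
class FieldState:
    """Per-node cell states plus the simulation clock."""

    Y: np.ndarray               # (n, N_STATES)
    t: float = 0.0              # ms

    @classmethod
    def resting(cls, geom: TissueGeometry) -> "FieldState":
        Y = np.tile(_INITIAL_STATE, (geom.n_nodes, 1))
        return cls(Y=Y)


@dataclass
class EATMap:
    """Per-node electrical activation time for one cycle.

    ``eat`` is measured in ms from ``cycle_onset``; NaN marks nodes that
    never crossed ``threshold`` (absent, excluded from statistics).
    """

    eat: np.ndarray
    cycle_onset: float
    threshold: float
    geom: TissueGeometry | None = None

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.eat)

    def to_frame(self):
        import pandas as pd
        g = self.geom
        data = {"node_id": np.arange(len(self.eat))}
        if g is not None:
            data.update(x=g.coords[:, 0], y=g.coords[:, 1], z=g.coords[:, 2])
        data["eat_ms"] = self.eat
        return pd.DataFrame(data)


def eat_duration(emap: EATMap) -> float:
    """Activation duration: latest activation time relative to cycle onset.

    Convention: a tissue fully depolarized at t ms has an EAT duration of
    t ms (duration is max(EAT), not max - min).
    """
    if not emap.present.any():
        raise ValueError("EAT map has no activated node")
    return float(np.nanmax(emap.eat))


# ---------------------------------------------------------------------------
# stepping kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _tissue_steps(Y, gto, gks, svar, c, nbr, dcoef, dt, n_steps, t0,
                  stim_nodes, stim_onsets, stim_amp, stim_dur, cl,
                  sample_every, out_V, out_t):
    """Advance the whole field ``n_steps`` steps; record V every
    ``sample_every`` steps.  Returns blow-up step or -1."""
    n = Y.shape[0]
    n_pairs = nbr.shape[1] // 2
    inf = np.empty(13); tau = np.empty(13); cur = np.empty(15)
    istim = np.zeros(n)
    Vbuf = np.empty(n)
    ks = 0
    for step in range(n_steps):
        t = t0 + step * dt
        # stimulus schedule: each site fires once per cycle at its onset
        istim[:] = 0.0
        for si in range(len(stim_nodes)):
            tc = (t - stim_onsets[si]) % cl
            if 0.0 <= tc < stim_dur and t >= stim_onsets[si] - 1e-9:
                istim[stim_nodes[si]] = stim_amp
        # reaction
        for i in range(n):
            _step_node(Y[i], gto[i], gks[i], svar[i], c, istim[i], dt,
                       inf, tau, cur)
            if np.abs(Y[i, 0]) > 200.0:
                return step
        # diffusion (explicit, mirror/no-flux at missing neighbors)
        for i in range(n):
            Vbuf[i] = Y[i, 0]
        for i in range(n):
            lap = 0.0
            for a in range(n_pairs):
                vl = Vbuf[nbr[i, 2 * a]] if nbr[i, 2 * a] >= 0 else Vbuf[i]
                vr = Vbuf[nbr[i, 2 * a + 1]] if nbr[i, 2 * a + 1] >= 0 else Vbuf[i]
                lap += dcoef[a] * (vl + vr - 2.0 * Vbuf[i])
            Y[i, 0] += dt * lap
        if (step + 1) % sample_every == 0:
            for i in range(n):
                out_V[ks, i] = Y[i, 0]
            out_t[ks] = t0 + (step + 1) * dt
            ks += 1
    return -1


@njit(cache=True, fastmath=True)
def _tissue_steps_tab(Y, gto, gks, svar, c, VT, UT, nbr, dcoef, dt, n_steps,
                      t0, stim_nodes, stim_onsets, stim_amp, stim_dur, cl,
                      sample_every, out_V, out_t):
    """Same as ``_tissue_steps`` with the tabulated reaction step."""
    n = Y.shape[0]
    n_pairs = nbr.shape[1] // 2
    istim = np.zeros(n)
    Vbuf = np.empty(n)
    ks = 0
    for step in range(n_steps):
        t = t0 + step * dt
        istim[:] = 0.0
        for si in range(len(stim_nodes)):
            tc = (t - stim_onsets[si]) % cl
            if 0.0 <= tc < stim_dur and t >= stim_onsets[si] - 1e-9:
                istim[stim_nodes[si]] = stim_amp
        for i in range(n):
            _step_node_tab(Y[i], gto[i], gks[i], svar[i], c, istim[i], dt,
                           VT, UT)
            if np.abs(Y[i, 0]) > 200.0:
                return step
        for i in range(n):
            Vbuf[i] = Y[i, 0]
        for i in range(n):
            lap = 0.0
            for a in range(n_pairs):
                vl = Vbuf[nbr[i, 2 * a]] if nbr[i, 2 * a] >= 0 else Vbuf[i]
                vr = Vbuf[nbr[i, 2 * a + 1]] if nbr[i, 2 * a + 1] >= 0 else Vbuf[i]
                lap += dcoef[a] * (vl + vr - 2.0 * Vbuf[i])
            Y[i, 0] += dt * lap
        if (step + 1) % sample_every == 0:
            for i in range(n):
                out_V[ks, i] = Y[i, 0]
            out_t[ks] = t0 + (step + 1) * dt
            ks += 1
    return -1


def _node_params(geom: TissueGeometry, overrides: dict | None = None):
    gto = np.empty(geom.n_nodes)
    gks = np.empty(geom.n_nodes)
    svar = np.empty(geom.n_nodes, dtype=np.int64)
    ov = overrides or {}
    for code, name in enumerate(REGIONS):
        m = geom.region == code
        gto[m] = ov.get("g_to", _REGION_GTO[name])
        gks[m] = ov.get("g_Ks", _REGION_GKS[name])
        svar[m] = _REGION_SVAR[name]
    return gto, gks, svar


def _cfl_limit(tparams: TissueParams, geom: TissueGeometry) -> float:
    D = diffusion_coefficients(tparams)[:geom.ndim]
    return geom.dx ** 2 / (2.0 * D.sum())


def step_tissue(field: FieldState, geom: TissueGeometry,
                tparams: TissueParams, stim: np.ndarray | None = None,
                dt: float | None = None, ionic: bool = True) -> FieldState:
    """One operator-split step (reaction then diffusion) of the whole field.

    ``stim`` is a per-node I_stim array (pA/pF).  With ``ionic=False`` only
    the diffusion operator acts (used to test the conservative stencil).
    """
    dt = tparams.dt if dt is None else dt
    limit = min(_cfl_limit(tparams, geom), DT_STABILITY_LIMIT)
    if not 0 < dt <= limit:
        raise ValueError(f"dt={dt} ms violates the stability limit {limit:.4g} ms")
    Y = field.Y.copy()
    n = geom.n_nodes
    istim = np.zeros(n) if stim is None else np.asarray(stim, dtype=float)
    gto, gks, svar = _node_params(geom)
    c = CellParams().constants()
    inf = np.empty(13); tau = np.empty(13); cur = np.empty(15)
    if ionic:
        for i in range(n):
            _step_node(Y[i], gto[i], gks[i], svar[i], c, istim[i], dt,
                       inf, tau, cur)
    else:
        Y[:, 0] += -istim * dt
    D = diffusion_coefficients(tparams)
    Vb = Y[:, 0].copy()
    lap = np.zeros(n)
    for a in range(geom.ndim):
        left = geom.nbr[:, 2 * a]
        right = geom.nbr[:, 2 * a + 1]
        vl = np.where(left >= 0, Vb[np.maximum(left, 0)], Vb)
        vr = np.where(right >= 0, Vb[np.maximum(right, 0)], Vb)
        lap += D[a] / geom.dx ** 2 * (vl + vr - 2 * Vb)
    Y[:, 0] = Vb + dt * lap
    return FieldState(Y=Y, t=field.t + dt)


@dataclass
class TissueRun:
    """Recorded tissue simulation: sampled V field plus per-cycle EAT maps."""

    t: np.ndarray               # (n_samples,)
    V: np.ndarray               # (n_samples, n_nodes) float32
    geom: TissueGeometry
    cycle_length: float
    eat_maps: list = field(default_factory=list)

    @property
    def final_eat(self) -> EATMap:
        return self.eat_maps[-1]

    def save_npz(self, path):
        """Compact binary container for the sampled field (time-indexed)."""
        np.savez_compressed(path, t=self.t, V=self.V,
                            coords=self.geom.coords,
                            cycle_length=self.cycle_length)


def run_tissue_paced(geom: TissueGeometry, tparams: TissueParams,
                     protocol, duration: float, sample_dt: float = 1.0,
                     clamp_stim_sites: bool = True,
                     initial: FieldState | None = None,
                     tabulated: bool = True) -> TissueRun:
    """Paced monodomain run; extracts an EAT map for every complete cycle.

    ``protocol`` needs fields ``site_nodes``, ``site_onsets`` (ms),
    ``cycle_length``, ``amplitude``, ``duration`` (stimulus).  Stimulated
    Purkinje-terminal nodes are assigned their onset as activation time when
    ``clamp_stim_sites`` (they are fired directly by the conduction system);
    all other nodes activate at their first threshold crossing.
    """
    stim_nodes = getattr(protocol, "stim_nodes", ()) or protocol.site_nodes
    stim_onsets = (getattr(protocol, "stim_onsets", ())
                   or protocol.site_onsets)
    sites = np.asarray(stim_nodes, dtype=np.int32)
    if sites.size == 0:
        raise ValueError("protocol has no stimulus sites")
    if sites.min() < 0 or sites.max() >= geom.n_nodes:
        raise ValueError("stimulus sites outside the geometry")
    dt = tparams.dt
    limit = min(_cfl_limit(tparams, geom), DT_STABILITY_LIMIT)
    if dt > limit:
        raise ValueError(f"dt={dt} ms violates the stability limit {limit:.4g} ms")

    fld = initial or FieldState.resting(geom)
    Y = fld.Y.copy()
    gto, gks, svar = _node_params(geom)
    c = CellParams().constants()
    D = diffusion_coefficients(tparams) / geom.dx ** 2
    n_steps = int(round(duration / dt))
    sample_every = max(1, int(round(sample_dt / dt)))
    n_samples = n_steps // sample_every
    out_V = np.empty((n_samples, geom.n_nodes), dtype=np.float32)
    out_t = np.empty(n_samples)
    onsets64 = np.asarray(stim_onsets, dtype=np.float64)
    if tabulated:
        VT, UT = build_voltage_tables(c, dt)
        blow = _tissue_steps_tab(
            Y, gto, gks, svar, c, VT, UT, geom.nbr, D[:geom.ndim], dt,
            n_steps, fld.t, sites, onsets64, protocol.amplitude,
            protocol.duration, protocol.cycle_length, sample_every,
            out_V, out_t)
    else:
        blow = _tissue_steps(
            Y, gto, gks, svar, c, geom.nbr, D[:geom.ndim], dt, n_steps,
            fld.t, sites, onsets64, protocol.amplitude, protocol.duration,
            protocol.cycle_length, sample_every, out_V, out_t)
    if blow >= 0:
        raise FloatingPointError(f"numerical blow-up at t={blow * dt:.2f} ms")

    run = TissueRun(t=out_t, V=out_V, geom=geom,
                    cycle_length=protocol.cycle_length)
    n_cycles = int(duration // protocol.cycle_length)
    base_onset = float(np.min(stim_onsets))
    for cyc in range(n_cycles):
        onset = cyc * protocol.cycle_length
        emap = activation_map(run, tparams.threshold, onset,
                              window=protocol.cycle_length)
        if clamp_stim_sites:
            emap.eat[sites] = np.asarray(stim_onsets) % protocol.cycle_length
        run.eat_maps.append(emap)
        # repolarization check at the next cycle onset
        if cyc + 1 < n_cycles:
            k = np.searchsorted(run.t, onset + protocol.cycle_length + base_onset)
            if k < len(run.t):
                bad = np.flatnonzero(run.V[k] > -60.0)
                if bad.size:
                    warnings.warn(
                        f"{bad.size} node(s) not repolarized before cycle "
                        f"{cyc + 2} (first: node {bad[0]})")
    return run


def activation_map(run: TissueRun, threshold: float, cycle_onset: float,
                   window: float | None = None) -> EATMap:
    """First upward threshold crossing per node after ``cycle_onset``.

    Crossing times are linearly interpolated between samples and reported
    relative to ``cycle_onset``; nodes that never cross are NaN-flagged.
    """
    t = run.t
    sel = t >= cycle_onset
    if window is not None:
        sel &= t < cycle_onset + window
    ts = t[sel]
    if ts.size < 2:
        raise ValueError("trace does not cover the requested cycle")
    V = run.V[sel]
    above = V > threshold
    crossed = ~above[:-1] & above[1:]
    eat = np.full(run.geom.n_nodes, np.nan)
    first = np.argmax(crossed, axis=0)
    has = crossed.any(axis=0)
    for i in np.flatnonzero(has):
        k = first[i]
        v0, v1 = V[k, i], V[k + 1, i]
        frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
        eat[i] = ts[k] + frac * (ts[k + 1] - ts[k]) - cycle_onset
    return EATMap(eat=eat, cycle_onset=cycle_onset, threshold=threshold,
                  geom=run.geom)


def measure_cv(emap: EATMap, point_a: int, point_b: int) -> float:
    """Conduction velocity (cm/s) between two activated nodes: MCV = d / t."""
    ta, tb = emap.eat[point_a], emap.eat[point_b]
    if np.isnan(ta) or np.isnan(tb):
        raise ValueError("both measurement points must be activated")
    if ta == tb:
        raise ValueError("equal activation times: conduction velocity undefined")
    d = float(np.linalg.norm(emap.geom.coords[point_a] - emap.geom.coords[point_b]))
    if d == 0.0:
        raise ValueError("measurement points coincide (d = 0)")
    return d / (abs(tb - ta) / 1000.0)


def cable_cv(geom: TissueGeometry, tparams: TissueParams,
             stim_amplitude: float = -80.0, stim_duration: float = 2.0,
             frac_a: float = 0.25, frac_b: float = 0.75,
             initial: FieldState | None = None,
             duration: float | None = None) -> float:
    """Planar CV on a 1D cable: stimulate one end, measure between the 25%
    and 75% positions (interior window avoids boundary/stimulus artifacts).

    The end stimulus covers five nodes (strong enough to capture even at
    high diffusivity, where a point source is drained by its neighbors).
    """
    from types import SimpleNamespace
    n = geom.n_nodes
    a, b = int(round(frac_a * (n - 1))), int(round(frac_b * (n - 1)))
    length = geom.dx * (n - 1)
    if duration is None:
        duration = 25.0 + length / 8.0 * 1000.0  # reach at >= 8 cm/s
    sites = list(range(min(5, n)))
    proto = SimpleNamespace(site_nodes=sites, site_onsets=[5.0] * len(sites),
                            cycle_length=duration * 2.0,
                            amplitude=stim_amplitude, duration=stim_duration)
    run = run_tissue_paced(geom, tparams, proto, duration, sample_dt=0.25,
                           clamp_stim_sites=False, initial=initial)
    emap = activation_map(run, tparams.threshold, 0.0)
    if np.isnan(emap.eat[a]) or np.isnan(emap.eat[b]):
        raise RuntimeError("conduction failure: wave did not reach the "
                           "measurement window")
    return measure_cv(emap, a, b)


def calibrate_resistivity(target_cv: float, geom: TissueGeometry,
                          tparams_template: TissueParams, tol: float = 0.01,
                          bracket: tuple = (60.0, 2500.0),
                          max_iter: int = 60) -> tuple:
    """Bisection on rho until measured cable CV is within ``tol`` (relative)
    of ``target_cv``.  Returns (rho, achieved_cv).

    CV is strictly decreasing in rho over the bracket (checked); targets
    below the conduction-failure limit are rejected with the failing rho.
    """
    lo, hi = bracket

    def cv_at(rho):
        return cable_cv(geom, tparams_template.with_rho(rho))

    cv_lo = cv_at(lo)
    try:
        cv_hi = cv_at(hi)
    except RuntimeError:
        # shrink the upper bracket to the largest conducting rho
        while hi / lo > 1.05:
            hi *= 0.7
            try:
                cv_hi = cv_at(hi)
                break
            except RuntimeError:
                continue
        else:
            raise
    if not cv_lo > cv_hi:
        raise RuntimeError("CV(rho) not decreasing over the bracket")
    if target_cv > cv_lo or target_cv < cv_hi:
        raise ValueError(
            f"target {target_cv} cm/s outside achievable range "
            f"[{cv_hi:.1f}, {cv_lo:.1f}] (conduction fails above rho={hi:.0f})")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log-rho (CV ~ rho^-1/2)
        cv_mid = cv_at(mid)
        if abs(cv_mid - target_cv) / target_cv <= tol:
            return float(mid), float(cv_mid)
        if cv_mid > target_cv:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("resistivity calibration did not converge")
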