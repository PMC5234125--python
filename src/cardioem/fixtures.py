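"""Synthetic fixture generators: geometries, pacing protocol, Ca templates.

Everything the analysis consumes is generated here, deterministically:

* regular-grid tissue fixtures (1D cable, 2D sheet, 2D annular shell, 3D
  slab) with endo/mid/epi transmural layers, standing in for an imaging-
  derived ventricular mesh;
* a Purkinje-surrogate sinus-pacing protocol: early-activation sites sampled
  on the endocardium (seeded), with per-site onsets set by a 200 cm/s
  conduction-system path speed from a 20 ms terminal onset;
* per-region cytosolic Ca-transient templates extracted from converged
  paced single-cell runs.

``reference_fixture_suite`` freezes the configurations used by the whole
analysis: a 2 cm epicardial cable for conduction-velocity work and an
annular shell + sinus protocol for the conduction-velocity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ionic import CellParams, StimulusProtocol, run_paced_cell
from .tissue import TissueGeometry, REGION_CODES

__all__ = [
    "FixtureSpec", "SinusProtocol", "make_geometry", "make_sinus_protocol",
    "make_ca_template", "reference_fixture_suite",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a grid fixture.

    ``dimensions``: cable (L,); sheet (Lx, Ly); slab (Lx, Ly, Lz);
    shell (r_inner, r_outer) -- a 2D annulus, the desk-scale stand-in for a
    short-axis ventricular section (endocardium at the inner radius).
    ``layers``: transmural (endo, mid, epi) thickness fractions, summing to 1.
    """

    kind: str = "cable"
    dimensions: tuple = (2.0,)
    dx: float = 0.025
    layers: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("cable", "sheet", "slab", "shell"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if abs(sum(self.layers) - 1.0) > 1e-9 or any(f < 0 for f in self.layers):
            raise ValueError("layer fractions must be nonnegative and sum to 1")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.kind != "shell":
            for L in self.dimensions:
                n = L / self.dx
                if abs(n - round(n)) > 1e-9:
                    raise ValueError(f"dx={self.dx} does not divide extent {L}")


def _depth_to_region(depth: np.ndarray, layers) -> np.ndarray:
    """Map transmural depth in [0,1] (0 = endo surface) to region codes."""
    e, m, _ = layers
    region = np.full(depth.shape, REGION_CODES["epi"], dtype=np.int8)
    region[depth < e + m] = REGION_CODES["mid"]
    region[depth < e] = REGION_CODES["endo"]
    if e == 0 and m == 0:
        region[:] = REGION_CODES["epi"]
    return region


def make_geometry(spec: FixtureSpec) -> TissueGeometry:
    """Build the node grid, transmural labels and lattice neighbors."""
    dx = spec.dx
    if spec.kind == "cable":
        n = int(round(spec.dimensions[0] / dx)) + 1
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * dx
        depth = coords[:, 0] / spec.dimensions[0]
        mask_shape, flat_ids = (n,), np.arange(n)
        ndim = 1
        endo = depth < spec.layers[0] if spec.layers[0] > 0 else (coords[:, 0] == 0)
    elif spec.kind in ("sheet", "slab"):
        dims = spec.dimensions
        ndim = len(dims)
        shape = tuple(int(round(L / dx)) + 1 for L in dims)
        grids = np.meshgrid(*[np.arange(s) * dx for s in shape], indexing="ij")
        coords = np.zeros((int(np.prod(shape)), 3))
        for a in range(ndim):
            coords[:, a] = grids[a].ravel()
        # transmural axis = last axis, endocardium at 0
        depth = coords[:, ndim - 1] / dims[-1]
        mask_shape, flat_ids = shape, np.arange(coords.shape[0])
        endo = depth <= spec.layers[0] + 1e-12
    else:  # shell: 2D annulus
        r_in, r_out = spec.dimensions
        if not 0 < r_in < r_out:
            raise ValueError("shell needs 0 < r_inner < r_outer")
        half = int(np.ceil(r_out / dx))
        ax = np.arange(-half, half + 1) * dx
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        r = np.sqrt(X ** 2 + Y ** 2)
        mask = (r >= r_in - 1e-12) & (r <= r_out + 1e-12)
        idx = np.flatnonzero(mask.ravel())
        coords = np.zeros((idx.size, 3))
        coords[:, 0] = X.ravel()[idx]
        coords[:, 1] = Y.ravel()[idx]
        rr = r.ravel()[idx]
        depth = (rr - r_in) / (r_out - r_in)
        mask_shape, flat_ids = mask.shape, idx
        ndim = 2
        endo = depth <= max(spec.layers[0] * 0.5, dx / (r_out - r_in)) + 1e-12
        region = _depth_to_region(depth, spec.layers)
        nbr = _grid_neighbors(mask_shape, flat_ids, ndim)
        return TissueGeometry(coords=coords, dx=dx, ndim=ndim, region=region,
                              nbr=nbr, kind=spec.kind, endocardial=endo)

    region = _depth_to_region(depth, spec.layers)
    nbr = _grid_neighbors(mask_shape, flat_ids, ndim)
    return TissueGeometry(coords=coords, dx=dx, ndim=ndim, region=region,
                          nbr=nbr, kind=spec.kind, endocardial=np.asarray(endo))


def _grid_neighbors(shape, flat_ids, ndim) -> np.ndarray:
    """(n, 2*ndim) lattice neighbor table; -1 where no neighbor exists."""
    size = int(np.prod(shape))
    lut = np.full(size, -1, dtype=np.int64)
    lut[flat_ids] = np.arange(len(flat_ids))
    multi = np.array(np.unravel_index(flat_ids, shape)).T  # (n, ndim)
    nbr = np.full((len(flat_ids), 2 * ndim), -1, dtype=np.int32)
    for a in range(ndim):
        for side, delta in ((0, -1), (1, +1)):
            m2 = multi.copy()
            m2[:, a] += delta
            ok = (m2[:, a] >= 0) & (m2[:, a] < shape[a])
            flat2 = np.ravel_multi_index(tuple(m2[ok].T), shape)
            col = np.full(len(flat_ids), -1, dtype=np.int32)
            col[ok] = lut[flat2].astype(np.int32)
            nbr[:, 2 * a + side] = col
    return nbr


@dataclass(frozen=True)
class SinusProtocol:
    """Purkinje-surrogate pacing: endocardial sites with path-delayed onsets.

    Each terminal site is stimulated as a small patch (``stim_nodes``,
    nodes within ``site_radius`` of the terminal) to avoid source-sink
    capture failure; every patch node inherits its terminal's onset.
    """

    site_nodes: tuple
    site_onsets: tuple            # ms (absolute within a cycle)
    site_distances: tuple         # cm, geodesic path from the earliest site
    stim_nodes: tuple = ()        # patch nodes actually stimulated
    stim_onsets: tuple = ()       # per patch node, ms
    site_radius: float = 0.05     # cm
    purkinje_speed: float = 200.0  # cm/s
    cycle_length: float = 600.0    # ms
    amplitude: float = -52.0       # pA/pF
    duration: float = 2.0          # ms
    onset: float = 20.0            # ms, terminal (earliest) onset

    def __post_init__(self):
        if abs(min(self.site_onsets) - self.onset) > 1e-12:
            raise ValueError("minimum site onset must equal the global onset")

    def implied_speed(self, i: int, j: int) -> float:
        """Path speed between two sites recovered from the generated onsets."""
        dd = abs(self.site_distances[i] - self.site_distances[j])
        dt = abs(self.site_onsets[i] - self.site_onsets[j])
        if dt == 0:
            raise ValueError("sites have identical onsets")
        return dd / (dt / 1000.0)


def make_sinus_protocol(geom: TissueGeometry, n_sites: int = 3,
                        onset: float = 20.0, purkinje_speed: float = 200.0,
                        seed: int = 2016, cycle_length: float = 600.0,
                        amplitude: float = -52.0, duration: float = 2.0,
                        site_radius: float = 0.05) -> SinusProtocol:
    """Sample Purkinje-terminal sites on the endocardium (seeded) and assign
    onsets = onset + path distance from the earliest site / purkinje_speed.

    Path distances are exact grid-graph geodesics (lattice Dijkstra), which
    respect the cavity of non-convex fixtures.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    endo = geom.endocardial
    if endo is None or not endo.any():
        raise ValueError("geometry has no endocardial nodes")
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(endo)
    if n_sites > pool.size:
        raise ValueError("more sites requested than endocardial nodes")
    sites = rng.choice(pool, size=n_sites, replace=False)

    from scipy.sparse.csgraph import dijkstra
    all_dist = dijkstra(geom.adjacency(), indices=sites[0])
    dist = all_dist[sites]
    onsets = onset + dist / purkinje_speed * 1000.0
    # expand each terminal into its stimulation patch
    site_dist = dijkstra(geom.adjacency(), indices=sites)
    stim_nodes, stim_onsets = [], []
    owner = np.argmin(site_dist, axis=0)
    for k in range(n_sites):
        patch = np.flatnonzero((site_dist[k] <= site_radius + 1e-12)
                               & (owner == k))
        stim_nodes.extend(int(i) for i in patch)
        stim_onsets.extend([float(onsets[k])] * patch.size)
    return SinusProtocol(site_nodes=tuple(int(s) for s in sites),
                         site_onsets=tuple(float(o) for o in onsets),
                         site_distances=tuple(float(d) for d in dist),
                         stim_nodes=tuple(stim_nodes),
                         stim_onsets=tuple(stim_onsets),
                         site_radius=site_radius,
                         purkinje_speed=purkinje_speed,
                         cycle_length=cycle_length, amplitude=amplitude,
                         duration=duration, onset=onset)


_TEMPLATE_CACHE: dict = {}


def make_ca_template(region: str = "epi", cycle_length: float = 600.0,
                     n_prebeats: int = 20, sample_dt: float = 1.0,
                     params: CellParams | None = None):
    """Final-beat Ca_i trace of a converged paced cell, on a fixed grid.

    Rejects non-converged transients (beat-to-beat diastolic drift > 2%).
    Templates are cached per (region, cycle length, pre-beats).
    """
    from .myofilament import CaTransientTemplate

    key = (region, cycle_length, n_prebeats, sample_dt) if params is None else None
    if key is not None and key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]

    p = params or CellParams(region=region)
    proto = StimulusProtocol(cycle_length=cycle_length, n_beats=n_prebeats + 1)
    trace = run_paced_cell(p, proto, sample_dt=sample_dt)
    per_beat = int(round(cycle_length / sample_dt))
    last = trace.Ca_i[-per_beat:]
    prev = trace.Ca_i[-2 * per_beat:-per_beat]
    drift = abs(last[0] - prev[0]) / max(prev[0], 1e-12)
    if drift > 0.02:
        raise RuntimeError(
            f"Ca transient not converged: diastolic drift {100 * drift:.2f}%")
    # roll so the template starts at the pre-stimulus diastolic sample
    t = np.arange(per_beat) * sample_dt
    tmpl = CaTransientTemplate(t=t, ca=last.copy(), cycle_length=cycle_length,
                               region=region)
    if key is not None:
        _TEMPLATE_CACHE[key] = tmpl
    return tmpl


def reference_fixture_suite() -> dict:
    """The frozen fixture configurations used by the whole analysis.

    * ``cv_cable``: 2 cm epicardial cable, dx = 0.025 cm, with the 162
      Ohm cm resistivity preset of the 70 cm/s condition.
    * ``sweep_shell``: annular shell (r = 0.55..0.80 cm, dx = 0.025 cm,
      endo/mid/epi fractions 0.3/0.4/0.3) plus the default sinus protocol
      (2 sites, terminal onset 20 ms, path speed 200 cm/s, CL 600 ms).
    * ``rho_multipliers``: the documented resistivity-multiplier preset for
      the 60/50/40/30 cm/s conditions (not assumed to reproduce those
      velocities on the fixtures; calibration is used instead).
    """
    return {
        "cv_cable": {
            "spec": FixtureSpec(kind="cable", dimensions=(2.0,), dx=0.025,
                                layers=(0.0, 0.0, 1.0)),
            "rho_preset": 162.0,
        },
        "sweep_shell": {
            "spec": FixtureSpec(kind="shell", dimensions=(0.55, 0.80),
                                dx=0.025, layers=(0.3, 0.4, 0.3)),
            "protocol": {"n_sites": 2, "onset": 20.0, "purkinje_speed": 200.0,
                         "seed": 2016, "cycle_length": 600.0},
        },
        "rho_multipliers": {70: 1.0, 60: 1.25, 50: 1.67, 40: 2.5, 30: 3.3},
    }
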