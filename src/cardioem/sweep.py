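"""The conduction-velocity experiment: five MCV conditions end-to-end.

For each target myocardial conduction velocity (default 30..70 cm/s), the
sweep calibrates cellular resistivity on the reference cable, runs the
paced monodomain shell for 3 s (cycle length 600 ms), extracts the
last-cycle activation map, drives 32 mechanical cycles of the coupled
myofilament / circulation model, and reduces the final cycle to the
metrics of interest: EAT duration, systolic and mean arterial pressure,
EDV / ESV / SV / EF, stroke work, cycle ATP consumption, and the pumping-
efficiency index SW/ATP.  The monotonicity report checks the expected
directions of all nine metrics across ascending MCV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import RunConfig
from .tissue import (TissueParams, calibrate_resistivity, run_tissue_paced,
                     eat_duration)
from .fixtures import FixtureSpec, make_geometry, make_sinus_protocol
from .hemodynamics import run_cardiac_cycles, HemoTrace
from .myofilament import TensionTrace, integrate_atp

__all__ = [
    "CycleMetrics", "SweepCondition", "SweepResult", "pv_metrics",
    "sw_per_atp", "run_mcv_sweep", "monotonicity_report",
    "EXPECTED_DIRECTIONS",
]

#: expected metric directions for increasing conduction velocity
EXPECTED_DIRECTIONS = {
    "eat_duration": "down", "EDV": "down", "ESV": "down",
    "systolic_P": "up", "SV": "up", "EF": "up", "SW": "up",
    "ATP": "down", "SW_per_ATP": "up",
}


@dataclass
class CycleMetrics:
    """Final-cycle summary of one condition."""

    eat_duration: float | None = None   # ms
    systolic_P: float = 0.0             # mmHg, max LV pressure
    MAP: float = 0.0                    # mmHg, mean systemic arterial
    EDV: float = 0.0                    # mL
    ESV: float = 0.0                    # mL
    SV: float = 0.0                     # mL  (= EDV - ESV, exact)
    EF: float = 0.0                     # %   (= 100 SV / EDV, exact)
    SW: float = 0.0                     # mmHg mL, PV-loop area
    ATP: float | None = None            # 1/s, node-summed cycle average
    SW_per_ATP: float | None = None     # mmHg mL / ATP
    loop_gap: float = 0.0               # mL, |V(end) - V(start)| of the loop

    def as_dict(self) -> dict:
        return asdict(self)


def pv_metrics(trace: HemoTrace, atp: float | None = None) -> CycleMetrics:
    """Reduce the final cycle of a closed-loop run to pressure-volume
    metrics: EDV/ESV are the extremes of LV volume, SV = EDV - ESV,
    EF = 100 SV / EDV, SW is the PV-loop area and MAP the time average of
    systemic arterial pressure.  A non-closed loop (volume drift) attaches
    a warning but still reports.
    """
    fc = trace.final_cycle()
    V, P = np.asarray(fc["V_lv"]), np.asarray(fc["P_lv"])
    edv = float(V.max())
    esv = float(V.min())
    sv = edv - esv
    ef = 100.0 * sv / edv
    gap = float(abs(V[-1] - V[0]))
    if gap > 0.01 * max(sv, 1e-9):
        warnings.warn(f"PV loop not closed: volume drift {gap:.3g} mL")
    # loop area by the shoelace formula on the closed polygon
    Vc = np.append(V, V[0]); Pc = np.append(P, P[0])
    sw = float(abs(np.sum(Pc[:-1] * np.diff(Vc)
                          + 0.5 * np.diff(Pc) * np.diff(Vc))))
    m = CycleMetrics(systolic_P=float(P.max()),
                     MAP=float(np.mean(fc["P_sa"])),
                     EDV=edv, ESV=esv, SV=sv, EF=ef, SW=sw, loop_gap=gap)
    if atp is not None:
        m.ATP = float(atp)
        m.SW_per_ATP = sw_per_atp(m)
    return m


def sw_per_atp(metrics: CycleMetrics) -> float:
    """Pumping-efficiency index: stroke work per cycle ATP consumption."""
    if not metrics.ATP or metrics.ATP <= 0:
        raise ValueError("ATP consumption must be positive")
    return metrics.SW / metrics.ATP


def cycle_atp(trace: HemoTrace) -> float:
    """Node-summed, cycle-averaged ATP rate (1/s) of the final cycle."""
    t = np.arange(trace.atp_last.shape[0], dtype=float)
    traces = [TensionTrace(t=t, tension=trace.tension_last[:, k],
                           atp=trace.atp_last[:, k])
              for k in range(trace.atp_last.shape[1])]
    return integrate_atp(traces, float(t[-1] - t[0]))


@dataclass
class SweepCondition:
    """One MCV condition with its calibration and results."""

    target_cv: float                    # cm/s
    rho: float | None = None            # Ohm cm, calibrated
    achieved_cv: float | None = None    # cm/s on the reference cable
    metrics: CycleMetrics | None = None
    failed: bool = False
    failure_reason: str = ""
    eat_map: object = None
    hemo: HemoTrace | None = None


@dataclass
class SweepResult:
    """Per-condition metric table plus the trend analysis."""

    conditions: list = field(default_factory=list)
    trends: list = field(default_factory=list)
    config_hash: str = ""

    def completed(self):
        return [c for c in self.conditions if not c.failed]

    def to_frame(self):
        import pandas as pd
        rows = []
        for c in self.completed():
            row = {"MCV": c.target_cv, "rho": c.rho,
                   "achieved_cv": c.achieved_cv}
            row.update(c.metrics.as_dict())
            rows.append(row)
        if not rows:
            return pd.DataFrame(columns=["MCV", "rho", "achieved_cv"])
        return pd.DataFrame(rows).sort_values("MCV").reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"MCV": c.target_cv, "rho": c.rho,
                 "achieved_cv": c.achieved_cv, "failed": c.failed,
                 "failure_reason": c.failure_reason,
                 "metrics": c.metrics.as_dict() if c.metrics else None}
                for c in self.conditions],
            "trends": self.trends,
            "config_hash": self.config_hash,
        }


def run_mcv_sweep(conditions=None, config: RunConfig | None = None,
                  progress=None) -> SweepResult:
    """Run the full experiment over the given MCV conditions (cm/s).

    Deterministic end-to-end; a condition whose target velocity is below
    the conduction-failure limit is flagged and excluded, the sweep
    continues.
    """
    cfg = config or RunConfig()
    conditions = list(conditions or cfg.sweep["conditions"])

    fx = cfg.fixtures
    cable = make_geometry(FixtureSpec(
        kind="cable", dimensions=(float(fx["cable"]["length"]),),
        dx=float(fx["cable"]["dx"]), layers=(0.0, 0.0, 1.0)))
    shell = make_geometry(FixtureSpec(
        kind="shell",
        dimensions=(float(fx["shell"]["r_inner"]), float(fx["shell"]["r_outer"])),
        dx=float(fx["shell"]["dx"]), layers=tuple(fx["shell"]["layers"])))
    proto = make_sinus_protocol(
        shell, n_sites=int(fx["protocol"]["n_sites"]),
        onset=float(fx["protocol"]["onset"]),
        purkinje_speed=float(fx["protocol"]["purkinje_speed"]),
        seed=int(fx["protocol"]["seed"]),
        cycle_length=float(cfg.cell["cycle_length"]),
        amplitude=float(fx["protocol"]["amplitude"]),
        duration=float(fx["protocol"]["duration"]),
        site_radius=float(fx["protocol"]["site_radius"]))

    tp = TissueParams(rho=(float(cfg.tissue["rho"]),) * 3,
                      S=(float(cfg.tissue["S"]),) * 3,
                      Cm=float(cfg.tissue["Cm"]), dt=float(cfg.tissue["dt"]),
                      threshold=float(cfg.tissue["threshold"]))
    duration = float(cfg.sweep["electrical_duration"])
    n_cycles = int(cfg.sweep["n_cycles"])
    tol = float(cfg.sweep["calibration_tol"])

    result = SweepResult(config_hash=cfg.hash())
    for target in sorted(conditions):
        cond = SweepCondition(target_cv=float(target))
        try:
            rho, achieved = calibrate_resistivity(float(target), cable, tp,
                                                  tol=tol)
            cond.rho, cond.achieved_cv = rho, achieved
        except (ValueError, RuntimeError) as exc:
            cond.failed = True
            cond.failure_reason = f"calibration: {exc}"
            result.conditions.append(cond)
            continue
        if progress:
            progress(f"MCV {target:g} cm/s: rho = {rho:.1f} Ohm cm "
                     f"(cable CV {achieved:.1f} cm/s)")
        run = run_tissue_paced(shell, tp.with_rho(rho), proto, duration)
        emap = run.final_eat
        cond.eat_map = emap
        hemo = run_cardiac_cycles(emap, n_cycles=n_cycles, config=cfg)
        cond.hemo = hemo
        atp = cycle_atp(hemo)
        m = pv_metrics(hemo, atp=atp)
        m.eat_duration = eat_duration(emap)
        cond.metrics = m
        result.conditions.append(cond)
        if progress:
            progress(f"  EAT {m.eat_duration:.1f} ms | EDV {m.EDV:.1f} | "
                     f"ESV {m.ESV:.1f} | SV {m.SV:.2f} mL | EF {m.EF:.1f}% | "
                     f"Psys {m.systolic_P:.1f} mmHg | SW {m.SW:.0f} | "
                     f"ATP {m.ATP:.1f} /s | SW/ATP {m.SW_per_ATP:.1f}")
    if len(result.completed()) >= 2:
        result.trends = monotonicity_report(result)
    return result


def monotonicity_report(result: SweepResult) -> list:
    """Direction and strict monotonicity of every metric across ascending
    MCV, compared with the expected directions."""
    done = sorted(result.completed(), key=lambda c: c.target_cv)
    if len(done) < 2:
        raise ValueError("need at least two completed conditions")
    report = []
    for metric, expected in EXPECTED_DIRECTIONS.items():
        vals = np.array([getattr(c.metrics, metric) for c in done],
                        dtype=float)
        d = np.diff(vals)
        if np.all(d > 0):
            direction, strict = "up", True
        elif np.all(d < 0):
            direction, strict = "down", True
        else:
            direction = "up" if vals[-1] > vals[0] else (
                "down" if vals[-1] < vals[0] else "flat")
            strict = False
        report.append({"metric": metric, "direction": direction,
                       "strictly_monotone": bool(strict),
                       "expected": expected,
                       "matches_expected": bool(strict and
                                                direction == expected)})
    return report
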