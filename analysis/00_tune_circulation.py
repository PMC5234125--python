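"""One-time tuning of the circulation / ventricle-surrogate constants.

The lumped circulation has no published constants at this scale, so the
defaults in ``cardioem.hemodynamics`` were chosen by running this script
once and keeping the combination whose 70 cm/s baseline lands near the
reference operating range of a failing, hypertensive ventricle (EDV ~88-90 mL, ESV
~54 mL, SV ~34 mL, EF ~38%, MAP ~140 mmHg).  The frozen values are the
package defaults; re-running this script only reproduces that choice.

Usage:  python analysis/00_tune_circulation.py  [--quick]
"""

import sys
import warnings

import pandas as pd

from cardioem.config import RunConfig
from cardioem.fixtures import reference_fixture_suite, make_geometry, \
    make_sinus_protocol
from cardioem.hemodynamics import run_cardiac_cycles
from cardioem.sweep import pv_metrics, cycle_atp
from cardioem.tissue import TissueParams, run_tissue_paced

TARGET = {"EDV": 89.0, "ESV": 54.0, "SV": 34.2, "EF": 38.3, "MAP": 140.0}


def main(quick=False):
    suite = reference_fixture_suite()
    shell = make_geometry(suite["sweep_shell"]["spec"])
    proto = make_sinus_protocol(shell, **suite["sweep_shell"]["protocol"])
    run = run_tissue_paced(shell, TissueParams(), proto, duration=3000.0)
    emap = run.final_eat

    grid = [  # (alpha_lv, alpha_rv, V_sv_init)
        (200.0, 30.0, 2330.0), (220.0, 32.0, 2370.0), (240.0, 34.0, 2410.0),
    ] if not quick else [(220.0, 32.0, 2370.0)]

    rows = []
    for alv, arv, svv in grid:
        cfg = RunConfig.from_dict({"circulation": {
            "lv": {"alpha": alv}, "rv": {"alpha": arv}, "sv": {"V": svv}}})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = run_cardiac_cycles(emap, n_cycles=32, config=cfg)
        m = pv_metrics(h, atp=cycle_atp(h))
        err = sum(abs(getattr(m, k) - v) / v for k, v in TARGET.items())
        rows.append({"alpha_lv": alv, "alpha_rv": arv, "V_sv": svv,
                     "EDV": m.EDV, "ESV": m.ESV, "SV": m.SV, "EF": m.EF,
                     "MAP": m.MAP, "sysP": m.systolic_P, "misfit": err})
    df = pd.DataFrame(rows).sort_values("misfit")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
    print("\ntargets:", TARGET)
    print("best row's constants are the package defaults "
          "(alpha_lv=220, alpha_rv=32, V_sv=2370).")


if __name__ == "__main__":
    main(quick="--quick" in sys.argv)
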