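"""Trend report: does pumping efficacy improve with conduction velocity?

Reads results/sweep.json (written by 03_mcv_sweep.py) and prints the
metric table plus the direction of every metric across ascending MCV,
checked against the expected findings: with faster conduction the
activation time, ventricular volumes and ATP consumption fall while
systolic pressure, stroke volume, ejection fraction, stroke work and
stroke work per ATP rise.
"""

import json
import sys
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results" / "sweep.json"


def main(path=RESULTS):
    if not Path(path).exists():
        sys.exit(f"{path} not found; run analysis/03_mcv_sweep.py first")
    data = json.loads(Path(path).read_text())
    rows = [{"MCV": c["MCV"], **c["metrics"]}
            for c in data["conditions"] if not c["failed"]]
    df = pd.DataFrame(rows)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
    print("\ntrends with increasing MCV:")
    n_ok = 0
    for tr in data["trends"]:
        ok = tr["matches_expected"]
        n_ok += ok
        print(f"  {tr['metric']:>12}: {tr['direction']:>4} "
              f"(expected {tr['expected']:>4}, strict="
              f"{tr['strictly_monotone']}) [{'ok' if ok else 'MISMATCH'}]")
    print(f"\n{n_ok}/{len(data['trends'])} trends match the expected "
          "directions.")


if __name__ == "__main__":
    main(*sys.argv[1:])
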