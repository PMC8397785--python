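"""Well-mixed batch growth: logistic fits of replicate OD600 curves per
substrate (maximum growth rate, maximum OD, time to half-maximum), two-sample
t-tests with eta^2 between substrates, and the semilog regression of time to
half-maximum OD on inoculum density with a slope-difference test. Expected
outcome: slower, lower growth on the polymer, and a ~2x steeper inoculum
response on the polymer with a significant slope difference.
"""

import re
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, RESULTS, parse_seed, write_csv, write_json

from microcolony.growth import batch_metrics, semilog_inoculum_regression, stat_tests


def main() -> None:
    parse_seed(__doc__)
    batch_dir = DATA / "batch"
    if not batch_dir.exists():
        raise SystemExit("run 01_simulate_chambers.py first")

    rows = []
    for path in sorted(batch_dir.glob("*_rep*.csv")):
        sub, rep = re.match(r"(\w+)_rep(\d+)", path.stem).groups()
        m = batch_metrics(pd.read_csv(path))
        rows.append(
            {"substrate": sub, "replicate": int(rep),
             "max_growth_rate_per_h": m.max_growth_rate,
             "max_od": m.max_od, "t_half_h": m.t_half_h,
             "logistic_K": m.fit.params.get("K"), "r2": m.fit.r2}
        )
    reps = pd.DataFrame(rows)
    write_csv(reps, RESULTS / "batch_metrics.csv")

    by = {s: g for s, g in reps.groupby("substrate")}
    tests = stat_tests(
        {
            "max_growth_rate": (by["xylan"]["max_growth_rate_per_h"], by["xylose"]["max_growth_rate_per_h"]),
            "max_od": (by["xylan"]["max_od"], by["xylose"]["max_od"]),
        },
        test="t",
        fdr=True,
    )
    for r in tests:
        print(f"{r.test}: t={r.statistic:.2f} p={r.p_value:.2e} q={r.q_value:.2e} eta2={r.effect_size:.2f}")

    t_half, dens = {}, {}
    for path in sorted(batch_dir.glob("*_inoc*.csv")):
        sub, d = re.match(r"(\w+)_inoc(.+)", path.stem).groups()
        m = batch_metrics(pd.read_csv(path))
        t_half.setdefault(sub, []).append(m.t_half_h)
        dens.setdefault(sub, []).append(float(d))
    fits, diff = semilog_inoculum_regression(
        {s: np.array(v) for s, v in t_half.items()},
        {s: np.array(v) for s, v in dens.items()},
    )
    out = {
        s: {"slope_h_per_log10": f.params["b"], "intercept_h": f.params["a"], "r2": f.r2}
        for s, f in fits.items()
    }
    out["slope_difference"] = {"t": diff.statistic, "p": diff.p_value, "eta2": diff.effect_size}
    write_json(out, RESULTS / "inoculum_regression.json")
    for s, f in fits.items():
        print(f"{s}: t_half slope {f.params['b']:.2f} h per log10(cfu/ml), R2={f.r2:.3f}")
    print(f"slope difference: t={diff.statistic:.2f}, p={diff.p_value:.3g}")


if __name__ == "__main__":
    main()
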