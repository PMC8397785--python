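"""Simulate the in-silico study: replicate growth chambers for every
condition (colonial polymer vs solitary monomer defaults, matched-density
spatial variants, the half-saturation probe, nutrient-switch and mock-switch
experiments) plus batch growth curves, writing observation tables, ground
truth and metadata under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CHAMBER_CONDITIONS, DATA, condition_dir, parse_seed, write_csv

from microcolony import experiments as ex
from microcolony.io import chamber_meta_to_yaml, write_observations


def main() -> None:
    seed = parse_seed(__doc__)
    for cond in CHAMBER_CONDITIONS:
        d = condition_dir(cond)
        d.mkdir(parents=True, exist_ok=True)
        finals = []
        for i, (table, truth) in enumerate(ex.run_condition(cond, 9, base_seed=seed)):
            write_observations(table, d / f"chamber_{i}.csv")
            truth.to_json(d / f"truth_{i}.json")
            finals.append(truth.sessile_counts[-1])
        chamber_meta_to_yaml(ex.chamber_meta(cond), d / "meta.yaml")
        print(f"{cond:>22}: 9 chambers, final sessile counts {finals}")

    for sub in sorted(ex.BATCH_PARAMS):
        for i, curve in enumerate(ex.run_batch_replicates(sub, 4, base_seed=seed)):
            write_csv(curve, DATA / "batch" / f"{sub}_rep{i}.csv")
    for sub, curves in ex.run_inoculum_experiment(base_seed=seed).items():
        for dens, curve in curves:
            write_csv(curve, DATA / "batch" / f"{sub}_inoc{dens:.0e}.csv")
    print("batch curves written (4 replicates + 4 inoculum densities per substrate)")


if __name__ == "__main__":
    main()
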