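"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from microcolony.io import read_observations

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

CHAMBER_CONDITIONS = (
    "polymer",
    "monomer",
    "spatial_polymer",
    "spatial_monomer",
    "ksat_probe_polymer",
    "ksat_probe_monomer",
    "switch",
    "mock_switch",
)


def parse_seed(description: str) -> int:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="base seed of the study")
    return ap.parse_args().seed


def condition_dir(condition: str) -> Path:
    return DATA / condition


def load_condition(condition: str) -> list[pd.DataFrame]:
    """Observation tables of one simulated condition (written by 01)."""
    d = condition_dir(condition)
    paths = sorted(d.glob("chamber_*.csv"))
    if not paths:
        raise SystemExit(
            f"no simulated data for {condition!r} under {d}; run 01_simulate_chambers.py first"
        )
    return [read_observations(p) for p in paths]


def frame_times(table: pd.DataFrame):
    return sorted(table["time_h"].unique())


def write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=float))
    print(f"wrote {path.relative_to(ROOT)}")


def write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    print(f"wrote {path.relative_to(ROOT)}")
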