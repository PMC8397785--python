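"""Readers, writers and validation for cell-observation tables and chamber metadata.

The tabular interchange format is a plain CSV with one row per segmented cell
per frame::

    cell_id,frame,time_h,x_um,y_um,area_um2,parent_id,intensity_au

``parent_id`` is set only on a cell's birth frame (the frame where it first
appears as the daughter of a division); it is empty everywhere else and for
founder cells.  ``intensity_au`` is optional.  Coordinates are micrometres
with the origin at the lower-left chamber corner, x to the right and y up;
trackers that emit image coordinates (y down) can be ingested with
``y_down=True``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: mandatory columns of the observation table, in canonical order
OBS_COLUMNS = ["cell_id", "frame", "time_h", "x_um", "y_um", "area_um2", "parent_id"]
#: optional columns appended after the mandatory block when present
OPT_COLUMNS = ["intensity_au"]

SUBSTRATES = ("xylan", "xylose", "both", "none")
#: substrates degraded by cell-bound enzymes; leaving one triggers dispersal
POLYMER_SUBSTRATES = ("xylan",)


class SchemaError(ValueError):
    """An input table does not have the documented column schema."""


class ValidationError(ValueError):
    """An input table violates a hard invariant (e.g. non-monotone time)."""


@dataclass(frozen=True)
class ChamberMeta:
    """Geometry, imaging cadence and nutrient schedule of one growth chamber.

    The default geometry is the 60 x 60 um monolayer chamber used for
    time-lapse imaging; ``schedule`` lists ``(time_h, substrate)`` pairs with
    the first entry at time 0 and non-decreasing times.
    """

    chamber_id: str = "chamber"
    group_id: str = ""
    width_um: float = 60.0
    height_um: float = 60.0
    frame_interval_h: float = 8.0 / 60.0
    schedule: tuple[tuple[float, str], ...] = ((0.0, "xylan"),)

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if not self.schedule:
            raise ValueError("schedule must have at least one entry")
        if self.schedule[0][0] != 0.0:
            raise ValueError("first schedule entry must be at time 0")
        times = [t for t, _ in self.schedule]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be non-decreasing")
        for _, s in self.schedule:
            if s not in SUBSTRATES:
                raise ValueError(f"unknown substrate {s!r}")

    def substrate_at(self, time_h: float) -> str:
        """Substrate the chamber is fed at ``time_h``."""
        current = self.schedule[0][1]
        for t, s in self.schedule:
            if t <= time_h:
                current = s
        return current

    @property
    def switch_time(self) -> float | None:
        """Time of the first switch event, or None for constant feed.

        A mock switch (same substrate re-fed at t > 0) is still a switch
        event: series from mock experiments are aligned to it.
        """
        for t, _ in self.schedule[1:]:
            if t > 0:
                return t
        return None


def _default_bins() -> tuple[float, ...]:
    # seven equal birth-time bins tiling the 18.6 h observation window
    return tuple(np.linspace(0.0, 18.6, 8))


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants shared by the analysis stages.

    ``birth_bins_h`` are half-open bin edges ``[lo, hi)`` (last bin closed);
    ``k_list`` are the neighbor counts of the intercellular-distance profile;
    ``solitary_factor`` scales the median nearest-neighbor distance above
    which a cell counts as solitary; ``norm_offset_h`` is how long before a
    nutrient switch the density series is normalized to 1.
    """

    birth_bins_h: tuple[float, ...] = field(default_factory=_default_bins)
    k_list: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    solitary_factor: float = 5.0
    norm_offset_h: float = 4.0
    motility_threshold_um: float = 2.0
    candidate_models: tuple[str, ...] = ("linear", "exponential")
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        edges = np.asarray(self.birth_bins_h, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("birth-time bin edges must be strictly increasing")
        if any((not isinstance(k, (int, np.integer))) or k < 1 for k in self.k_list):
            raise ValueError("k values must be positive integers")
        if self.norm_offset_h <= 0:
            raise ValueError("normalization reference offset must be > 0")


# ---------------------------------------------------------------------------
# observation tables
# ---------------------------------------------------------------------------

def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["frame"] = df["frame"].astype(int)
    for col in ("time_h", "x_um", "y_um", "area_um2"):
        df[col] = df[col].astype(float)
    pid = df["parent_id"]
    df["parent_id"] = pid.where(pid.notna(), "").astype(str).replace("nan", "")
    if "intensity_au" in df.columns:
        df["intensity_au"] = df["intensity_au"].astype(float)
    return df


def read_observations(
    path: str | Path,
    chamber: ChamberMeta | None = None,
    y_down: bool = False,
) -> pd.DataFrame:
    """Read an observation CSV, validate its schema, and sort it.

    Parameters
    ----------
    path:
        CSV file with the documented schema.
    chamber:
        Optional metadata; required when ``y_down`` is set (the flip needs the
        chamber height).
    y_down:
        Flip the y axis on ingest for trackers using image coordinates.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the message names the column).
    ValidationError
        If time is not strictly increasing with frame within any cell.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    for col in OBS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    df = _coerce_types(df)
    if y_down:
        if chamber is None:
            raise ValueError("y_down flip requires chamber metadata")
        df["y_um"] = chamber.height_um - df["y_um"]
    df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    bad = []
    for cid, grp in df.groupby("cell_id", sort=False):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            bad.append(cid)
    if bad:
        raise ValidationError(
            "time not strictly increasing with frame for cells: " + ", ".join(bad)
        )
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table with the canonical column order."""
    cols = list(OBS_COLUMNS) + [c for c in OPT_COLUMNS if c in df.columns]
    out = df[cols].copy()
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    kind: str
    severity: str
    message: str


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(pd.util.hash_pandas_object(df, index=True).values.tobytes()).hexdigest()


def validate_observations(
    df: pd.DataFrame, chamber: ChamberMeta | None = None
) -> list[Finding]:
    """Report (never repair) structural problems in an observation table.

    Checks out-of-bounds coordinates (needs ``chamber``), duplicated
    ``(cell_id, frame)`` rows, and parent links referencing absent cells.
    The input is not mutated.
    """
    findings: list[Finding] = []
    before = _table_hash(df)

    dup = df.duplicated(subset=["cell_id", "frame"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, df.loc[dup, ["cell_id", "frame"]].itertuples(index=False))))
        for cid, fr in pairs:
            findings.append(Finding("duplicate", "error", f"duplicate row for cell {cid} frame {fr}"))

    if chamber is not None:
        oob = (
            (df["x_um"] < 0)
            | (df["x_um"] > chamber.width_um)
            | (df["y_um"] < 0)
            | (df["y_um"] > chamber.height_um)
        )
        for cid in sorted(df.loc[oob, "cell_id"].unique()):
            findings.append(Finding("out_of_bounds", "warning", f"cell {cid} has out-of-bounds coordinates"))

    if (df["area_um2"] <= 0).any():
        for cid in sorted(df.loc[df["area_um2"] <= 0, "cell_id"].unique()):
            findings.append(Finding("nonpositive_area", "error", f"cell {cid} has non-positive area"))

    known = set(df["cell_id"])
    parents = df.loc[df["parent_id"] != "", ["cell_id", "parent_id"]]
    for cid, pid in parents.itertuples(index=False):
        if pid not in known:
            findings.append(Finding("orphan_parent", "error", f"cell {cid} references absent parent {pid}"))

    assert _table_hash(df) == before, "validation must not mutate its input"
    return findings


# ---------------------------------------------------------------------------
# YAML metadata / config
# ---------------------------------------------------------------------------

def chamber_meta_to_yaml(meta: ChamberMeta, path: str | Path) -> None:
    d = dataclasses.asdict(meta)
    d["schedule"] = [list(entry) for entry in meta.schedule]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def chamber_meta_from_yaml(path: str | Path) -> ChamberMeta:
    d = yaml.safe_load(Path(path).read_text())
    d["schedule"] = tuple((float(t), str(s)) for t, s in d["schedule"])
    return ChamberMeta(**d)


def analysis_config_to_yaml(cfg: AnalysisConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["birth_bins_h"] = [float(x) for x in cfg.birth_bins_h]
    d["k_list"] = [int(k) for k in cfg.k_list]
    d["candidate_models"] = list(cfg.candidate_models)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def analysis_config_from_yaml(path: str | Path) -> AnalysisConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key, caster in (
        ("birth_bins_h", float),
        ("k_list", int),
        ("candidate_models", str),
    ):
        if key in d:
            d[key] = tuple(caster(v) for v in d[key])
    return AnalysisConfig(**d)


def assign_birth_bins(birth_times: Sequence[float], edges: Sequence[float]) -> np.ndarray:
    """Bin indices for birth times under half-open ``[lo, hi)`` bins.

    The last bin is closed on the right so the edges tile the whole window;
    times outside the edges get index -1.
    """
    t = np.asarray(birth_times, dtype=float)
    e = np.asarray(edges, dtype=float)
    idx = np.searchsorted(e, t, side="right") - 1
    idx[t == e[-1]] = len(e) - 2
    idx[(t < e[0]) | (t > e[-1])] = -1
    return idx
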