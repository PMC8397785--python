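"""Frozen in-silico study designs and end-to-end pipeline runs.

This module is the single source of the simulated experimental conditions the
analysis drivers, the tests and the acceptance script all share:

``polymer`` / ``monomer``
    The default chamber conditions.  Polymer chambers start from 2-3 founder
    cells, retain ~90% of daughters and grow colonially (sessile counts
    doubling every ~3 h toward 40-110 cells); monomer chambers start from
    ~45 scattered cells, lose most daughters to dispersal and accumulate
    cells near-linearly toward a competition-capped ~65 cells.

``spatial_polymer`` / ``spatial_monomer``
    Matched-cell-number variants (>100 cells each) used for the
    intercellular-distance contrast, isolating the spatial arrangement
    (one clonal colony vs scattered solitary cells) from abundance.

``ksat_probe_polymer`` / ``ksat_probe_monomer``
    A controlled probe for the density benefit: retention equalized
    (p_disperse 0.1 both), no competition, conditions differing only in the
    half-saturation cell number (4 vs 1), with durations spanning a
    comparable multiple of each condition's own saturation scale -- the
    regime in which the growth-rate-vs-cell-number analysis can recover the
    configured four-fold saturation-density ratio.

``switch`` / ``mock_switch``
    Polymer growth with a polymer-to-monomer switch (or a polymer-to-polymer
    mock switch) at 12 h, imaged to 16 h, for the dispersal dynamics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ChamberMeta
from .growth import (
    BinSummary,
    GrowthFit,
    bin_growth_by_birth_time,
    fit_growth_model,
    select_best_model,
)
from .lineage import (
    LineageTree,
    filter_negative_rates,
    reconstruct_lineage,
    records_frame,
    sessile_count_series,
)
from .simulate import SimChamberConfig, SubstrateParams, simulate_chamber

#: substrate behavior under the default study conditions (see docs/methods.md)
STUDY_SUBSTRATES = {
    "xylan": SubstrateParams(
        p_disperse=0.10, r_max=0.35, K_sat=4.0, c_comp=0.0003,
        detach_rate=0.0, is_polymer=True,
    ),
    "xylose": SubstrateParams(
        p_disperse=0.65, r_max=0.35, K_sat=1.0, c_comp=0.005,
        detach_rate=0.8, is_polymer=False,
    ),
    "both": SubstrateParams(
        p_disperse=0.65, r_max=0.35, K_sat=1.0, c_comp=0.005,
        detach_rate=0.4, is_polymer=False,
    ),
    "none": SubstrateParams(
        p_disperse=0.65, r_max=1e-6, K_sat=1.0, c_comp=0.0,
        detach_rate=0.5, is_polymer=False,
    ),
}

#: probe substrates: identical retention and no competition, K_sat ratio 4
PROBE_SUBSTRATES = {
    "xylan": SubstrateParams(
        p_disperse=0.10, r_max=0.35, K_sat=4.0, c_comp=0.0,
        detach_rate=0.0, is_polymer=True,
    ),
    "xylose": SubstrateParams(
        p_disperse=0.10, r_max=0.35, K_sat=1.0, c_comp=0.0,
        detach_rate=0.0, is_polymer=False,
    ),
}

SWITCH_TIME_H = 12.0

_CONDITIONS = {
    # condition -> (substrates, schedule, n_founders, duration_h)
    "polymer": (STUDY_SUBSTRATES, ((0.0, "xylan"),), 2, 18.6),
    "monomer": (STUDY_SUBSTRATES, ((0.0, "xylose"),), 45, 18.6),
    "spatial_polymer": (STUDY_SUBSTRATES, ((0.0, "xylan"),), 3, 20.0),
    "spatial_monomer": (STUDY_SUBSTRATES, ((0.0, "xylose"),), 110, 2.0),
    "ksat_probe_polymer": (PROBE_SUBSTRATES, ((0.0, "xylan"),), 2, 18.6),
    "ksat_probe_monomer": (PROBE_SUBSTRATES, ((0.0, "xylose"),), 2, 7.0),
    "switch": (STUDY_SUBSTRATES, ((0.0, "xylan"), (SWITCH_TIME_H, "xylose")), 2, 16.0),
    "mock_switch": (STUDY_SUBSTRATES, ((0.0, "xylan"), (SWITCH_TIME_H, "xylan")), 2, 16.0),
}


def chamber_config(condition: str, seed: int) -> SimChamberConfig:
    """The frozen configuration of one chamber of a named condition."""
    substrates, schedule, n_founders, duration = _CONDITIONS[condition]
    return SimChamberConfig(
        substrate_schedule=schedule,
        substrates=dict(substrates),
        n_founders=n_founders,
        duration_h=duration,
        seed=seed,
    )


def chamber_meta(condition: str, chamber_id: str = "") -> ChamberMeta:
    _, schedule, _, _ = _CONDITIONS[condition]
    return ChamberMeta(chamber_id=chamber_id or condition, schedule=tuple(schedule))


def run_condition(condition: str, n_chambers: int = 9, base_seed: int = 1):
    """Simulate replicate chambers; chamber i uses seed base_seed*1000+i."""
    out = []
    for i in range(n_chambers):
        cfg = chamber_config(condition, base_seed * 1000 + i)
        out.append(simulate_chamber(cfg))
    return out


def bin_edges_for(condition: str, config: AnalysisConfig | None = None) -> np.ndarray:
    """Birth-time bin edges for a condition: the standard seven bins over the
    18.6 h window, rescaled to shorter probe durations."""
    config = config or AnalysisConfig()
    edges = np.asarray(config.birth_bins_h, dtype=float)
    duration = _CONDITIONS[condition][3]
    if duration < edges[-1]:
        edges = np.linspace(0.0, duration, len(edges))
    return edges


def analyze_chamber_counts(
    table: pd.DataFrame, frame_times, models=("linear", "exponential")
) -> tuple[GrowthFit, dict[str, GrowthFit], LineageTree, pd.DataFrame]:
    """Reconstruct the lineage, fit candidate models to the sessile-count
    series, and select the best; returns (best, fits, tree, counts)."""
    tree = reconstruct_lineage(table)
    counts = sessile_count_series(tree, frame_times)
    fits = {
        m: fit_growth_model(counts["time_h"], counts["n_sessile"], m) for m in models
    }
    best = select_best_model(list(fits.values()))
    return best, fits, tree, counts


def rate_density_bins(
    table: pd.DataFrame, frame_times, edges
) -> tuple[list[BinSummary], float]:
    """Birth-time-binned median growth rate vs mean cell count for one
    chamber, after the negative-rate exclusion; returns (bins, excluded
    fraction)."""
    tree = reconstruct_lineage(table)
    records = list(tree.records.values())
    kept, excluded = filter_negative_rates(records)
    counts = sessile_count_series(tree, frame_times)
    return bin_growth_by_birth_time(kept, counts, edges), excluded


def ksat_recovery(
    probe_runs: dict[str, list], config: AnalysisConfig | None = None
) -> dict[str, float]:
    """Recover the saturating-benefit parameters from probe chambers.

    Fits the Monod rate model to each chamber's instantaneous growth rate vs
    the cell count at each frame and takes per-condition medians of r_max
    and K; the headline number is the polymer/monomer ratio of recovered
    half-saturation cell numbers (configured value: 4).  The bin-level
    linear slope of the classic birth-time-binned analysis is reported
    alongside.
    """
    from .growth import instantaneous_rate_vs_count

    out: dict[str, float] = {}
    for cond, runs in probe_runs.items():
        edges = bin_edges_for(cond, config)
        Ks, rmaxs, slopes = [], [], []
        for table, truth in runs:
            inst = instantaneous_rate_vs_count(table)
            fit = fit_growth_model(inst["n_cells"], inst["rate_per_h"], "monod")
            if fit.success:
                Ks.append(fit.params["K"])
                rmaxs.append(fit.params["Ymax"])
            bins, _ = rate_density_bins(table, truth.frame_times, edges)
            if len(bins) >= 3:
                x = np.array([b.mean_count for b in bins])
                y = np.array([b.median_rate for b in bins])
                slopes.append(float(np.polyfit(x, y, 1)[0]))
        out[f"{cond}_K_median"] = float(np.median(Ks))
        out[f"{cond}_rmax_median"] = float(np.median(rmaxs))
        out[f"{cond}_linear_slope_median"] = float(np.median(slopes))
    poly = [c for c in probe_runs if "polymer" in c][0]
    mono = [c for c in probe_runs if "monomer" in c][0]
    out["ksat_ratio"] = out[f"{poly}_K_median"] / out[f"{mono}_K_median"]
    out["slope_ratio_monomer_over_polymer"] = (
        out[f"{mono}_linear_slope_median"] / out[f"{poly}_linear_slope_median"]
    )
    return out


def records_with_counts(table: pd.DataFrame, frame_times) -> pd.DataFrame:
    """Filtered per-cell records joined with the mean sessile count each cell
    experienced over its life (for the rate-vs-density ANCOVA)."""
    tree = reconstruct_lineage(table)
    kept, _ = filter_negative_rates(list(tree.records.values()))
    counts = sessile_count_series(tree, frame_times)
    t = counts["time_h"].to_numpy()
    n = counts["n_sessile"].to_numpy()
    rows = []
    for r in kept:
        mask = (t >= r.birth_time - 1e-9) & (t <= r.end_time + 1e-9)
        mean_n = float(n[mask].mean()) if mask.any() else float("nan")
        rows.append((r.cell_id, r.birth_time, r.growth_rate, mean_n))
    return pd.DataFrame(rows, columns=["cell_id", "birth_time_h", "growth_rate_per_h", "mean_count"])


def records_table(table: pd.DataFrame) -> pd.DataFrame:
    return records_frame(reconstruct_lineage(table))


# ---------------------------------------------------------------------------
# batch-culture designs
# ---------------------------------------------------------------------------

from .simulate import SimBatchConfig, simulate_batch_curve  # noqa: E402

#: well-mixed growth is limited on the polymer (lower plateau and rate) and
#: its time-to-half-maximum responds ~2x more steeply to inoculum density
BATCH_PARAMS = {
    "xylan": {"K": 0.18, "r": 0.18, "lag_slope": -6.78},
    "xylose": {"K": 0.40, "r": 0.35, "lag_slope": -3.41},
}
BATCH_NOISE_SD = 0.004
BATCH_N0 = 0.005
INOCULUM_DENSITIES = (1e3, 1e4, 1e5, 1e6)
REFERENCE_DENSITY = 1e5


def batch_config(
    substrate: str,
    seed: int,
    inoculum_density: float = REFERENCE_DENSITY,
    noise_sd: float = BATCH_NOISE_SD,
) -> SimBatchConfig:
    p = BATCH_PARAMS[substrate]
    return SimBatchConfig(
        K=p["K"],
        r=p["r"],
        N0=BATCH_N0,
        noise_sd=noise_sd,
        inoculum_density=inoculum_density,
        reference_density=REFERENCE_DENSITY,
        lag_slope_h_per_log10=p["lag_slope"],
        seed=seed,
    )


def run_batch_replicates(substrate: str, n: int = 4, base_seed: int = 1):
    """Replicate batch growth curves at the reference inoculum density."""
    return [
        simulate_batch_curve(batch_config(substrate, base_seed * 2000 + i))
        for i in range(n)
    ]


def run_inoculum_experiment(base_seed: int = 1):
    """One batch curve per inoculum density per substrate (the time-to-half-
    maximum vs inoculum design); returns {substrate: [(density, curve), ...]}."""
    out = {}
    for j, substrate in enumerate(sorted(BATCH_PARAMS)):
        curves = []
        for i, d in enumerate(INOCULUM_DENSITIES):
            cfg = batch_config(substrate, base_seed * 3000 + 100 * j + i, inoculum_density=d)
            curves.append((d, simulate_batch_curve(cfg)))
        out[substrate] = curves
    return out
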