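"""Agent-based generator of chamber tracking tables and batch growth curves.

The generator emulates the dimorphic life cycle of a surface-attached
bacterium in a monolayer growth chamber: sessile stalked cells grow
exponentially in area, divide asymmetrically, and release a motile swarmer
daughter that either disperses out of the chamber or attaches next to its
mother and becomes sessile itself.  The per-cell growth rate depends on the
number of sessile cells ``n`` in the chamber through a saturating benefit and
a linear competition penalty::

    r(n) = r_max * n / (K_sat + n) - c_comp * n        [1/h]

On a polymer the benefit saturates at a ~four-fold higher cell number than on
the corresponding monomer (cells pool the products of their cell-bound
depolymerases), and daughters mostly stay; on a monomer daughters mostly
disperse.  When the feed switches from a polymer to a monomer (or to no
carbon), attached non-founder cells start detaching with an exponential
hazard after a 20-minute lag (the time medium takes to reach the chamber).

Everything the simulation does is logged in a :class:`SimGroundTruth` so the
downstream analysis can be tested against exact truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OBS_COLUMNS, POLYMER_SUBSTRATES


class ConfigurationError(ValueError):
    """A simulation configuration is non-finite, out of range, or cannot grow."""


#: lag between a nutrient switch and cells experiencing the new medium (h)
SWITCH_LAG_H = 20.0 / 60.0


@dataclass(frozen=True)
class SubstrateParams:
    """Behavioral parameters of one carbon source.

    p_disperse : probability that a newborn swarmer leaves the chamber
    r_max      : maximal single-cell exponential growth rate (1/h)
    K_sat      : half-saturation sessile-cell number of the density benefit
    c_comp     : competition penalty per sessile cell (1/h per cell)
    detach_rate: detachment hazard (1/h) applied after a polymer-to-monomer
                 or polymer-to-none switch lands on this substrate
    is_polymer : whether the substrate is a polymer (its loss triggers
                 dispersal of attached cells)
    """

    p_disperse: float
    r_max: float
    K_sat: float
    c_comp: float = 0.0
    detach_rate: float = 0.0
    is_polymer: bool = False

    def __post_init__(self) -> None:
        vals = (self.p_disperse, self.r_max, self.K_sat, self.c_comp, self.detach_rate)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("substrate parameters must be finite")
        if not 0.0 <= self.p_disperse <= 1.0:
            raise ConfigurationError("p_disperse must be in [0, 1]")
        if self.r_max <= 0:
            raise ConfigurationError("r_max must be positive")
        if self.K_sat < 1:
            raise ConfigurationError("K_sat must be >= 1")
        if self.c_comp < 0 or self.detach_rate < 0:
            raise ConfigurationError("c_comp and detach_rate must be >= 0")

    def rate(self, n: int | float) -> float:
        """Density-dependent single-cell growth rate r(n) in 1/h."""
        return self.r_max * n / (self.K_sat + n) - self.c_comp * n


def default_substrates() -> dict[str, SubstrateParams]:
    """Study-condition parameters for the four feed labels.

    Calibrated against the observed chamber dynamics: on the polymer,
    colonies founded by one or two cells double their sessile count every
    ~3.6 h and reach ~40-110 cells in 18.6 h while single-cell rates rise
    from ~0.1 to ~0.25 1/h; on the monomer nearly all daughters disperse and
    counts climb near-linearly by ~1-3 cells/h toward 18-65 cells, capped by
    competition.  The saturation cell number is four-fold higher on the
    polymer (K_sat 6 vs 1.5).
    """
    return {
        "xylan": SubstrateParams(
            p_disperse=0.1, r_max=0.25, K_sat=6.0, c_comp=0.0003,
            detach_rate=0.0, is_polymer=True,
        ),
        "xylose": SubstrateParams(
            p_disperse=0.9, r_max=0.25, K_sat=1.5, c_comp=0.0025,
            detach_rate=0.8, is_polymer=False,
        ),
        "both": SubstrateParams(
            p_disperse=0.9, r_max=0.28, K_sat=1.5, c_comp=0.0025,
            detach_rate=0.4, is_polymer=False,
        ),
        "none": SubstrateParams(
            # no growth is not representable with r_max > 0; use a vanishing
            # rate so cells effectively stall while detachment proceeds
            p_disperse=0.9, r_max=1e-6, K_sat=1.0, c_comp=0.0,
            detach_rate=0.5, is_polymer=False,
        ),
    }


@dataclass(frozen=True)
class SimChamberConfig:
    """Full specification of one simulated chamber run."""

    width_um: float = 60.0
    height_um: float = 60.0
    frame_interval_h: float = 8.0 / 60.0
    duration_h: float = 18.6
    n_founders: int = 2
    substrate_schedule: tuple[tuple[float, str], ...] = ((0.0, "xylan"),)
    substrates: dict[str, SubstrateParams] = field(default_factory=default_substrates)
    interdivision_cv: float = 0.15
    placement_distance_um: float = 1.6
    initial_area_um2: float = 1.0
    include_intensity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("width_um", self.width_um),
            ("height_um", self.height_um),
            ("frame_interval_h", self.frame_interval_h),
            ("duration_h", self.duration_h),
            ("placement_distance_um", self.placement_distance_um),
            ("initial_area_um2", self.initial_area_um2),
        ):
            if not math.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{name} must be finite and positive")
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")
        if self.interdivision_cv < 0:
            raise ConfigurationError("interdivision_cv must be >= 0")
        if self.duration_h < self.frame_interval_h:
            raise ConfigurationError("duration must cover at least one frame interval")
        if not self.substrate_schedule or self.substrate_schedule[0][0] != 0.0:
            raise ConfigurationError("substrate schedule must start at time 0")
        times = [t for t, _ in self.substrate_schedule]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigurationError("schedule times must be non-decreasing")
        for _, label in self.substrate_schedule:
            if label not in self.substrates:
                raise ConfigurationError(f"no parameters for substrate {label!r}")
        for label, params in self.substrates.items():
            if params.rate(1) <= 0:
                raise ConfigurationError(
                    f"r(1) <= 0 on substrate {label!r}: a lone cell cannot grow"
                )

    def substrate_at(self, time_h: float) -> str:
        current = self.substrate_schedule[0][1]
        for t, s in self.substrate_schedule:
            if t <= time_h:
                current = s
        return current


@dataclass
class SimGroundTruth:
    """Exact event log of a simulated chamber (the oracle for the pipeline)."""

    parent: dict[str, str]
    dispersal_events: list[tuple[str, float, str]]
    detach_events: list[tuple[str, float]]
    division_events: list[tuple[str, str, float]]
    true_growth_rate: dict[str, float]
    sessile_counts: list[int]
    frame_times: list[float]
    founders: list[str]
    config: SimChamberConfig

    def to_json(self, path: str | Path) -> None:
        d = {
            "parent": self.parent,
            "dispersal_events": self.dispersal_events,
            "detach_events": self.detach_events,
            "division_events": self.division_events,
            "true_growth_rate": self.true_growth_rate,
            "sessile_counts": self.sessile_counts,
            "frame_times": self.frame_times,
            "founders": self.founders,
            "config": _config_to_dict(self.config),
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _config_to_dict(cfg: SimChamberConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["substrate_schedule"] = [list(x) for x in cfg.substrate_schedule]
    d["substrates"] = {k: dataclasses.asdict(v) for k, v in cfg.substrates.items()}
    return d


@dataclass
class _Cell:
    cid: str
    x: float
    y: float
    area: float
    birth_area: float
    div_threshold: float
    birth_time: float
    birth_frame: int
    parent: str | None
    is_founder: bool
    cum_log_growth: float = 0.0


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def simulate_chamber(config: SimChamberConfig) -> tuple[pd.DataFrame, SimGroundTruth]:
    """Run one chamber and return its observation table plus ground truth.

    The state advances frame by frame (interval ``frame_interval_h``): areas
    grow at the current r(n), cells whose area crossed their division
    threshold divide at the frame boundary, and newborn swarmers either
    disperse (never entering the table) or attach ``placement_distance_um``
    from their mother at a uniform random angle, clipped to the chamber.
    All randomness comes from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_h
    n_frames = int(math.floor(config.duration_h / dt)) + 1

    cells: list[_Cell] = []
    next_id = 0

    def new_id() -> str:
        nonlocal next_id
        next_id += 1
        return f"c{next_id:04d}"

    for _ in range(config.n_founders):
        cid = new_id()
        area = config.initial_area_um2 * float(rng.uniform(0.7, 1.3))
        cells.append(
            _Cell(
                cid=cid,
                x=float(rng.uniform(0.0, config.width_um)),
                y=float(rng.uniform(0.0, config.height_um)),
                area=area,
                birth_area=area,
                div_threshold=2.0 * area * _lognormal_factor(rng, config.interdivision_cv),
                birth_time=0.0,
                birth_frame=0,
                parent=None,
                is_founder=True,
            )
        )

    truth = SimGroundTruth(
        parent={},
        dispersal_events=[],
        detach_events=[],
        division_events=[],
        true_growth_rate={},
        sessile_counts=[],
        frame_times=[],
        founders=[c.cid for c in cells],
        config=config,
    )

    # first polymer -> non-polymer transition in the schedule, if any
    detach_from: float | None = None
    for (t0, s0), (t1, s1) in zip(config.substrate_schedule, config.substrate_schedule[1:]):
        was_poly = config.substrates[s0].is_polymer
        now_poly = config.substrates[s1].is_polymer
        if was_poly and not now_poly:
            detach_from = t1 + SWITCH_LAG_H
            break

    rows: list[tuple] = []
    ended: dict[str, tuple[float, float]] = {}  # cid -> (cum_log_growth, lifespan)

    for f in range(n_frames):
        t = f * dt
        truth.frame_times.append(t)
        truth.sessile_counts.append(len(cells))
        for c in cells:
            rows.append(
                (
                    c.cid,
                    f,
                    t,
                    c.x,
                    c.y,
                    c.area,
                    (c.parent or "") if f == c.birth_frame else "",
                    c.area * 120.0 if config.include_intensity else np.nan,
                )
            )
        if f == n_frames - 1:
            break

        substrate = config.substrates[config.substrate_at(t)]
        n = len(cells)
        if n == 0:
            continue
        r = substrate.rate(n)
        growth = math.exp(r * dt)
        t_next = (f + 1) * dt

        newborn: list[_Cell] = []
        for c in cells:
            c.area *= growth
            c.cum_log_growth += r * dt
            if c.area >= c.div_threshold:
                # asymmetric division at the frame boundary: the stalked
                # mother keeps her id and half the area, the swarmer daughter
                # takes the other half
                half = c.area / 2.0
                c.area = half
                c.birth_area = half
                c.div_threshold = 2.0 * half * _lognormal_factor(rng, config.interdivision_cv)
                did = new_id()
                truth.division_events.append((c.cid, did, t_next))
                if rng.uniform() < substrate.p_disperse:
                    truth.dispersal_events.append((did, t_next, c.cid))
                else:
                    angle = rng.uniform(0.0, 2.0 * math.pi)
                    x = min(max(c.x + config.placement_distance_um * math.cos(angle), 0.0), config.width_um)
                    y = min(max(c.y + config.placement_distance_um * math.sin(angle), 0.0), config.height_um)
                    newborn.append(
                        _Cell(
                            cid=did,
                            x=x,
                            y=y,
                            area=half,
                            birth_area=half,
                            div_threshold=2.0 * half * _lognormal_factor(rng, config.interdivision_cv),
                            birth_time=t_next,
                            birth_frame=f + 1,
                            parent=c.cid,
                            is_founder=False,
                        )
                    )
                    truth.parent[did] = c.cid

        survivors: list[_Cell] = []
        if detach_from is not None and t_next > detach_from and substrate.detach_rate > 0:
            exposed = min(dt, t_next - detach_from)
            p_detach = 1.0 - math.exp(-substrate.detach_rate * exposed)
            for c in cells:
                if (not c.is_founder) and rng.uniform() < p_detach:
                    truth.detach_events.append((c.cid, t_next))
                    # last observation was at t; drop the growth increment of
                    # the unobserved final interval
                    ended[c.cid] = (c.cum_log_growth - r * dt, t - c.birth_time)
                else:
                    survivors.append(c)
        else:
            survivors = cells

        cells = survivors + newborn

    for c in cells:
        ended.setdefault(c.cid, (c.cum_log_growth, (n_frames - 1) * dt - c.birth_time))
    for cid, (cum, life) in ended.items():
        truth.true_growth_rate[cid] = cum / life if life > 0 else float("nan")

    df = pd.DataFrame(rows, columns=OBS_COLUMNS + ["intensity_au"])
    if not config.include_intensity:
        df = df.drop(columns=["intensity_au"])
    df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    return df, truth


# ---------------------------------------------------------------------------
# batch growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimBatchConfig:
    """Logistic batch growth-curve generator settings.

    The trajectory is ``N(t) = K / (1 + ((K - N0)/N0) exp(-r t'))`` with
    ``t' = t - lag_slope * log10(inoculum / reference)``: a ten-fold denser
    inoculum shifts the whole curve earlier by ``-lag_slope`` hours.
    """

    K: float = 0.4
    r: float = 0.35
    N0: float = 0.005
    noise_sd: float = 0.0
    sample_times_h: tuple[float, ...] = tuple(np.arange(0.0, 48.01, 0.5))
    inoculum_density: float = 1e5
    reference_density: float = 1e5
    lag_slope_h_per_log10: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.K > self.N0 > 0):
            raise ConfigurationError("need K > N0 > 0")
        if self.r <= 0:
            raise ConfigurationError("r must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.sample_times_h) == 0:
            raise ConfigurationError("sample_times_h must not be empty")
        if self.inoculum_density <= 0 or self.reference_density <= 0:
            raise ConfigurationError("densities must be positive")


def logistic(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Logistic growth curve N(t)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def simulate_batch_curve(config: SimBatchConfig) -> pd.DataFrame:
    """One noisy OD600 trajectory; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.sample_times_h, dtype=float)
    shift = config.lag_slope_h_per_log10 * math.log10(
        config.inoculum_density / config.reference_density
    )
    od = logistic(t - shift, config.K, config.r, config.N0)
    if config.noise_sd > 0:
        od = od + rng.normal(0.0, config.noise_sd, size=od.shape)
    return pd.DataFrame({"time_h": t, "od600": od})


# backwards-compatible plural alias used by the drivers
def simulate_batch_curves(config: SimBatchConfig) -> pd.DataFrame:
    return simulate_batch_curve(config)


# ---------------------------------------------------------------------------
# swimming-assay tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSwimConfig:
    """High-frame-rate swimming-assay generator.

    Motile swarmers run at ``speed_mean`` um/s (per-cell lognormal spread)
    with small directional wobble; sessile cells only jitter in place.
    """

    n_cells: int = 40
    motile_fraction: float = 0.5
    speed_mean_um_s: float = 26.0
    speed_cv: float = 0.35
    fps: float = 7.5
    duration_s: float = 4.0
    jitter_um: float = 0.05
    turn_sd_rad: float = 0.3
    arena_um: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or not 0.0 <= self.motile_fraction <= 1.0:
            raise ConfigurationError("bad swim configuration")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fps and duration must be positive")


def simulate_swim_tracks(config: SimSwimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate swimming tracks; returns (observations, truth table).

    Observations use the motility CSV convention (``time_s`` seconds);
    the truth table gives each cell's class and true mean speed.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.fps
    n_steps = int(round(config.duration_s * config.fps))
    rows = []
    truth = []
    n_motile = int(round(config.n_cells * config.motile_fraction))
    for i in range(config.n_cells):
        cid = f"s{i:03d}"
        motile = i < n_motile
        x = float(rng.uniform(0, config.arena_um))
        y = float(rng.uniform(0, config.arena_um))
        heading = float(rng.uniform(0, 2 * math.pi))
        sigma = math.sqrt(math.log(1 + config.speed_cv**2))
        speed = (
            config.speed_mean_um_s * float(rng.lognormal(-0.5 * sigma**2, sigma))
            if motile
            else 0.0
        )
        for step in range(n_steps + 1):
            rows.append((cid, step, step * dt, x, y))
            if motile:
                heading += float(rng.normal(0.0, config.turn_sd_rad))
                x += speed * dt * math.cos(heading)
                y += speed * dt * math.sin(heading)
            else:
                x += float(rng.normal(0.0, config.jitter_um))
                y += float(rng.normal(0.0, config.jitter_um))
        truth.append((cid, "motile" if motile else "sessile", speed))
    obs = pd.DataFrame(rows, columns=["cell_id", "frame", "time_s", "x_um", "y_um"])
    truth_df = pd.DataFrame(truth, columns=["cell_id", "true_class", "true_speed_um_s"])
    return obs, truth_df
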