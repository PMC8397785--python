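# Methods

## Scope and data model

The package consumes per-frame cell observation tables
(`cell_id, frame, time_h, x_um, y_um, area_um2, parent_id[, intensity_au]`)
as produced by any segmentation/tracking tool, with `parent_id` set only on
a daughter's birth frame. Coordinates are micrometres, origin at the
lower-left chamber corner, y up; a `y_down` ingest flag flips image-style
coordinates. Time is hours everywhere except the motility module, which
works in seconds at high frame rates (default 7.5 frames/s) and converts at
its boundary. Segmentation and tracking themselves are out of scope.

## The chamber simulator

The generator emulates a dimorphic surface-colonizing lifecycle in a
60 × 60 μm monolayer chamber imaged every 8 min:

* Sessile stalked cells grow exponentially in area at the shared
  density-dependent rate `r(n) = r_max·n/(K_sat+n) − c_comp·n`, where `n`
  is the current sessile count. The saturating term models the local
  pooling of breakdown products from cell-bound depolymerases; the linear
  term models competition for substrate.
* A cell divides when its area exceeds a threshold of twice its birth area,
  multiplied by lognormal noise with configurable CV (default 0.15); the
  distribution of interdivision noise is a modeling choice, as single-cell
  data constrain only its scale. Division is asymmetric: the mother keeps
  her identity and half the area; the swarmer daughter disperses with
  probability `p_disperse` (and never enters the table — chambers track
  sessile cells) or attaches 1.6 μm from the mother at a uniform random
  angle, clipped to the chamber.
* On a polymer→monomer or polymer→none switch, attached non-founder cells
  detach with an exponential hazard (`detach_rate`) starting 20 min after
  the switch, the time the new medium needs to reach the chamber interior.
* Cells are discs characterized by centroid and area; no rod shapes or
  mechanical exclusion, since every downstream statistic uses centroids.
* One `numpy` Generator keyed by the config seed drives all randomness;
  identical seeds give byte-identical tables. Replicate chambers use
  `base_seed·1000 + index`.

Every event (division, dispersal, detachment) and every cell's true
time-averaged rate are logged in a ground-truth object used only by tests
and recovery analyses, never by the pipeline itself.

### Study-condition defaults

The default conditions were calibrated once against the observed chamber
phenomenology and then frozen:

| condition | founders | p_disperse | r_max (h⁻¹) | K_sat | c_comp | outcome |
|---|---|---|---|---|---|---|
| polymer | 2 | 0.10 | 0.35 | 4 | 3·10⁻⁴ | exponential counts, doubling ≈ 2.5–3.5 h, finals ~20–80 |
| monomer | 45 | 0.65 | 0.35 | 1 | 5·10⁻³ | near-linear counts, ≈ 1–2 cells/h, finals ~60–70 |

Notes on these choices:

* `K_sat` is the half-saturation of the rate curve, not the cell number at
  which rates visibly plateau (≈ 4–7·K_sat). A four-fold polymer/monomer
  ratio is built in. Putting `K_sat` at the plateau scale itself (tens of
  cells) would make a 1–2 cell inoculum grow at `r_max/K` and stall for
  tens of hours, which contradicts how single founders build colonies
  within a day; hence the half-saturation reading.
* On the monomer, a near-linear sessile-count series requires the
  chamber-level retention flux `(1−p)·n·r(n)/ln2` to be flat-to-declining
  over the observation window; with rates that rise with `n`, this forces
  the competition term to bend the flux down. The monomer defaults place
  the chambers just below their competition cap (≈ 70 cells). Strongly
  saturated regimes (cap reached mid-movie) were avoided: a rise-then-flat
  series is fit *better* by a shallow exponential than by a line, flipping
  model selection back.
* Dispersal probabilities per division are not directly measured; 0.10 and
  0.65 reproduce the retention difference implied by the two count-growth
  regimes.
* Batch curves are logistic (`K`, `r`, `N0`) plus Gaussian noise; the
  polymer curve is slower and lower (K 0.18 vs 0.40 OD600, r 0.18 vs
  0.35 h⁻¹). Inoculum density shifts the whole curve in time by
  `lag_slope · log10(inoculum/reference)` with slopes −6.78 (polymer) and
  −3.41 (monomer) hours per decade.

### What the generator does *not* emulate

Segmentation noise and tracking errors (areas are exact, links are
perfect), transiently visible dispersing swarmers, rod-shaped geometry and
crowding, nutrient gradients within the chamber, and cell-cycle age
structure beyond the area-doubling rule. Consequently, passing tests show
the *analysis* is correct and the *designed* statistical structure is
recovered; they do not certify performance on noisy real segmentations.
Two paper-level observables are knowingly outside the generator's reach:
the observable offspring propensity is retention-weighted (dispersed
daughters leave no trace in the table), and on the monomer the measured
rates mildly *decline* with count because competition, not a rising
benefit, is what linearizes the count series under high dispersal.

## Analysis pipeline

**Lineage.** Parent links at birth frames define a forest (cycles,
multiple parents, or children born no later than their parents are
structural errors). Fates: `divided` (has a child), `disappeared` (lost
before the last frame), `censored` (present at movie end; kept, with the
partial-life rate). A chamber is flagged single-progenitor when the forest
has one root. Newick export writes one statement per root with branch
lengths equal to lifespans.

**Per-cell growth rate.** Least-squares slope of ln(area) on time over the
cell's observed life. Observed areas halve at divisions, so the estimator
first multiplies areas by 2^(divisions so far); divisions are detected both
from daughter links and from frame-to-frame area drops below 0.75 (growth
steps never approach that; halving is ≈ 0.5), which covers mothers whose
daughters dispersed. An endpoint log-ratio variant is available via
`method="endpoint"`. Cells observed in fewer than two frames get NaN, never
a fabricated value. The deterministic rule "exclude rate < 0" replaces the
manual curation used on real data, where negative rates mark segmentation
or linking artifacts; the excluded fraction is reported per chamber.

**Counts and propensity.** A cell is counted from its birth frame through
its last observed frame (closed interval — a cell is present on the frame
where it was last seen). Offspring propensity divides daughter births in a
window by the exact time integral of the count; for an exponentially
growing census this equals ln2 / interdivision time, the population rate
constant.

**Spatial statistics.** k-NN profiles use a KD-tree, excluding the focal
cell, averaging over neighbors then focal cells; k > n−1 is flagged
undefined rather than truncated. The colony density divides the cell count
by the area of the smallest axis-aligned rectangle enclosing the centroids
(a rotated-rectangle variant exists for sensitivity); "smallest rectangle"
is read as axis-aligned because that is how chamber images are cropped and
annotated. Solitary cells — nearest-neighbor distance beyond `factor`
(default 5) times the median nearest-neighbor distance — are excluded; the
factor operationalizes a qualitative rule and is a config knob. Switch
experiments fix the rectangle from the last pre-switch frame and normalize
the series to its density 4 h before the switch; cross-chamber averages use
linear interpolation onto a common grid with Student-t 95% CIs (the CI
construction is our choice).

**Growth inference.** Models: linear and semilog-linear in closed form;
exponential, saturating-exponential `Ymax(1−e^{−kx})`, Monod `Ymax·x/(K+x)`
and logistic by nonlinear least squares with deterministic initializations
(exponential rate from the endpoint log-ratio; logistic K from max(y) and
rate from the early log-linear phase). Selection takes the highest R², ties
to fewer parameters. Birth-time bins are seven equal half-open intervals
tiling [0, 18.6 h] (the last closed), rescaled for shorter runs. The
rate-vs-count slope defaults to the linear-regression slope of per-bin
median rate on mean count; an `initial-derivative` variant returns
`Ymax/K` of a Monod fit. ANCOVA compares `rate ~ birth` against
`rate ~ birth + count` (F-test, partial eta²); batch metrics take the
logistic `r` as the maximum growth rate (the standard growth-curve
convention; a windowed derivative was deliberately not used), the smoothed
maximum OD, and the interpolated time to half-maximum; the inoculum
regression tests slope differences through the interaction term of a pooled
model. Two-sample tests are two-sided t (eta² = t²/(t²+df)) or
Mann–Whitney (exact enumeration when both groups ≤ 8), with
Benjamini–Hochberg FDR across families.

**Parameter recovery.** Recovering `r_max` and `K_sat` uses the
*instantaneous* rate — the median per-frame log-area increment of
non-dividing cells paired with the count at that frame — because per-cell
lifetime rates average `r(n)` across the near-doubling of `n` within one
cell cycle and bias `K` estimates unstably. The recovery experiment is a
controlled probe: 9+9 chambers with retention equalized (p_disperse = 0.1)
and no competition, differing only in `K_sat` (4 vs 1), with durations
chosen so each condition spans a comparable multiple (~0.5–10×) of its own
half-saturation scale. On this design the Monod fit recovers `r_max` and
the four-fold `K_sat` ratio essentially exactly, while the bin-level
*linear* slope ratio lands near 2–3, not 4: both conditions start from the
same two-cell inoculum, so the low-K condition begins already at 2·K where
the hyperbola is flat. A slope ratio of ~4 would require each condition to
be observed over count ranges proportional to its own K from below, which a
common inoculum forbids.

**Motility.** Trajectories from high-frame-rate tables; path length is the
stepwise Euclidean sum, mean speed path length over elapsed time (net-
displacement speed is reported alongside, since either convention is
defensible). Cells are motile when net displacement exceeds 2 μm (≈ one
cell length) — a deterministic stand-in for the manual classification used
with real movies; positions are not smoothed by default.

## Numerical choices and degenerate inputs

R² is undefined (NaN, flagged) when the response is constant; selection
over only-undefined fits is an error. A logistic fit with `K ≈ N0` (flat
curve) reports growth rate 0 because `r` is unidentifiable there. The
ANCOVA returns F = 0 when birth time alone already explains the response to
machine precision. Density is undefined for fewer than two points or a
zero-area extent (error, not silent NaN); a missing normalization reference
frame (nothing within half a frame interval) is an error. Ties in neighbor
distances are broken by distance then index, deterministically. The
zero-variance/equal-means two-sample case returns p = 1 with a note.

## Problem sizes

The shipped study uses 9 chambers per condition (matching the chamber-level
replication the analysis is designed around), 4 batch replicates and 4
inoculum densities per substrate, and 1000 null simulations for the type-I
calibration of the slope-difference test; the whole study, tests included,
runs in well under a minute on one core.

## Known limitations

Generator realism limits are listed above. The per-cell rate estimator
assumes multiplicative area noise is small at the frame scale; heavily
mis-segmented data should be curated before ingest (the validator reports
duplicates, orphan links and out-of-bounds coordinates but does not
repair). The solitary-exclusion factor and the motility threshold are
operational constants, not measured quantities; both are exposed in
`AnalysisConfig`. Exact Mann–Whitney enumeration is exponential in group
size and is capped at n ≤ 8 per group by default.
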