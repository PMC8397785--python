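# microcolony

Quantitative single-cell analysis of **colonial vs solitary bacterial growth
on polymeric vs monomeric carbon sources**, paired with an agent-based
generator of the chamber tracking data such an analysis consumes.

Aquatic bacteria such as *Caulobacter crescentus* degrade plant
polysaccharides (e.g. xylan) with cell-bound enzymes, so the breakdown
products of one cell are available mostly to its close neighbors. In
microfluidic monolayer chambers this produces two distinct growth modes:
on the polymer, swarmer daughters stay after division and clonal
microcolonies form; on the monomer (xylose), daughters swim away and cells
grow solitarily. This package is for microbial ecologists and quantitative
microscopists who have per-frame segmentation/tracking tables (any tracker,
converted to a documented CSV) and want the downstream numbers: lineage
trees, per-cell growth rates, density-dependent rate curves, intercellular
distances, and dispersal dynamics around nutrient switches.

## The model at the core

Sessile (stalked) cells grow exponentially in area and divide when their
area doubles. The single-cell rate depends on the number *n* of sessile
cells in the chamber through a saturating benefit and a competition penalty:

    r(n) = r_max · n/(K_sat + n) − c_comp · n        [h⁻¹]

with the half-saturation cell number **K_sat four-fold higher on the
polymer** than on the monomer. Each division releases a swarmer that
disperses with probability `p_disperse` (low on the polymer, high on the
monomer) or attaches next to its mother. After a polymer→monomer switch,
attached non-founder cells detach with an exponential hazard beginning
~20 min after the switch (the time the new medium takes to reach the
chamber). The analysis layer estimates per-cell rates as the division-
corrected log-area regression slope, fits count dynamics with linear vs
exponential models selected by R², computes k-nearest-neighbor distance
profiles (k = 10…100) and bounding-rectangle densities, and tests
density dependence with Monod fits, ANCOVA, Mann–Whitney/t tests and
Benjamini–Hochberg FDR.

## Worked example

Simulate a polymer-fed chamber, reconstruct its lineage, and export records
plus a Newick forest:

```sh
$ mcd simulate --seed 7 --out chamber.csv --truth truth.json
wrote 430 observations of 6 cells
$ mcd lineage --in chamber.csv --out records.csv --newick tree.nwk
6 cells, 2 founders, single progenitor: False, negative-rate excluded fraction: 0.000
```

`records.csv` holds one row per cell (parent, birth/end time, fate, growth
rate in h⁻¹, offspring count). A condition-level summary over a small
synthetic study:

```sh
$ mcd report --seed 1
condition  final_count  best_model  count_doubling_h  excluded_fraction
  polymer           47 exponential          2.771552              0.085
  polymer           39 exponential          2.918549              0.051
  polymer           72 exponential          2.566045              0.042
  monomer           65      linear         32.105625              0.000
  ...
```

Polymer chambers grow exponentially in sessile-cell number (count doubling
≈ 2.6–2.9 h here), monomer chambers accumulate cells near-linearly — the
signature that daughters disperse instead of joining the colony.

The full in-silico study lives under `analysis/`, numbered in run order:

```sh
python analysis/01_simulate_chambers.py --seed 1   # writes results/data/
python analysis/02_count_dynamics.py    --seed 1   # model selection, doubling times
python analysis/03_spatial_structure.py --seed 1   # k-NN distance profiles
python analysis/04_density_dependence.py --seed 1  # rate-vs-count, K_sat recovery, ANCOVA
python analysis/05_batch_growth.py      --seed 1   # logistic fits, inoculum regression
python analysis/06_nutrient_switch.py   --seed 1   # switch-aligned density series
python analysis/07_swimming.py          --seed 1   # swimming speeds
```

Each driver prints what it found and writes tables under `results/`.

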