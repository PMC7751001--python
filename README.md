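# lsomorph

Morphometrics of the avian lumbosacral vertebral canal.

Birds carry a suite of specializations in their lower spine — an expanded
vertebral canal housing a glycogen body, flanked by segmental transverse
recesses (lumbosacral transverse canals, LSTCs) — that together form the
lumbosacral organ (LSO), hypothesized to act as a secondary balance sensor.
`lsomorph` is for comparative morphologists who quantify this anatomy from
µ-CT-derived cross-sectional area profiles of the synsacral canal and ask
whether its shape tracks locomotor lifestyle (perching, terrestrial
bipedality, ...).

## The two statistics

Given an ordered anterior→posterior series of canal cross-sectional areas
*A*₁…*A*ₙ (the canonical protocol uses *n* = 11: the maximum-area section
±5 sections), with movmean₃ the 3-point running mean (2-point at the ends):

* **LSTC prominence** = sample SD of the dimensionless ratios
  *R*ₙ = *A*ₙ / movmean₃(*A*)ₙ, which on interior sections equals
  3*A*ₙ/(*A*ₙ₋₁+*A*ₙ+*A*ₙ₊₁). A smooth canal gives ratios ≈ 1 and
  prominence ≈ 0; deep alternating recesses push it up.
* **expansion ratio** = max movmean₃(*A*) / ((*A*₁+*A*ₙ)/2), isolating the
  fusiform glycogen-body expansion from the recess signal.

Both are scale-invariant, so specimens of different body size are directly
comparable. Distributions are compared between locomotor groups
(species-level, one value per species) with two-sample, two-sided
Kolmogorov–Smirnov tests.

Every stage is validated against synthetic phantoms: analytic area profiles
with known prominence/expansion drivers, and voxelized canal lumens (with
dorsal recesses and mock nerve-root-foramina notches) whose exact analytic
areas are emitted alongside the volume, so the fill-based section-area
measurement and the downstream metrics can be checked against ground truth.

## Worked example

Generate a 16-species synthetic cohort whose perching species have shifted
canal prominence, then run the full pipeline:

```python
from lsomorph import (CohortConfig, PipelineConfig, cohort_area_tables,
                      run_full_pipeline, write_area_table, write_species_table)

series, species = cohort_area_tables(CohortConfig(n_species=16, seed=12, group_shift=1.0))
write_area_table(series, "areas.csv")
write_species_table(species, "species.csv")
bundle = run_full_pipeline(PipelineConfig("areas.csv", "species.csv", out_dir="out"))
print(bundle.ks_results.to_string(index=False))
```

prints

```
         metric        flag  d_statistic  p_value  n_group1  n_group2 method
lstc_prominence    perching     0.875000 0.002486         8         8  exact
expansion_ratio    perching     0.375000 0.660140         8         8  exact
lstc_prominence terrestrial     0.333333 0.712537         6        10  exact
expansion_ratio terrestrial     0.400000 0.505495         6        10  exact
```

The planted prominence shift in the perching group is detected
(D = 0.875, exact p = 0.0025) while the unshifted expansion ratio and the
unrelated terrestrial flag show only noise-level separation. `out/`
additionally contains `metrics.csv` (per-specimen statistics),
`group_summaries.csv`, morphospace/ECDF/histogram figures per flag, and a
JSON run manifest. The same analyses are available from the shell via the
`lsomorph` CLI (`metrics`, `compare`, `phantom`, `cohort`, `run`
subcommands).

To analyze real measurements instead, supply a long-format CSV
(`specimen_id, species_id, section_index, section_label, area_mm2`) and a
species table with yes/no locomotor flags; an optional Newick phylogeny
orders the tip-aligned prominence bar chart.

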