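# holocyte

Digital holographic microscopy (DHM) of suspended leukocytes, end to
end: synthesis and reconstruction of off-axis holograms, sphere-model
retrieval of the integral cellular refractive index and radius, derived
single-cell biophysics (volume, dry mass, form factor), and the cohort
statistics used to track these parameters across a perioperative time
course — all exercisable on fully synthetic, ground-truthed data.

## The science

Quantitative phase imaging measures the optical path-length delay a
cell imposes on transmitted light. For a suspended cell of thickness
`d(x, y)` the phase contrast relative to the buffer is

    Δφ_cell(x, y) = (2π/λ) · d(x, y) · (n_cell − n_medium)

with λ the laser wavelength (532 nm), `n_medium` the buffer index
(1.337) and `n_cell` the volume-averaged cellular refractive index.
Suspended lymphocytes and monocytes are near-spherical, so
`d(x, y) = 2·√(R² − ρ²)` and a damped Gauss–Newton fit of the sphere
model to the phase map decouples `n_cell` from the radius `R` per cell.
From the fit follow

* volume `V = (4/3)πR³` (µm³),
* dry mass `DM = (V/α)(n_cell − n_medium)` with the refractive index
  increment α = 0.2 mL/g (≡ 0.2 µm³/pg, so DM is in pg),
* form factor `FF = 4πA/P²` of the segmented outline (1 for a circle),

per cell; 150 cells per cell type per sample are averaged into
patient × timepoint aggregates. The cohort layer computes per-patient
day differences (e.g. d1 − PreOP), screens pairs of change scores with
two-sided Pearson tests, probes effect stability with a
with-replacement bootstrap (sample p = fraction of 10,000 resample
means outside a ±0.3 SD corridor, Benjamini–Hochberg adjusted), and
compares clinical subgroups (complicated course, epinephrine treatment,
CRP > 14 mg/dL) with Welch t-tests.

Because clinical cohort data are not redistributable, the package ships
a calibrated simulator: cell phantoms whose radius and index
distributions reproduce the reported lymphocyte/monocyte population
moments, an off-axis hologram forward model, and a 25-patient × 4
timepoint cohort generator with injectable correlations between
biophysical and flow-cytometry change scores (Gaussian copula on the
difference scale) and the study's exact subgroup overlap structure.

## Worked example

```python
import numpy as np
from holocyte import (CellPhantom, OpticalConfig, center_phantom,
                      render_phase_image, synthesize_hologram,
                      reconstruct_hologram, segment_cells, fit_sphere_model)

cfg = OpticalConfig()                       # 532 nm, n_medium 1.337, 0.1 µm/px
cell = center_phantom(CellPhantom((0, 0), radius_um=3.675,
                                  n_cell=1.3497), cfg)
phase = render_phase_image(cell, cfg)       # peak phase ≈ 1.10 rad
holo = synthesize_hologram(phase, cfg)      # off-axis carrier fringes
recon = reconstruct_hologram(holo)          # demodulate + unwrap + flatten
mask = segment_cells(recon)[0]
m = fit_sphere_model(recon, mask, cfg)
print(f"R = {m.radius_um:.3f} µm, n_cell = {m.n_cell:.4f}, "
      f"V = {m.volume_um3:.1f} µm³, DM = {m.dry_mass_pg:.1f} pg, "
      f"FF = {m.ff:.3f}")
```

prints

```
R = 3.679 µm, n_cell = 1.3497, V = 208.6 µm³, DM = 13.2 pg, FF = 0.991
```

— the ground truth of this phantom is R = 3.675 µm (V = 207.9 µm³) and
n_cell = 1.3497, i.e. the full hologram → reconstruction → fit chain
recovers the radius to ~0.1% and the index to ~1×10⁻⁵. A cohort-level
run is one call:

```python
from holocyte.pipeline import RunConfig, run_pipeline
run_pipeline(RunConfig(out_dir="run", mode="aggregates", seed=1))
```

which writes `cohort.csv` (25 patients × 4 timepoints × 2 cell types),
`table1.csv` (change-score Pearson screening), `fig5_summary.csv`
(per-day cohort means ± SD with paired contrasts) and `fig6_groups.csv`
(subgroup comparisons plus Venn counts). The same is available from the
shell: `holocyte run --seed 1 --out run`, plus `holocyte
reconstruct/analyze/simulate/correlate/bootstrap` for the individual
stages (float-TIFF images, CSV tables).

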