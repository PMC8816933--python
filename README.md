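# bullseye-wmh

Reusable pipeline for analysing the spatial distribution of white-matter
hyperintensities (WMH) in a "bullseye" coordinate system: cerebral white
matter is divided into 9 lobar regions (frontal / parietal / temporal /
occipital per hemisphere plus bilateral basal ganglia) crossed with 4
concentric equidistant layers of normalized ventricle-to-cortex distance,
giving 36 parcels. The package covers:

- **`bullseye.phantom`** — synthetic brain phantoms (nested ellipsoids with
  lobar wedges) and cohort simulation with a known 3-block latent structure,
  so every downstream stage is testable without restricted MRI data;
- **`bullseye.parcellation`** — spacing-aware Euclidean distance maps,
  normalized distance `d_vent / (d_vent + d_cortex)`, layer assignment
  `[0,0.25) [0.25,0.5) [0.5,0.75) [0.75,1]`, and the 36-parcel intersection
  with voxel-count conservation;
- **`bullseye.quantify`** — per-parcel WMH volumetry (mm³), eTIV head-size
  adjustment (`v · eTIV_mean / eTIV_i`), brain parenchymal fraction, natural
  log transform with recorded offset, descriptive summaries;
- **`bullseye.components`** — PCA on the 36-parcel correlation matrix, Horn
  parallel analysis for retention, direct oblimin (oblique) rotation via
  gradient projection, communalities, regression-method scores;
- **`bullseye.stats`** — standardized cognitive domain scores, per-parcel and
  per-component covariate-adjusted linear models, Benjamini–Hochberg FDR,
  case-resampling bootstrap percentile CIs, VIF, age-tertile gamma GLM (log
  link), demographic correlations;
- **`bullseye.cli`** — a `bullseye` command with subcommands orchestrating
  the stages, each writing a JSON sidecar (config, seed, input checksums).

## CLI

```sh
bullseye phantom --shape 96 96 96 --seed 0 --out-dir phantom/
bullseye parcellate --ventricles phantom/ventricles.nii.gz \
    --cortex phantom/cortex.nii.gz --wm phantom/wm.nii.gz \
    --lobar phantom/lobar.nii.gz --out bullseye.nii.gz --code-table codes.csv
bullseye quantify --parcels bullseye.nii.gz --wmh wmh.nii.gz \
    --etiv 1500000 --subject-id S1 --out-csv volumes.csv
bullseye simulate-cohort --n 108 --seed 0 --out-csv cohort.csv
bullseye components --table-csv cohort.csv --auto --seed 0 --out-prefix comp
bullseye associate --components-csv comp_scores.csv --cognition-csv cog.csv \
    --covariates-csv cov.csv --family component --bootstrap 1000 --seed 0 \
    --out-csv associations.csv
bullseye demo --out-dir demo/ --seed 0     # full synthetic end-to-end run
```

Parcel codes are `region*10 + layer` (11..94); CSV columns are `p11`..`p94`
in fixed region order (frontal-L, frontal-R, parietal-L, parietal-R,
temporal-L, temporal-R, occipital-L, occipital-R, basal-ganglia).

## Notes

- All computations are voxel-space with spacing-aware metrics; volumes are
  reported in mm³. NIfTI affines are carried through untouched.
- Analysis order is fixed and recorded: eTIV adjustment → ln(v + 1) →
  PCA/associations.
- One global integer seed feeds named RNG streams, so stages are
  independently reproducible.
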