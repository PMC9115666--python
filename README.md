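# freshcube

Hyperspectral analysis of postharvest freshness in broccoli, built around a
fully synthetic senescence scene generator so every stage is testable
without proprietary image data.

The pipeline:

1. **scene_sim** — simulates a 2-temperature × 6-day × 4-replicate storage
   design: 300-band (400–998 nm) reflectance cubes with planted FRESH /
   SENESCED / BACKGROUND endmembers, per-pixel convex mixtures whose
   senesced fraction follows a logistic day course at room temperature and
   stays flat in the cold, center-bright illumination, band-end noise,
   per-sample lamp-tint drift, raw/white/dark frames, and glucosinolate
   concentrations linked linearly to the planted senesced fraction (with
   optional non-monotone replicate outliers). Ground truth ships with every
   sample for parameter-recovery testing.
2. **preprocess** — reflectance calibration `(raw − dark)/(white − dark)`,
   a 5-band median filter along the wavelength axis, trimming to band
   centers in [500, 900) nm (300 → 200 bands), and l2 normalization of
   every pixel spectrum.
3. **segment** — broccoli/background separation by 2-means clustering with
   the vegetation cluster picked by a green-bump score, morphological
   closing, a deterministic seeded min-cut for floret/stem separation, and
   k-means down-sampling to a fixed spectra budget (default 5,000) with
   exact cluster means.
4. **spice** — sparsity-promoting unmixing: an exact active-set simplex QP
   for abundances (fully constrained least squares with optional linear
   penalties) alternating with a closed-form dispersion-regularized
   endmember update and reweighted pruning, jointly estimating the number,
   shape and abundances of endmembers; plus the mean-abundance feature.
5. **miace** — multiple-instance learning of an adaptive-cosine-estimator
   target signature from bags labeled by the glucosinolate threshold (50),
   background whitening from negative bags, per-pixel confidences, and the
   mean-confidence feature.
6. **regress** — multivariable linear regression of features on
   concentration, the overall-significance F-test, PLSR on per-sample mean
   spectra, and RMSE / R² evaluation.
7. **experiment** — replicate-stratified 4-way splits, 10 × 3-fold
   cross-validation over the Γ grid (10…150, step 10), model selection,
   test-fold evaluation for both segmentation scenarios, the
   outlier-relocation experiment, and CSV/PNG reporting.
8. **cube_io** — ENVI cube I/O (BSQ/BIL/BIP, both endiannesses), design
   CSVs, portable binary arrays with JSON sidecars, and deterministic
   fixed-colormap map rendering.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (band accounting,
down-sampling budget, endmember-count recovery, QP/ACE/MLR oracle
equivalence, end-to-end parameter recovery, F-test calibration, and the
monotonicity/conservation suites). The full suite takes a couple of
minutes on one CPU.

## CLI

```bash
freshcube simulate --config sim.yaml --out data/ --seed 1
freshcube preprocess --data data/ --out prep/
freshcube segment    --data data/ --out masks/
freshcube unmix      --data data/ --out unmix/ --gamma 70
freshcube detect     --data data/ --out detect/ --threshold 50
freshcube regress    --features unmix/features.csv --metadata data/design.csv --out fit.json
freshcube run        --config experiment.yaml --out report/ --seed 1
```

YAML configuration uses top-level blocks named after the modules
(`simulate:`, `preprocess:`, `experiment:`); every dataclass field of
`ScenarioParams`, `PreprocessConfig` and `ExperimentConfig` is accepted.

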