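# deltarad

Delta-radiomics signatures from paired (pre/post-treatment) MRI volumes:

* **synthetic cohort** — paired T2-weighted-like volumes on an anisotropic
  grid with a textured ellipsoidal tumor that shrinks and homogenizes with a
  latent response, a ~1 cm³ bladder-urine reference sphere, and
  proportional-hazards outcomes for three endpoints (LR, DM, DFS);
* **preprocessing** — Collewet ±3σ clipping, bladder-urine intensity
  normalization, isotropic 1 mm resampling, 64-level quantization, and a
  largest-axial-slice 2D route;
* **features** — 55 radiomics features per ROI: volume/area, 8 first-order,
  15 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM (Haralick / Galloway / Thibault /
  Amadasun–King definitions, direction-averaged, distance 1);
* **delta + robustness** — after − before feature differences and a
  translation-based robustness filter: features are re-extracted from the
  original and 8 in-plane ±1 mm translated masks, and kept when the one-way
  single-measure ICC(1,1) exceeds 0.9 in all four tables
  ({2D, 3D} × {before, after});
* **signature** — L1-penalized Cox fitting with 10-fold cross-validated
  penalty selection (minimum CV partial-likelihood deviance), the six
  published Rad-score coefficient sets encoded digit-for-digit, linear Rad
  scoring, and log-rank-optimal cutoffs;
* **evaluation** — Kaplan–Meier/log-rank, Cox uni/multivariate tables,
  Harrell's C-index with paired bootstrap comparison, AUC with a
  Hosmer–Lemeshow calibration check, and Pearson r / VIF for 2D-vs-3D score
  comparison.

Arrays are ordered `(z, y, x)`; axial slices index `z`; spacings are mm in
the same order.

## CLI

The `deltarad` command exposes each stage and a full pipeline:

```sh
deltarad simulate --n 30 --seed 7 --out cohort/
deltarad preprocess --image cohort/P0000/before_image.nii.gz \
    --tumor cohort/P0000/before_tumor.nii.gz \
    --bladder cohort/P0000/before_bladder.nii.gz --levels 64 --out prep/
deltarad extract --quantized-dir prep/ --dims 3d --out features.csv
deltarad fit --features delta.csv --outcomes outcomes.csv \
    --endpoint DFS --dims 3d --seed 7 --out signature.json
deltarad run-all --n 30 --seed 7 --endpoint DFS --dims 3d --out run/
```

`run-all` chains simulate → preprocess → extract → delta → robustness →
fit → evaluate and writes every stage output plus a manifest
(seed + config hash). `--published` scores with a published signature
instead of fitting; `--skip-robustness` feeds all 55 delta features to the
fit.

## Layout

```
src/deltarad/
  synthetic.py      cohort generator, survival simulation, 2:1 split
  preprocessing.py  normalization, resampling, quantization
  features/         registry, texture-matrix builders, per-family formulas
  robustness.py     delta features, translated ROIs, ICC filter
  signature.py      LASSO-Cox, published coefficients, Rad score, cutoff
  evaluation.py     KM/log-rank, Cox, C-index, AUC/HL, Pearson/VIF
  io.py             NIfTI / CSV / JSON readers and writers
  cli.py            click-based CLI
tests/              unit + property tests, brute-force oracles,
                    test_acceptance.py (one test per acceptance criterion)
scripts/acceptance.py
```
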