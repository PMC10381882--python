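# radrobust

Robustness scoring of radiomics features under segmentation perturbation in
mammography-like greyscale images.

Given a lesion image and its binary ROI mask, the pipeline

1. **preprocesses** the image with contrast-limited adaptive histogram
   equalization (CLAHE: tile-wise clipped equalization, bilinear blending);
2. **perturbs** the segmentation with a binary morphological dilation and
   erosion using an octagonal structuring element whose scale is 6% of the
   ROI's equivalent-ellipse major axis (rounded to a multiple of 3 px),
   yielding an over- and an under-estimated mask;
3. **extracts** six families of radiomics features (first-order, GLCM, GLDM,
   GLRLM, GLSZM, NGTDM) from each of the three segmentations;
4. **scores** every feature: Shapiro–Wilk tests gate each comparison to a
   parametric (ANOVA, Welch t-test) or nonparametric (Kruskal–Wallis,
   Mann–Whitney U) branch; the *overall robustness score* is the p-value of
   the three-group test and the *segmentation-specific scores* are the
   p-values of the original-vs-over and original-vs-under tests, stratified
   by abnormality type, pathology and image view, with a median-split binary
   robustness level and per-family boxplot summaries.

A synthetic-data module (`radrobust.synthdata`) generates deterministic
lesion phantoms (masses, calcification clusters; benign/malignant effect
sizes; CC/MLO labels), sensitivity-pair fixtures, and feature-level
simulations with controllable class shifts, so the entire pipeline is
testable without any image archive.

## CLI

```sh
radrobust simulate --n-per-stratum 5 --seed 1 --out cohort/   # phantom cohort
radrobust preprocess --tiles 8x8 --clip 0.01 --in img.tif --out eq.tif
radrobust perturb --k 0.06 --in mask.png --out-prefix case1_
radrobust extract --image eq.tif --mask mask.png --out feats.csv
radrobust score --features features.csv --out report.csv
radrobust report --report report.csv --out summary.csv --plot boxes.png
radrobust run --seed 1 --out run_out/                         # end to end
```

`radrobust run` accepts `--config cfg.yaml` with keys such as
`n_per_stratum`, `k`, `alpha`, `clahe: {tiles, clip_limit, n_bins}`,
`extraction: {n_bins, glcm_distance, gldm_delta, gldm_alpha, ngtdm_delta}`,
or `input_dir` pointing at a directory of images + masks + `metadata.csv`
(columns `case_id, abnormality, pathology, view, image, mask`). Outputs are
`features.csv` (long-format feature table, metadata columns first),
`report.csv` (per-stratum per-feature scores and levels), `summary.csv`
(five-number summaries per feature family) and `manifest.json`.

## Conventions

- Row-major, 0-based pixel-centre coordinates throughout.
- Discretization uses a fixed bin count (default 64) over the per-mask
  min–max range, recomputed per segmentation.
- All texture matrices are validated against exhaustive brute-force oracles
  in the test suite; Mann–Whitney exact p-values against full enumeration.
- Scores are raw p-values in [0, 1]; no multiple-testing correction is
  applied, by definition of the score.
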