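# sbradiomics

A tested, reusable implementation of a 3D MRI radiomics pipeline for
discriminating two radiographically similar skull base tumor classes
(chordoma vs chondrosarcoma roles) from paired post-gadolinium T1 ("GD")
and T2-weighted volumes with a tumor volume-of-interest (VOI) mask.

The pipeline has three stages, written for researchers who want the whole
chain — not just feature extraction — under test:

1. **Masked 3D feature extraction.** Each sequence volume is decomposed by
   an undecimated single-level Coiflet-1 wavelet transform into 8 subbands
   (LLL … HHH) alongside the original image. From each of the 9 images the
   package computes 18 intensity and 20 histogram features (64-level
   quantization), and — at 16, 32, 64 and 128 gray levels — the five
   texture families: 11 GLCM, 13 GLRLM, 13 GLSZM, 16 NGLDM and 5 NGTDM
   features, all at Chebyshev distance 1 with counts merged over the 13
   unique 3D directions. With 8 morphology features from the mask this is

   8 + 9·(18 + 20) + 9·4·(11 + 13 + 13 + 16 + 5) = **2438 features per
   sequence**, 4876 per two-sequence case.

2. **Feature selection.** Logistic-regression recursive feature
   elimination (LG-RFE): the feature count 1..10 is chosen by a
   4-subgroup × 5-repeat cross-validated simulation; features are then
   voted over 5 repeated RFE runs and pruned so no same-sequence pair has
   |Pearson r| > 0.7.

3. **Model selection and test.** Logistic regression and SVM tuned by
   grid search with nested stratified 2-fold CV on 80% of the training
   cases, evaluated by stratified repeated 5-fold CV AUC (mean ± SD), and
   finally scored once on a disjoint hold-out validation split. A
   one-sample t-test compares a panel of human-reader accuracies against
   the model accuracy.

Because no patient data are distributed, the package ships a seeded
synthetic-cohort generator: paired 3D phantoms whose two classes differ in
within-VOI texture correlation length and mean intensity by a controllable
effect size, with ellipsoidal VOIs on anisotropic grids (1×1×3 mm by
default). All tests and analyses run end-to-end on these phantoms.

## Worked example

The `analysis/` scripts chain the full study on a simulated cohort
(20 training + 5 validation cases per class, effect size 1.5):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_extract_features.py
python analysis/03_select_features.py --seed 1
python analysis/04_train_evaluate.py --seed 1
python analysis/05_compare_readers.py --seed 1
```

Output of the run above (volumes land in `scratch/`, tables in `results/`):

```
wrote 50 cases (20+5 per class) to scratch/cohort
VOI sizes: 2029-3592 voxels (6.1-10.8 cm^3), effect size 1.5
extracted 4876 features (2438 per sequence) for 50 cases in 38.2 s
feature number: 1 per sequence
voted 2 features, pruned 0 correlated (|r| > 0.7), kept 2:
  -_GD_LLH_INT_standard_deviation  (frequency 2/5)
  -_T2_LLH_INT_interquartile_range  (frequency 1/5)
logistic_regression: params {'C': 0.01}; CV AUC 1.00 +/- 0.00; hold-out accuracy 1.00 (1)
svm: params {'kernel': 'linear', 'C': 0.01}; CV AUC 1.00 +/- 0.00; hold-out accuracy 1.00 (1)
20 simulated readers: median accuracy 0.60, mean 0.615 (95% CI 0.545-0.685)
model accuracy 1.00 differs from the reader panel (t = -11.51, p = 0.000; Shapiro-Wilk p = 0.13)
```

Read it as: the cross-validated simulation decided a single feature per
sequence suffices at this effect size, and the repeats voted dispersion
features of the LLH subband (the class-specific texture scale shows up as
within-VOI spread after high-pass filtering along z); note the selection
frequencies of 1–2 out of 5 — with many nearly equivalent discriminative
features, different resampled RFE runs legitimately pick different ones.
The tuned models separate the hold-out cases perfectly at this effect
size, and the simulated reader panel (a binomial panel with 60% per-case
skill — the statistical comparison, not the readers, is the point) is
significantly worse than the model.

At `--effect-size 0` the classes are identically distributed and the same
chain yields chance-level AUC and hold-out accuracy — the null behaves.

## Layout

- `src/sbradiomics/` — the library: `synthetic`, `image_io`, `wavelet`,
  `discretize`, `firstorder`, `texture` (+ `registry`), `features`,
  `selection`, `modeling`, `pipeline`.
- `analysis/` — the numbered study drivers shown above.
- `tests/` — unit, property and acceptance tests; `tests/oracles.py`
  holds the brute-force reference implementations.
- `docs/methods.md` — modeling assumptions, conventions and limitations.
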