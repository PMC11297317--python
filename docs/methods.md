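# Methods

## Problem and model

A protein's subcellular localization is treated as a multi-label
assignment over seven compartments (Cytoplasm, Endoplasmic reticulum,
Golgi apparatus, Mitochondria, Plasma membrane, Nuclear, Vesicles). The
observable is a bag of IHC images per protein and condition; the estimand
is, per condition, a 7-vector of localization probabilities, and
downstream, the set of proteins whose thresholded label sets differ
between tumor and normal tissue.

The predictor is a multi-instance aggregator: per-image feature vectors
are tokens to a pre-norm transformer encoder (depth 4, 6 attention heads,
head dimension `dim // 6`, feed-forward width 4×dim), followed by masked
mean pooling over tokens and a linear layer with per-label sigmoids.
Attention plus mean pooling makes the prediction exactly invariant to
image order, and the model accepts any bag size. Training minimizes
per-label binary cross-entropy with Adam (lr 3·10⁻³, full batch) on
normal-condition bags and labels only; tumor-condition vectors always come
from the normal-trained model, so a tumor/normal difference is a statement
about the images, not about separately fitted models.

The backbone is the classic 18-layer residual design (7×7 stem, four
stages of two basic blocks at 64/128/256/512 channels) implemented in
NumPy with im2col convolutions and **seeded random weights** (He-scaled).
There is no trained normalization; block outputs are RMS-normalized over
channels to keep magnitudes stable. Features are taken by global average
pooling at the requested stage and L2-normalized per image: the rectified
network is positively homogeneous, so overall stain intensity mostly
rescales the vector, and normalization removes that nuisance. On the
synthetic renders these random features support ~95% single-image class
accuracy (linear probe), which is all the aggregator needs. Pretrained
weights are not bundled; `weights="pretrained"` is an explicit error.

## Training regularization

The study scale (tens of proteins) makes bag-level overfitting the
dominant failure: a memorizing model predicts a protein's unseen tumor bag
confidently but inconsistently, which inflates false difference calls.
Two bag-level augmentations are applied each epoch: every token is dropped
with probability 0.3 (never emptying a bag) and N(0, 0.15) noise is added
to the standardized features. Both target exactly the invariances the
downstream statistics assume (deletion robustness, render-to-render
stability). Early stopping uses validation micro-F1 when a validation
fold exists (best weights restored), otherwise a plateau of the clean
training loss (patience 12, min improvement 5·10⁻⁴, max 120 epochs).

## Differential-localization statistic

Per ensemble scheme (10 models at 90% protein sampling, 10 at 70%), a
protein's difference count is the number of models whose thresholded label
sets differ between conditions (strict set inequality; probability drift
without a label change does not count).

* **Stability.** Default rule: keep proteins whose count reaches the
  scheme's upper-quartile value Q — the count at 1-based position
  ⌊0.75·(n+1)⌋ of the ascending counts — in both schemes. Retention
  additionally requires at least one difference call: proteins never
  called different are not candidates, and without this floor an all-zero
  count distribution (Q = 0) would retain everything. When ensembles are
  well calibrated most counts *are* zero and Q collapses to 0–1, so the
  quartile loses its meaning as a stringency bar; the study configuration
  therefore uses the fixed-fraction variant (`min_count_fraction = 0.75`,
  i.e. different in more than 75% of each scheme's models), which is
  scale-independent. Both rules are exposed.
* **Distance.** The single reference model is the ensemble member with the
  highest held-out F1 (ties: AUC, then model id). The top ⌈q·n⌉ proteins
  by Euclidean distance between its condition vectors are kept; cutoff
  ties break lexicographically by protein id. The default budget is
  q = 0.05. Recovery experiments with a planted relocation fraction f set
  q = f: a selection budget below the prevalence caps recall at q/f by
  construction.
* **Robustness.** For each condition with ≥2 images, each image is removed
  in turn, the bag is re-predicted, and a two-sided paired t-test across
  the 7 components compares the reduced vector with the full-bag vector.
  A protein is robust iff, in both conditions, every p ≥ α (0.05) *and*
  no deletion changes the thresholded label set; a condition with a single
  image is skipped and flagged. The call-level requirement exists because
  the paired test is blind in exactly the direction that matters: a flip
  concentrated in one component dilutes across seven paired differences
  and can stay non-significant, while the requirement is that the
  predicted *result* not depend on any single image. Identical vectors give
  p = 1 by convention, and a practical-significance floor
  (`min_effect = 0.02` on the probability scale) treats deletions that
  move no component by more than 2 points as no change — the paired test
  otherwise reaches significance on consistently-signed shifts of ~10⁻³
  that are far below any meaningful prediction change.

The final DLP set is the three-way intersection, serialized with all
intermediate sets, both Q values, and the parameters used.

## Expression-based check

The synthetic expression cohort is proteins × (20 tumor + 20 normal)
samples on the log2 scale: per-protein baselines N(22, 1.5²), residual sd
0.5, 5% missing completely at random plus 5% of rows at ~45% missing (so
the >30%-missing row filter has work), a DE subset with a ±2 (default)
group shift, and sub-fold-change signal (±0.6, sd 0.35) at the truly
relocated proteins — mirroring the observation that differentially
localized proteins are typically not differentially expressed yet still
carry condition information. Preprocessing drops rows with >30% missing
(strict) and imputes the rest from the 10 nearest protein rows (Euclidean
on shared observed samples, uniform mean). DE calls use Welch's t-test
(p < 0.05) and |log2FC| > 1 on group-mean differences. The classifier is
a random forest (500 trees, mtry = ⌊log₂N⌋ with N the number of samples —
an unconventional, fidelity-first choice; overridable), scored by
leave-one-out CV after subsampling the majority class to the minority size
(seeded). DLP-set AUC is replicated over balancing seeds and compared to
size-matched random sets (optionally stratified all/DE/nonDE) by Welch's
t-test.

## Synthetic data: what it does and does not emulate

The renderer draws a jittered grid of cells (blue nuclei on a light
background) and stains them brown with one geometry per category: solid
nucleus disks, diffuse cytoplasm, boundary rings, small granules, sparse
puncta, a juxtanuclear blob, or thin reticular arcs. Multi-label proteins
composite patterns in one image. Staining covariates are simulated per
image (intensity strong/moderate/weak scales stain opacity; stained
quantity is the fraction of stained cells) so that screening has real
work; the first two images per condition are always screen-passing, so no
protein is lost to screening by construction. Default label weights are
Nuclear-heavy, matching the published breast-corpus label distribution;
the multi-label rate (0.1) matches that corpus's ~9% multi-label fraction;
and default bag sizes (normal 2–4, tumor 5–8 images) mirror its roughly
threefold tumor/normal image imbalance. Relocated proteins swap their
dominant compartment for a new one in every tumor image. The
recovery/specificity study renders screen-passing images at strong
intensity with pixel noise 0.02 — the strongly stained, noise-light
regime those experiments are meant to probe — while degraded images keep
exercising the screening rules; the generator's defaults retain the
strong/moderate mix and noise 0.05 for harder conditions.

Not emulated: tissue morphology, cell segmentation ambiguity, stain
spectral overlap, label noise in the truth table, and any correlation
between image content and expression beyond the planted group shifts.
Passing tests therefore demonstrate that the statistics and the pipeline
machinery recover planted structure under realistic class imbalance and
staining covariates — not that the model reaches any particular accuracy
on real IHC corpora.

## Numerical choices and problem sizes

All randomness flows from one master seed through SHA-256-named
substreams (simulation, feature weights, fold shuffling, ensemble
membership, initialization, balancing), so stages are independently
reproducible and adding a stage never perturbs another. Floating point is
float32 in the networks (float64 in gradient-check tests; backward passes
are verified against central finite differences). Order-invariance
tolerances are 1e-5. The study runs at 50 proteins, 96-px renders,
stage-2 (128-d) features, 20 ensemble members, and 10-fold CV — sizes
chosen so a full recovery-plus-specificity study completes in minutes on
one CPU while keeping every per-label cell of the truth populated.

## Known limitations

* Random-weight features are a floor, not a ceiling; on real IHC images a
  pretrained backbone would be loaded instead (the extraction API takes a
  backbone object).
* The paired t-test robustness filter is weak against single-component
  flips (see above); it is kept because it is the published procedure,
  with the effect floor as the only numerical guard.
* Macro-AUC on small held-out sets (5 proteins) is coarse; reports list
  skipped degenerate labels explicitly.
* The label-mapping table is a best-effort stand-in for an unpublished
  grouping; unknown terms are hard errors so silent label loss cannot
  occur.
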