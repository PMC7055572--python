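# Methods

## The case-based risk model

`gifa` scores a query case against a reference library in a standardized
feature space. With features f_1..f_n (z-scored using means and SDs
learned from the reference cases only), the distance between a query y_q
and reference x_i is Euclidean,

    d(y_q, x_i) = sqrt( Σ_r [f_r(y_q) − f_r(x_i)]² ),

each of the K nearest references contributes an inverse-square distance
weight w_i = 1/d², and the risk score is the positive share of the total
weight,

    P_risk = Σ w⁺ / (Σ w⁺ + Σ w⁻) ∈ [0, 1].

Defaults and conventions:

- **K = 15** neighbors (the published operating point). Ties in distance
  break by case-id order so scoring is deterministic.
- **d = 0 handling.** The weight is singular at zero distance; distances
  below ε = 1e−6 are clamped, capping the weight at 1/ε² = 1e12. This
  keeps an exact-match neighbor dominant but finite.
- **Standardization** precedes the distance; raw-scale Euclidean distance
  would be dominated by large-range features (e.g. fibroglandular area in
  pixels vs a 4-level ordinal category). It can be disabled per model.
- A query carrying the same case id as a reference is excluded from its
  own neighborhood (leave-one-case-out semantics).

Swapping the class labels maps P to 1 − P, and rescaling all weights by a
common factor leaves P unchanged; both are enforced by tests.

## Class balance and feature selection

**SMOTE.** Each synthetic minority case is x + u·(x_nn − x), u ~ U(0,1),
with x_nn one of the k = 5 nearest minority neighbors of a randomly drawn
minority case x. Original rows are never modified, and dropping the
`synthetic` rows restores the input table bit-exactly. Either a
multiplier (2 doubles the minority class) or a target minority:majority
ratio (1.0 balances) can be requested.

**CFS.** Correlation-based feature selection maximizes the merit

    M(S) = k·r̄_cf / sqrt( k + k(k−1)·r̄_ff ),

where k = |S|, r̄_cf is the mean absolute feature–class (point-biserial)
correlation and r̄_ff the mean absolute pairwise feature–feature Pearson
correlation within S. The search is best-first: expand the best open
subset by one feature, stop after five consecutive non-improving
expansions. A candidate must beat the incumbent by more than 1e−9 so that
an exactly redundant duplicate (equal merit up to floating-point jitter)
never displaces the smaller subset; constant features receive correlation
0 and are never selected. For ≤ 6 features the search provably matches
exhaustive enumeration (tested).

## Evaluation protocol

Leave-one-case-out (LOCO) cross-validation holds out one original case at
a time; **standardization, SMOTE, CFS and classifier training are all
re-run on the remaining cases only**, and the held-out case is scored
once. Synthetic cases exist only inside training folds and are never
scored. A leakage canary (a feature informative only in the held-out row)
verifies the protocol yields chance performance where a leaking pipeline
would not.

Statistics:

- **AUC** by the Mann–Whitney U with ties counted ½ (equal to trapezoidal
  ROC integration on tie-free data), SE by Hanley–McNeil.
- **Confusion matrix** at operating threshold T = 0.5; a score exactly at
  T predicts positive. Metrics with zero denominators are reported as
  undefined, not zero. Percentages are reported to one decimal.
- **Quintile stratification**: rank-based bins whose sizes differ by at
  most one (1045 cases → five bins of 209), stable under any monotone
  transform of the scores. Odds ratios are crude subgroup ORs versus the
  lowest bin with Woolf 95% CIs, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d));
  this reproduces the published quintile ORs and CI bounds from the
  printed counts to their printed precision, so no covariate adjustment
  is implemented. Zero cells get the Haldane–Anscombe 0.5 correction and
  are flagged.
- **Trend** across ordered bins by the Cochran–Armitage z test with
  integer scores 1..k (the published analyses report only the trend
  conclusion from a logistic fit; the CA test is the standard
  contingency-table equivalent and is cross-checked against a chi-square
  formulation in tests).

## Image-feature stages

**Mammography.** The breast is the largest connected component above an
Otsu background threshold (histogram-derived, hence offset-invariant).
Dense tissue is thresholded by Otsu *within* the breast mask (a
constant-intensity breast counts as fully dense). The focal-region
feature thresholds the difference-of-Gaussian map at its within-mask 99th
percentile and takes the largest 8-connected component. The local
fluctuation map is a sliding-window SD (window 9, reflect padding); its
in-mask mean excludes a boundary rim of the window radius so the
breast/background edge does not count as tissue fluctuation. Default DoG
sigmas are 2 and 8 px. The ordinal density category uses percent-dense
bins <10%, 10–25%, 25–50%, >50%. All of these are configurable; none of
the originating studies publish their exact operators, so the defaults
are this package's documented choices.

**Lung CT.** The emphysema mask is lung ∧ (HU ≤ −950), inclusive; the
percentage is the volume-weighted voxel ratio. The 21-feature panel has
fixed names/order: 5 volume-and-shape features (percentage, blob count
under 26-connectivity, mean/max blob volume, sphericity
π^{1/3}(6V)^{2/3}/A of the largest blob with the surface from marching
cubes), 8 lung-HU distribution features, and 6 GLCM texture features
(entropy in bits, uniformity, autocorrelation with 1-based level indices,
contrast, homogeneity, correlation). The GLCM quantizes the region's own
intensity range into 32 levels (2 for the binary emphysema-pattern map),
counts symmetric co-occurrences along one-voxel axis offsets between
in-mask voxels, and pools offsets before normalizing; quantizing over the
region range makes the features scale- and offset-invariant. Texture is
computed on the binary emphysema-pattern map (the "global emphysema
pattern"), falling back to the lung HU map when no emphysema is present.
The exact 21-feature list of the originating study is unpublished; this
panel is a documented surrogate that always contains the three named
texture features.

**Abdominal CT.** Fat is body ∧ (−140 ≤ HU ≤ 40), inclusive at both
ends. SFA is the union of fat connected components touching the body's
boundary shell (body minus its erosion by 10 mm, configurable); VFA is
the remainder — always a disjoint partition of the fat mask. Areas and
volumes are voxel counts × spacing; TPA features are reported only when a
psoas mask is supplied (absent, not zero, otherwise).

**Breast MRI.** Air is removed by an Otsu threshold; tissue at or behind
the chest-wall line (fitted as the first anterior–posterior row where
foreground occupancy becomes near-full-width, or supplied as a fixed
plane for phantoms) is excluded. Registration is an exhaustive
integer-translation search (±5 voxels) maximizing correlation —
deliberately minimal; deformable registration is out of scope. Kinetic
statistics use population moments (skewness m₃/m₂^{3/2}, reported as 0
when the SD is 0) and top-k% means over the ⌈k%·N⌉ largest in-mask
values, computed per breast (a config switch pools both breasts).

## The synthetic-data generators

Every generator is bit-deterministic given its seed (all randomness flows
through one `numpy` Generator per call) and returns ground truth next to
the data. HU phantoms keep ≥ 30 HU between each tissue class and the
thresholds it must not cross, so threshold operators are unambiguous:
lung parenchyma is clipped above −920 HU, emphysema below −981 HU, fat
inside −135..−45 HU, organs above +72 HU. Planted emphysema fractions and
fat areas are honored exactly to one voxel by trimming the last planted
blob. Bilateral pairs mirror the left image about the vertical axis
(chest wall at the image edge) and inject asymmetry as extra dense blobs
plus local noise-variance inflation on one side. Feature tables are
two-class equicorrelated Gaussians; with a single informative feature of
standardized shift d, the theoretical AUC is Φ(d/√2), which anchors the
end-to-end tests.

What the phantoms do *not* emulate: anatomical texture, scanner physics,
partial-volume effects, registration artifacts, or the correlation
structure of real radiomic panels. Passing phantom tests therefore
demonstrates correctness of the operators and protocol, not clinical
performance on patient data.

## Problem sizes and numerical choices

Tests run on small geometries (48–192 px images, ≤ 24×48×48 voxel
volumes) and tables of 20–4000 cases; the end-to-end recovery experiment
uses 500-case tables over 50 seeds. Quantile binning uses stable argsort;
lower bins receive the extra case when n is not divisible by k. All
threshold comparisons at published cutoffs (−950 HU, −140..40 HU,
T = 0.5) are inclusive as documented above.

## Known limitations

- **Neighborhood scores cannot recover a planted AUC at modest n.** On
  synthetic tables with one informative feature and theoretical AUC 0.70,
  the SMOTE+CFS+KNN LOCO pipeline measures mean AUC ≈ 0.60 (SD 0.03 over
  50 seeds at n = 500). This is a property of the score, not a defect of
  the implementation: P_risk is a local posterior estimate from K = 15
  neighbors, and the inverse-square weight concentrates most of the mass
  on the nearest one to three references, so the score behaves like a
  smoothed nearest-neighbor label. Its ranking is bounded well below the
  true feature's AUC (an independent Monte-Carlo oracle puts even an
  unweighted 15-NN vote at ≈ 0.66 in this setting, and the
  inverse-square-weighted score at ≈ 0.60 regardless of K, class balance,
  or added noise dimensions). The acceptance suite states the 0.70 ± 0.05
  recovery expectation and the corresponding test fails honestly; the
  acceptance script reports the measured value.
- "Adjusted" odds ratios are computed as crude subgroup ORs (which
  reproduce the published values exactly); any covariate adjustment used
  originally is unknown.
- Automatic lung segmentation, tumor segmentation, CNN slice selection,
  L3 vertebra localization and deformable registration are out of scope;
  masks are inputs.
- The second of the two mammographic "fluctuation maps" named by the
  originating work is undefined there; one local-SD map is implemented
  and the second slot is a plug-in point.
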