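# Methods

## Model

Two modality towers map a patient into one unit-sphere embedding space.

**Imaging tower.** Either a precomputed feature vector (bypass mode, the
default for simulated cohorts) or a 4-channel volume through a small
residual 3D CNN: stem convolution (stride 2), one residual block, a second
stride-2 convolution, another residual block, global average pooling over
the spatial dimensions, and a linear map to the feature length (default
512). The default widths (16, 32) keep the network well under 200k
parameters; widths and depth are configuration options. Volumes intended
for encoding are first cropped to an axis-aligned cube (default 80³)
centered on the tumor centroid, shifting the window inward at boundaries.

**Pathology tower.** A slide is a variable-length set of N patch features
of dimension C (64 by default in simulation; 1536 when patch features come
from a modern pathology foundation model). A learnable CLS token is
prepended and the sequence passes through a post-norm transformer encoder
(depth 2, 4 heads, MLP ratio 4.0, dropout 0.1 in training only). A key
padding mask assigns −10³⁰ to padded keys before the softmax, so padded
rows have exactly zero attention weight; because all other per-token
operations are pointwise, padded rows provably cannot influence the CLS
output (property-tested). No positional encodings are used, so the
aggregator is a set function — permutation invariance is also tested.

**Projection and objective.** Each tower output passes through
g(x) = W₂·ReLU(LayerNorm(W₁x)) (hidden 256 imaging / 512 pathology, output
d = 256) and is L2-normalized. For a batch of N patients the symmetric
InfoNCE loss averages the row-wise and column-wise cross-entropies of the
temperature-scaled cosine matrix S_ij = ê_img(i)·ê_path(j)/τ. The softmax
is computed with max-subtraction; at the smallest grid temperature
τ = 0.01 the logits reach ±100, which would overflow otherwise.

**Optimization.** Adam with initial learning rate 3e-3 cosine-annealed to
1e-6, weight decay 1e-5 (applied as an L2 gradient term; normalization
parameters, biases and the CLS token are excluded, as is standard), batch
size 15 for alignment and 20 for the survival head. Temperature is either
fixed (0.07, the value the grid selects in practice) or grid-searched over
{0.01, 0.05, 0.07, 0.1, 0.2}; each temperature trains from the same seeded
initialization and is scored by held-out Recall@1 (configurable to MRR),
and the best epoch's checkpoint is kept — the validation metric for both
choices defaults to Recall@1 because retrieval quality is what the library
is later used for. Augmentation (random flips and in-plane quarter
rotations) applies only to volume inputs and is off in feature-bypass
mode. One master seed fans out to initialization, data order and dropout;
evaluation passes are deterministic.

All neural components run on a small reverse-mode autodiff core over numpy
(`radpath._autodiff`, `radpath._nn`) written for this package; gradients of
every operator, including the 3D convolution and the InfoNCE objective,
are verified against central finite differences in the test suite.

## Retrieval and fusion

After training, the frozen model embeds the full paired cohort once into a
library of (patient id, ê_img, ê_path) records, sorted by id. A query
imaging embedding retrieves proxies directly against the stored *pathology*
embeddings (the literal cross-modal argmax); a documented alternative mode
matches imaging-to-imaging and returns the paired pathology embedding —
both readings of the retrieval step are defensible, so both ship, with the
cross-modal form as default. For k = 1 the proxy is the best record's
ê_path verbatim; for k > 1 the top-k pathology embeddings are combined
with weights max(similarity, 0) normalized to sum 1 (uniform if all are
nonpositive) and re-normalized to unit length. Ties break by patient-id
order. K is small, so retrieval is an exact scan — the brute-force oracle
and the implementation coincide by construction and are cross-checked
anyway.

The survival input is the flat concatenation [imaging feature; proxy
embedding] — "channel-wise" fusion reduces to vector concatenation because
the proxy is a vector, not a feature map. The classifier is a
one-hidden-layer network (hidden 32) on standardized features, trained
with cross-entropy under the same optimizer schedule; when a validation
split is given, the epoch with the best validation AUROC is kept (the
selection criterion is otherwise unstated, so best-validation is the
documented default). Three input modes exist: imaging-only,
imaging + trained proxy, and imaging + proxy from a *randomly initialized*
alignment model — the control that distinguishes learned cross-modal
structure from the mere presence of 256 extra dimensions.

## Metrics

Ranks of the true cross-modal match are pessimistic under ties (equal
similarities count against the query), so recall never benefits from
degenerate embeddings. Recall@k and MRR have analytic uniform-ranking
baselines k/N and H_N/N used throughout as reference levels. AUROC is the
Mann–Whitney rank statistic with half-weight ties — exact, and invariant
to monotone score transforms. Sensitivity, specificity, accuracy and F1
are computed at threshold 0.5 (score ≥ threshold predicts the positive,
longer-surviving class). With a single-class label vector AUROC is
reported as nan while threshold metrics are still computed.

## Slide preprocessing

Tiling is a regular non-overlapping grid; partial border tiles are dropped
(no border rule is established for this kind of pipeline, and padding
would fabricate tissue). Otsu's threshold is computed once per slide from
the 256-bin luminance histogram, maximizing ω₀ω₁(μ₀−μ₁)² with class 0 =
levels ≤ t and ties resolved to the lowest level; tissue is luminance
*below* the threshold (H&E tissue is darker than glass), and a tile is
kept when its tissue fraction reaches 0.5. Both the per-slide scope of the
threshold and the 0.5 cutoff are judgment calls, exposed as parameters.

Macenko normalization uses optical density OD = −log((I+1)/(I₀+1)) with
I₀ = 255 — the symmetric +1 offset makes a pixel at I₀ have OD exactly 0,
so pure white is a fixed point of normalization. Pixels with OD ≤ β = 0.15
in every channel are background and discarded; the top-2 singular
directions of the remaining OD cloud define the stain plane; stain vectors
are the directions at the 1st and 99th angular percentiles, sign-fixed
nonnegative and ordered hematoxylin-first (larger blue-channel OD weight).
Concentrations are solved by exact nonnegative least squares (2-variable
case, vectorized) because concentrations are physical quantities;
per-stain 99th-percentile concentrations are matched to the reference
model's before re-rendering through Beer–Lambert. The shipped reference is
the conventional H&E OD matrix (H = [0.65, 0.70, 0.29],
E = [0.07, 0.99, 0.11], columns normalized) with ceilings (1.97, 1.03),
overridable everywhere. A rank-1 OD cloud (single-stain tile; singular
value ratio below 0.02, an order of magnitude above what quantization
noise produces) raises an estimation error, and the slide-level
convenience wrapper keeps such tiles un-normalized rather than dropping
them.

## Synthetic cohort: what it emulates and what it does not

Each patient has a latent state z ~ N(0, I_L) (L = 4 by default). The
imaging view is A·z plus isotropic Gaussian noise (sd 2.5 by default over
512 dimensions); every pathology patch is B·[z; h(z)] plus small noise
(sd 0.1), with h(z) = z² − 1 applied coordinate-wise and N_i ~ U{8..32}
patches per patient. A and B are drawn once per seed and stored with the
cohort, so the modality link is reproducible. The survival logit is
w·h(z); log(OS/12) = logit + ε with ε standard logistic, so
P(OS > 12) = sigmoid(logit) exactly (a log-logistic survival time whose
location is tied to the logit — this choice makes the binary label law
analytic and testable). Exactly 12.0 months is class 0.

Two structural choices deserve emphasis:

- **Directional survival weights.** The default w alternates signs
  (±1.5/√L), making the logit a *directional* function of z. This is
  deliberate: the projection head's LayerNorm is scale-invariant and the
  imaging view A·z is homogeneous in z, so imaging embeddings carry the
  direction of z but not its norm. A radial survival signal (equal-sign
  weights) would be invisible to cosine retrieval by construction, and the
  mediation mechanism the simulator exists to exhibit could never operate.
- **Mediation asymmetry.** Survival depends on h(z), which patches expose
  *linearly* at low noise while imaging exposes it only through z under
  heavy noise — a small classifier cannot reliably synthesize the
  quadratic from noisy imaging, but the retrieved neighbor's pathology
  embedding carries it almost directly. Zeroing w removes the gap between
  the bimodal and unimodal classifiers (tested over 5 seeds); restoring it
  re-opens the gap.

The simulator reproduces pairing structure, variable patch counts, a
shared cross-modal signal and pathology-mediated survival. It does not
attempt MRI contrast physics, histology texture, class imbalance,
censoring, multi-slide patients (one patch set per patient; how multiple
WSIs map to one MRI is genuinely ambiguous and left out), or cohort
substructure such as molecular subtypes. The last omission matters for one
qualitative result: with a smooth i.i.d. latent, similarity rankings stay
informative deep into the library, so averaging the top-k proxies acts as
a variance-reducing ensemble and k = 10 tends to match or beat k = 1. In
heterogeneous real cohorts additional neighbors bring in unrelated
histology and the ordering reverses. Passing the simulation studies
therefore says nothing about the optimal k on real data.

## Study sizes and defaults

Desk-scale runs use feature bypass with C = 64: alignment on 98 train / 38
validation paired patients (the library holds all 136), survival on 600
imaging-only patients split 70/30, alignment for 30 epochs at τ = 0.07 and
the survival head for 50 epochs. The low-noise preset (imaging sd 1.0,
patch sd 0.1) is used for alignment-recovery studies (60 train / 38
held-out). The full 100-epoch schedule, the τ grid, volume encoding and
C = 1536 are configuration switches. A complete pipeline run takes roughly
ten seconds on one CPU; `scripts/acceptance.py` (five-seed study included)
about a minute.

## Numerical notes and limitations

- InfoNCE and its analytic gradient are verified to 1e-5 against finite
  differences; the uniform-matrix identity L = ln N and the transpose
  symmetry hold exactly.
- Contrastive batches of size 1 are rejected (no negatives); a trailing
  batch of size 1 is merged into the previous batch.
- l2-normalization rejects vectors with norm below 1e-12; the weighted
  proxy falls back to the single best match in the measure-zero event that
  the weighted neighbor mean cancels to zero.
- Determinism holds per platform (single-threaded numpy evaluation);
  bit-identical results across BLAS implementations are not promised.
- The imaging-only survival baseline is limited by classifier capacity by
  design; with a much larger classifier and training budget the unimodal
  model could in principle recover more of the quadratic signal and narrow
  the reported gap.
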