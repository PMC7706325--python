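# Methods

`lspheno` quantifies *response-to-treatment* from longitudinal image
sequences without hand-engineered trait extraction. The method has three
stages: a treatment-discriminative embedding, a decoder back to image space,
and a geodesic path length through decoded image space that serves as a
single scalar trait per individual. A synthetic circle study with simulated
genetics provides a fully controlled validation loop.

## Data model

A study is a set of individuals, each with a complete, ordered sequence of U
images and a treated/control label; a genotype identifier groups replicates.
Sequences with missing time points are rejected rather than imputed: the
sequence model consumes fixed-length trajectories and a silent gap would
shift the temporal alignment of every downstream quantity. All images are
resized to one working resolution (default 64x64, must be divisible by 16)
and standardized per image to zero mean and unit variance (population
standard deviation, epsilon 1e-8 so constant images map to zeros).
Per-image — rather than dataset-global — standardization removes per-image
lighting offsets, which would otherwise be a nuisance feature correlated
with nothing.

The train/validation split is by genotype (80/20, rounded, at least one
validation genotype), so all replicates and both conditions of a genotype
land on the same side. Splitting by individual would leak: the treated and
control replicates of one genotype share morphology, and the validation
loss would no longer measure generalization across genotypes.

## Embedding network

Each image passes through a four-layer CNN (3x3 kernels, stride 2, channel
widths 16/32/64/128, ReLU) followed by one fully connected layer of width
n = 16 whose activations *are* the latent embedding. The U per-timepoint
embeddings feed a single-layer LSTM (hidden width 64, forget-gate bias 1);
the final LSTM state drives a two-layer head (64 -> 16 -> 1) producing the
treated-vs-control logit, trained with sigmoid cross-entropy. Adam with
learning rate 1e-3; batches of m = 8 sequences.

Alongside cross-entropy and L2 weight decay (coefficient 1e-5, summed
unweighted with the other terms) the loss includes the *generalized
variance* of the batch embeddings,

    C = E^T E / (mU) + lambda_v I,     L_v = det(C),

where E is the column-centered (mU) x n matrix of all embeddings in the
batch and lambda_v = 0.2. The determinant penalizes volume: latent
directions that do not help classification collapse, so the decoder later
only has to model treatment-relevant variation. The diagonal constant keeps
C invertible when a direction has collapsed and removes the degenerate
optimum of shrinking a single direction to zero out the determinant while
leaving the others large. det(C) >= lambda_v^n always, with equality
exactly at zero batch variance. Centering is per batch, following the
definition of E as a batch quantity. The gradient is computed analytically
(d det/dE = det(C) * 2/(mU) * E_c C^{-1}; the centering correction vanishes
because the columns of E_c sum to zero) in float64 for stability.

The validation set is evaluated once per epoch; the returned model is the
best-validation-accuracy checkpoint, taking the latest evaluation on ties,
with early stopping after 20 evaluations without an accuracy improvement.
Selection is on accuracy rather than validation cross-entropy because once
predictions become confident the BCE can rise monotonically while accuracy
is flat — loss-based selection then restores a nearly untrained model; the
latest tied checkpoint carries the most-trained features. The run is
*converged* when the selected checkpoint's validation accuracy reaches the
configurable threshold (default 0.75). Because this is a maximum over
epoch evaluations it is slightly optimistic on small validation sets; the
log also records the final evaluation's accuracy as an unbiased estimate
at the stopping point (on label-permuted data the former stays well below
the 0.75 gate at study scale while the latter sits at chance).

Training-time augmentation (horizontal flips, brightness/contrast jitter,
random crop-and-resize) is available for small natural datasets and off by
default; the synthetic study does not need it.

### Restart selection

Classification accuracy does not measure how much image detail the latent
space retains, and restarts vary in how much survives: once the classifier
has converged, continued training lets the variance penalty erode
within-condition detail that the decoder (and hence the trait) needs. The
pipeline therefore trains a few independent restarts (default 3, seeds
derived from the stage seed) and keeps the one whose frozen embeddings are
most decodable, scored by the held-out reconstruction MSE of a short probe
decoder (default 2500 steps) fit per candidate; the winning probe is then
trained onward as the final decoder. The score is internal — it uses only
the images themselves. Non-converged restarts are never selected while a
converged one exists.

## Decoder

The decoder g maps latent vectors back to standardized image space. The
16-vector enters as a 4x4 single-channel map — deliberately no dense layer,
which limits the decoder's ability to memorize individuals — followed by
two stride-1 3x3 convolutions at 128 channels and a stack of stride-2
transposed convolutions (non-overlapping 2x2 kernels, channel widths
halving to a floor of 32) up to the working resolution; the last transposed
convolution maps linearly to the image channels. An optional 3x3 smoothing
convolution at full resolution is available but off by default — in the
sweep it improved reconstruction MSE slightly while costing several times
more per decoder pass, which the geodesic stage cannot afford. The decoder
is trained by mean-squared-error
reconstruction of the training images against their frozen embeddings, Adam
at the lower learning rate 1e-4; 10% of training images are held out and
the returned parameters are those with the best held-out MSE.

Because embeddings only retain treatment-correlated features, the decoder
output at a latent point tends toward the mean of all images embedding
nearby: decodes are blurry and individual-specific features (e.g., a static
marker uncorrelated with condition) are attenuated. This is intended — a
smooth, denoised image manifold is what makes path lengths meaningful.

## Geodesic trait

Latent space is not Euclidean: distances are meaningful only through g.
The response trait of an individual is the discrete geodesic length of its
latent trajectory measured in image space:

    T = sum_{i=1..j} || g(z_i) - g(z_{i-1}) ||^2,

minimized over the free vertices. In longitudinal mode the embeddings of
all U observed time points are pinned as stationary vertices and k free
vertices are interpolated into each gap, k maximal with U + (U-1)k <= 30
(a memory-motivated budget; with U = 30 no interpolation happens). In
cross-sectional mode the path runs between the treated and the control
final-timepoint embeddings of one genotype, with only the two endpoints
pinned. Free vertices start at linear interpolation (all-at-once
optimization, no progressive subdivision) and are moved by Adam (lr 0.15,
up to 150 iterations) on the summed squared image-space distance; a path
freezes once its per-iteration relative objective change falls below 1e-4,
and frozen paths cost nothing further. These values were chosen from a
convergence study: the objective plateaus by roughly iteration 100-150 and
the plateau is insensitive to the learning rate over 0.05-0.3, so more
iterations buy nothing. Every path retains the best vertices seen, so the
reported objective never exceeds the linear-interpolation initialization;
with a linear decoder the optimizer reproduces the closed-form optimum
||A(z_end - z_start)||^2 / j at equally spaced vertices (tested to 0.1%).

A structural note: per gap, the summed squared segment objective is bounded
below by chord^2/(k+1) (Cauchy-Schwarz), the value attained if the decoder
could render straight-line image cross-fades. In practice the optimum sits
above this bound (the decoder renders disc-like images, not blends), and
the optimized trait is a noisier relative of the chord-sum trait one gets
from the stationary vertices alone.

The squared-distance sum is the primary trait (`trait_sq`); the unsquared
path length (`trait_len`) is reported alongside, since both readings of
"total path length" are defensible and the two are monotonically related
for near-uniform segmentations. With phase boundaries set (longitudinal
only), each segment is attributed to the phase of its earlier stationary
anchor and per-phase sums partition the total exactly.

All paths of a dataset are optimized jointly in one batched loop; decoded
stationary vertices are computed once and cached since they never move.

## Synthetic circle study

The generator renders each individual as a centered antialiased white disc
on black, diameter d0 + rate * t over U = 6 time points on 64x64 images.
d0 ~ N(10, 1.5) px; rate ~ N(7, 1) px/timepoint for control and N(4, 1)
under treatment. Treated growth additionally gains 0.25 px/timepoint per
active hypothetical QTL (7 loci, Bernoulli(0.5) per genotype) and 0.75
px/timepoint per minor allele at one causal marker of a synthetic SNP panel
(independent biallelic loci, per-marker MAF uniform in [0.1, 0.45], calls
binomial(2, p)). These values make the conditions overlap but remain
separable, keep final diameters inside the frame (out-of-range diameters
are clamped and counted), and give the causal locus an effect comparable to
the polygenic background. Antialiased edges (one-pixel linear coverage
ramp) make pixel counts differentiable in diameter, so ground truth is
recoverable: final pixel counts regress on true final squared diameter with
R^2 > 0.99.

The ground-truth phenotype is *relative pixel growth*,
(final - initial)/initial count of above-threshold pixels. The panel has
independent loci by construction, so the association demonstration uses
per-marker ordinary least squares with a Bonferroni threshold alpha/n_snps
(default alpha 0.01) — no kinship correction is needed or applied; real
panels with structure should use a dedicated mixed-model GWAS tool.

What the simulator does *not* emulate: background clutter, lighting drift,
perspective and zoom changes, morphological complexity, linkage
disequilibrium, population structure. Passing the synthetic validation
shows the machinery is sound end-to-end, not that the method is robust to
natural-image nuisance variation.

## Validation loop and problem sizes

`run_synthetic_benchmark` simulates a study, runs the full pipeline, and
reports: Pearson R between the per-individual longitudinal trait and
relative pixel growth; and, matching the cross-sectional protocol used for
synthetic experiments, a per-genotype cross-sectional association scan with
`causal_recovered` and `false_positives` under Bonferroni p < 0.01. If the
embedding does not converge the benchmark reports that and attempts no
association.

Default problem sizes are chosen for a single CPU: 60 individuals per
condition at 64x64; embedding restarts train a few hundred steps each
(early stopping), the selected probe decoder continues to 12,500 total
steps, and path optimization runs to its freeze tolerance within 150
iterations. A full pipeline run takes several minutes and the packaged
validation script (`scripts/acceptance.py`) repeats it for two
independently seeded studies. One master seed
drives genotype sampling, causal-locus choice, simulation, the split,
weight initialization, batching and holdout selection through independent
derived stage seeds, making runs bit-reproducible on one platform.

## Numerical choices and degenerate inputs

- Convolutions are im2col/BLAS; the stride-2 transposed convolution with a
  2x2 kernel reduces to a per-pixel matmul (no overlap), which is what makes
  CPU-only geodesic optimization practical. All checked against central
  finite differences at float64.
- det(C) and its gradient use float64 regardless of network precision.
- Degenerate paths (identical endpoints) have objective 0 and are left at
  initialization. Monomorphic markers report beta 0, p 1. Constant images
  standardize to zeros. Non-finite losses raise immediately with the step
  index rather than propagating NaNs.
- PCA embedding plots are approximate by construction (latent distances are
  only semantic through the decoder) and are labelled as such.

## Known limitations

- Binary conditions only (sigmoid head); multi-condition studies would need
  a softmax head and one-vs-one analyses.
- Fixed-length complete sequences only.
- The trait is relative to the study population: it has no absolute unit
  and is not comparable across separately trained runs.
- Nondeterminism across platforms: results are seeded and reproducible on
  one BLAS/platform, but bitwise reproducibility across different BLAS
  builds is not guaranteed.
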