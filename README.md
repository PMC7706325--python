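# lspheno — latent-space phenotyping of treatment response

`lspheno` measures how individual plants respond to an experimental
treatment (drought, nutrient deficiency, …) directly from longitudinal
image sequences, without hand-engineering an image-analysis pipeline for a
named trait. The output is one scalar *response-to-treatment* value per
individual, suitable for downstream association mapping or response rating.

It is aimed at phenotyping/quantitative-genetics researchers running
treatment-vs-control imaging studies who want a trait that captures
*whatever* visually distinguishes treated from control material — size,
shape, color, or combinations no single engineered trait would capture.

## Method

Three stages, run in sequence:

1. **Embedding.** A four-layer CNN maps each image to an n = 16 dimensional
   latent point (the activations of its final fully connected layer); an
   LSTM over the U per-timepoint embeddings feeds a small head trained with
   sigmoid cross-entropy to classify sequences as treated vs control.
   Besides L2 weight decay, the loss includes the *generalized variance*

       C = EᵀE/(mU) + λᵥI,   Lᵥ = det(C),   λᵥ = 0.2,

   of the centered batch embedding matrix E, which collapses latent
   directions the classification does not need.
2. **Decoding.** A convolutional generator g : Z → X is trained to
   reconstruct training images from their frozen embeddings (MSE, Adam,
   lr 1e-4). Decodes are deliberately blurry mean-like images — g defines
   the manifold on which distances are meaningful.
3. **Geodesic trait.** Each individual's latent trajectory is scored by the
   discrete geodesic objective

       T = Σᵢ ‖g(zᵢ) − g(zᵢ₋₁)‖²,

   with the embeddings of observed time points pinned as stationary
   vertices, free vertices interpolated up to a 30-vertex budget, and the
   free vertices optimized from a linear-interpolation start. *Longitudinal*
   mode traces first → last time point per individual; *cross-sectional*
   mode traces treated-final → control-final per genotype. `trait_sq` (the
   squared sum above) is the primary trait; the unsquared length
   `trait_len` is reported alongside.

A synthetic validation module renders treatment studies of growing white
discs whose growth rates carry simulated QTL and one causal SNP, so the
entire pipeline can be exercised end-to-end against ground truth without
any external data. See `docs/methods.md` for modelling details and all
defaults.

## Worked example

`examples/` contains one short script per capability. The core loop:

```python
from lspheno import (
    CircleConfig, EmbeddingConfig, DecoderConfig, PathSpec, PathOptConfig,
    generate_genotypes, generate_circle_dataset, split_train_validation,
    train_embedding, train_decoder, compute_traits,
    relative_pixel_growth, trait_phenotype_correlation,
)
import numpy as np

genotypes = generate_genotypes(20, 50, causal_index=3, seed=11)
dataset, _ = generate_circle_dataset(
    CircleConfig(n_per_condition=20, image_size=64, seed=7), genotypes)
train, val = split_train_validation(dataset, seed=1)

embedding = train_embedding(train, val, EmbeddingConfig(max_steps=400, seed=1))
decoder = train_decoder(embedding, train, DecoderConfig(max_steps=3000, seed=1))
traits = compute_traits(dataset, embedding, decoder,
                        PathSpec(mode="longitudinal"), PathOptConfig(max_iters=50))

growth = np.array([relative_pixel_growth(s) for s in dataset.samples])
r, p = trait_phenotype_correlation(traits["trait_sq"].to_numpy(), growth)
print(r, p)
```

Running `python examples/03_geodesic_traits.py` prints the head of the
trait table:

```
individual_id genotype_id condition    trait_sq  trait_len
      g0000_T       g0000   treated 1952.602295 219.974579
      g0000_C       g0000   control 2456.790527 245.689972
      g0001_T       g0001   treated 1416.802246 187.437988
      g0001_C       g0001   control 2732.534912 260.603302

Pearson R(trait_sq, relative pixel growth) = 0.739 (p = 5.23e-08)
```

Treated individuals grow less, so their paths through decoded image space
are shorter (`trait_sq` lower), and the learned trait recovers the
hand-measured ground-truth phenotype. This demonstration runs at a small
scale (20 individuals per condition, short training, no restart
selection); the packaged validation at 60 per condition with restart
selection reaches R ≈ 0.83.
`examples/04_association_scan.py` completes the loop: cross-sectional
traits per genotype, a per-marker regression scan, and a Manhattan plot in
which the planted causal SNP clears the Bonferroni p < 0.01 line with no
false positives.

The same stages are available from the shell for manifest-based datasets
(CSV rows of `individual_id,genotype_id,condition,timepoint,image_path`):

```bash
lsp simulate --out study/ --seed 1
lsp run --manifest study/manifest.csv --image-root study/ --out run1/ --seed 1
lsp traits --manifest study/manifest.csv --image-root study/ \
    --embedding run1/embedding.npz --decoder run1/decoder.npz \
    --out traits.csv --mode cross_sectional
lsp benchmark --out bench/ --seed 1
```

`lsp run` exits with status 3 (distinct from a crash) when the embedding
fails its validation-accuracy convergence gate — e.g. when there is no
consistent visual difference between conditions — and writes no trait
table in that case.

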