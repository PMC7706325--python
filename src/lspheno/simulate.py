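"""Synthetic treatment-study generator: growing circles with simulated QTL.

Each individual is rendered as a white disc on a black background whose
diameter grows linearly over U time points. The initial diameter is normal;
the growth rate is normal with a condition-dependent mean (treatment slows
growth). Under treatment the rate is additionally shifted by seven
hypothetical QTL (Bernoulli states, additive effect) and by the
minor-allele count at one causal locus of a matching synthetic SNP panel —
so the image data carry a genetic signal that the full pipeline should
recover by association.

Defaults are chosen so the conditions overlap but remain separable on
64 x 64 images: d0 ~ N(10, 1.5) px, rate N(7, 1) px/timepoint for control
vs. N(4, 1) treated, QTL effect 0.25, causal effect 0.75 per allele copy.
Disc edges are antialiased (subpixel coverage) so pixel counts vary smoothly
with diameter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    Condition,
    Dataset,
    GenotypeMatrix,
    SampleSequence,
    save_dataset,
    write_genotypes,
)

__all__ = [
    "CircleConfig",
    "SyntheticTruth",
    "render_disc",
    "generate_genotypes",
    "generate_circle_dataset",
    "relative_pixel_growth",
    "write_synthetic_run",
]


@dataclass
class CircleConfig:
    n_per_condition: int = 60
    n_timepoints: int = 6
    image_size: int = 64
    d0_mean: float = 10.0
    d0_sd: float = 1.5
    rate_mean_control: float = 7.0
    rate_mean_treated: float = 4.0
    rate_sd: float = 1.0
    n_qtl: int = 7
    qtl_prob: float = 0.5
    qtl_effect: float = 0.25
    causal_effect: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.d0_sd <= 0 or self.rate_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")


@dataclass
class SyntheticTruth:
    """Ground truth per individual plus the genotype panel used."""

    per_individual: pd.DataFrame  # individual_id, genotype_id, condition, d0, rate, qtl states, causal count
    genotypes: GenotypeMatrix
    causal_index: int
    clipped: int = 0  # diameters clamped to stay inside the frame


def render_disc(image_size: int, diameter: float) -> np.ndarray:
    """Antialiased white disc, centered; returns (H, W, 1) float32 in [0, 1].

    Pixel intensity approximates subpixel coverage: 1 inside, 0 outside,
    with a one-pixel linear ramp across the boundary.
    """
    c = (image_size - 1) / 2.0
    yy, xx = np.ogrid[:image_size, :image_size]
    dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    img = np.clip(diameter / 2.0 - dist + 0.5, 0.0, 1.0).astype(np.float32)
    return img[..., None]


def generate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: Tuple[float, float] = (0.1, 0.45),
    causal_index: Optional[int] = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Independent biallelic loci: per-SNP minor-allele frequency uniform in
    ``maf_range``, calls binomial(2, p) minor-allele counts."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 0.5, got {maf_range}")
    if causal_index is not None and not (0 <= causal_index < n_snps):
        raise ValueError(f"causal_index {causal_index} out of range for {n_snps} SNPs")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    calls = rng.binomial(2, p[None, :], size=(n_individuals, n_snps))
    return GenotypeMatrix(
        individual_ids=[f"g{i:04d}" for i in range(n_individuals)],
        snp_ids=[f"snp{j:04d}" for j in range(n_snps)],
        calls=calls,
        causal_index=causal_index,
    )


def generate_circle_dataset(config: CircleConfig, genotypes: GenotypeMatrix):
    """Render the circle study: one treated and one control individual per
    genotype row, with treated growth rates modulated by QTL and the causal
    allele. Returns ``(Dataset, SyntheticTruth)``."""
    g = config.n_per_condition
    if len(genotypes.individual_ids) < g:
        raise ValueError(f"need >= {g} genotype rows, got {len(genotypes.individual_ids)}")
    if genotypes.causal_index is None:
        raise ValueError("genotypes.causal_index must be set for the circle simulation")
    rng = np.random.default_rng(config.seed)
    u = config.n_timepoints
    size = config.image_size
    max_d = size - 2.0

    qtl_states = rng.binomial(1, config.qtl_prob, size=(g, config.n_qtl))
    causal_counts = genotypes.calls[:g, genotypes.causal_index].astype(float)

    samples = []
    rows = []
    clipped = 0
    for gi in range(g):
        gid = genotypes.individual_ids[gi]
        for cond in (Condition.treated, Condition.control):
            d0 = rng.normal(config.d0_mean, config.d0_sd)
            if cond is Condition.treated:
                rate = rng.normal(config.rate_mean_treated, config.rate_sd)
                rate += config.qtl_effect * qtl_states[gi].sum()
                rate += config.causal_effect * causal_counts[gi]
            else:
                rate = rng.normal(config.rate_mean_control, config.rate_sd)
            imgs = []
            for t in range(u):
                d = d0 + rate * t
                if d > max_d or d < 1.0:
                    clipped += 1
                    d = min(max(d, 1.0), max_d)
                imgs.append(render_disc(size, d))
            ind_id = f"{gid}_{'T' if cond is Condition.treated else 'C'}"
            samples.append(
                SampleSequence(
                    individual_id=ind_id,
                    genotype_id=gid,
                    condition=cond,
                    images=np.stack(imgs),
                    timepoint_labels=list(range(u)),
                )
            )
            row = {
                "individual_id": ind_id,
                "genotype_id": gid,
                "condition": cond.value,
                "d0": d0,
                "rate": rate,
                "causal_count": causal_counts[gi],
            }
            row.update({f"qtl{q}": int(qtl_states[gi, q]) for q in range(config.n_qtl)})
            rows.append(row)

    dataset = Dataset(samples=samples, image_shape=(size, size, 1))
    truth = SyntheticTruth(
        per_individual=pd.DataFrame(rows),
        genotypes=genotypes,
        causal_index=genotypes.causal_index,
        clipped=clipped,
    )
    return dataset, truth


def render_leaf_pair(image_size: int, length: float, angle_deg: float, width_frac: float = 0.28) -> np.ndarray:
    """Two white ellipse 'leaves' leaving the center at ±angle from horizontal.

    Antialiased like :func:`render_disc`; returns (H, W, 1) float32 in [0, 1].
    Used by the angle-mode smoke data where treatment changes inclination
    rather than size.
    """
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[:image_size, :image_size].astype(np.float32)
    x = xx - c
    y = c - yy  # mathematical orientation
    img = np.zeros((image_size, image_size), dtype=np.float32)
    half = length / 2.0
    b = max(width_frac * half, 1.0)
    for sign in (1.0, -1.0):
        t = np.deg2rad(angle_deg) * sign
        # rotate into the leaf frame; the leaf extends along +u from the center
        u = x * np.cos(t) * sign + y * np.sin(t)
        v = -x * np.sin(t) * sign + y * np.cos(t)
        # ellipse centered half-way along the leaf
        r = np.sqrt(((u - half) / half) ** 2 + (v / b) ** 2)
        cover = np.clip((1.0 - r) * half + 0.5, 0.0, 1.0)
        img = np.maximum(img, cover)
    return img[..., None]


def generate_angle_dataset(config: CircleConfig, angle_control: float = 15.0,
                           angle_treated: float = 45.0, angle_sd: float = 5.0):
    """Angle-mode smoke data: leaf inclination, not size, separates conditions.

    Plant length grows at a condition-INDEPENDENT rate while the leaf
    elevation angle is drawn per individual around a condition-dependent
    mean, so a pixel-count classifier carries no signal. Reuses the size
    fields of ``config`` for the length process. Returns ``(Dataset, truth
    DataFrame)``; this is a harder smoke test, not part of the circle study.
    """
    rng = np.random.default_rng(config.seed)
    u = config.n_timepoints
    size = config.image_size
    samples = []
    rows = []
    for gi in range(config.n_per_condition):
        for cond in (Condition.treated, Condition.control):
            d0 = rng.normal(config.d0_mean, config.d0_sd)
            rate = rng.normal(config.rate_mean_control, config.rate_sd)
            mean_angle = angle_treated if cond is Condition.treated else angle_control
            angle = rng.normal(mean_angle, angle_sd)
            max_len = size / 2.0 - 1.0  # leaves extend from the center
            imgs = [render_leaf_pair(size, min(d0 + rate * t, max_len), angle) for t in range(u)]
            ind_id = f"a{gi:04d}_{'T' if cond is Condition.treated else 'C'}"
            samples.append(
                SampleSequence(
                    individual_id=ind_id, genotype_id=f"a{gi:04d}", condition=cond,
                    images=np.stack(imgs), timepoint_labels=list(range(u)),
                )
            )
            rows.append({"individual_id": ind_id, "condition": cond.value, "angle": angle, "rate": rate})
    return Dataset(samples=samples, image_shape=(size, size, 1)), pd.DataFrame(rows)


def relative_pixel_growth(sequence, threshold: float = 0.5) -> float:
    """(final - initial) / initial count of above-threshold pixels."""
    imgs = sequence.images
    initial = int((imgs[0] > threshold).sum())
    final = int((imgs[-1] > threshold).sum())
    if initial == 0:
        raise ValueError(f"{sequence.individual_id}: no above-threshold pixels at the initial time point")
    return (final - initial) / initial


def write_synthetic_run(dataset: Dataset, truth: SyntheticTruth, out_dir) -> dict:
    """Write manifest + PNGs, the genotype TSV and the truth CSV."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = save_dataset(dataset, out_dir)
    geno_path = os.path.join(out_dir, "genotypes.tsv")
    write_genotypes(truth.genotypes, geno_path)
    truth_path = os.path.join(out_dir, "truth.csv")
    truth.per_individual.to_csv(truth_path, index=False)
    return {"manifest": manifest, "genotypes": geno_path, "truth": truth_path, "causal_index": truth.causal_index}
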