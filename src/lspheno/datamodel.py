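"""Dataset model and I/O for longitudinal treatment-study image sequences.

A study is a collection of individuals, each observed as an ordered sequence
of U images under either a treated or a control condition. Sequences must be
complete: an individual missing any time point is rejected outright, because
the downstream sequence model consumes fixed-length trajectories and a gap
would silently shift the temporal alignment.

Images are held in memory as float32 arrays in [0, 1] with shape
(U, H, W, C); all individuals in one dataset share U and the image shape.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["individual_id", "genotype_id", "condition", "timepoint", "image_path"]


class DatasetValidationError(ValueError):
    """Raised when a dataset violates the completeness/shape contract."""


class Condition(str, Enum):
    treated = "treated"
    control = "control"


@dataclass
class SampleSequence:
    """One individual's ordered image sequence plus labels."""

    individual_id: str
    genotype_id: str
    condition: Condition
    images: np.ndarray  # (U, H, W, C) float32 in [0, 1]
    timepoint_labels: list

    def __post_init__(self):
        self.condition = Condition(self.condition)
        img = np.asarray(self.images, dtype=np.float32)
        if img.ndim == 3:
            img = img[..., None]
        if img.ndim != 4:
            raise DatasetValidationError(
                f"{self.individual_id}: images must be (U, H, W, C), got shape {img.shape}"
            )
        self.images = img
        u = img.shape[0]
        if u < 2:
            raise DatasetValidationError(f"{self.individual_id}: need at least 2 time points, got {u}")
        if len(self.timepoint_labels) != u:
            raise DatasetValidationError(f"{self.individual_id}: {len(self.timepoint_labels)} labels for {u} images")
        tp = list(self.timepoint_labels)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise DatasetValidationError(f"{self.individual_id}: timepoint labels must be strictly increasing: {tp}")
        self.timepoint_labels = tp

    @property
    def n_timepoints(self) -> int:
        return self.images.shape[0]


@dataclass
class Dataset:
    """A validated collection of complete image sequences."""

    samples: list
    image_shape: tuple  # (H, W, C)
    condition_pairing: Optional[dict] = None  # genotype_id -> (treated_id, control_id)

    def __post_init__(self):
        if not self.samples:
            raise DatasetValidationError("no samples")
        u0 = self.samples[0].n_timepoints
        tp0 = self.samples[0].timepoint_labels
        for s in self.samples:
            if tuple(s.images.shape[1:]) != tuple(self.image_shape):
                raise DatasetValidationError(
                    f"{s.individual_id}: image shape {s.images.shape[1:]} != dataset shape {self.image_shape}"
                )
            if s.n_timepoints != u0 or s.timepoint_labels != tp0:
                raise DatasetValidationError(
                    f"{s.individual_id}: timepoints {s.timepoint_labels} differ from {tp0}; "
                    "all sequences must share one complete timepoint grid"
                )
        conds = {s.condition for s in self.samples}
        if Condition.treated not in conds or Condition.control not in conds:
            raise DatasetValidationError("dataset must contain at least one treated and one control sample")
        if self.condition_pairing is None:
            self.condition_pairing = infer_condition_pairing(self.samples)

    @property
    def n_timepoints(self) -> int:
        return self.samples[0].n_timepoints

    @property
    def timepoint_labels(self) -> list:
        return self.samples[0].timepoint_labels

    def genotype_ids(self) -> list:
        seen = []
        for s in self.samples:
            if s.genotype_id not in seen:
                seen.append(s.genotype_id)
        return seen

    def subset(self, genotypes) -> "Dataset":
        keep = set(genotypes)
        samples = [s for s in self.samples if s.genotype_id in keep]
        pairing = None
        if self.condition_pairing:
            pairing = {g: v for g, v in self.condition_pairing.items() if g in keep}
        return Dataset(samples=samples, image_shape=self.image_shape, condition_pairing=pairing or None)

    def images_array(self) -> np.ndarray:
        """Stack to (n_samples, U, H, W, C)."""
        return np.stack([s.images for s in self.samples])

    def labels_array(self) -> np.ndarray:
        """1.0 for treated, 0.0 for control."""
        return np.array([1.0 if s.condition is Condition.treated else 0.0 for s in self.samples], dtype=np.float32)


def infer_condition_pairing(samples) -> Optional[dict]:
    """Genotypes with exactly one treated and one control replicate pair up."""
    by_geno: dict = {}
    for s in samples:
        by_geno.setdefault(s.genotype_id, []).append(s)
    pairing = {}
    for g, reps in by_geno.items():
        treated = [s.individual_id for s in reps if s.condition is Condition.treated]
        control = [s.individual_id for s in reps if s.condition is Condition.control]
        if len(treated) == 1 and len(control) == 1:
            pairing[g] = (treated[0], control[0])
    return pairing or None


def _load_image(path: str, image_size: Optional[int], channels: Optional[int]) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        if channels == 3:
            im = im.convert("RGB")
        else:
            im = im.convert("L")
        if image_size is not None and im.size != (image_size, image_size):
            im = im.resize((image_size, image_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = arr[..., None]
    return arr


def load_dataset(manifest_path, image_root=None, image_size: Optional[int] = None,
                 channels: int = 1) -> Dataset:
    """Load and validate a dataset from a CSV manifest.

    The manifest has one row per (individual, timepoint) with columns
    ``individual_id, genotype_id, condition, timepoint, image_path``. Every
    individual must cover the full set of timepoints observed in the study;
    sequences with gaps are rejected rather than imputed.
    """
    df = pd.read_csv(manifest_path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetValidationError(f"manifest missing columns: {missing_cols}")
    if len(df) == 0:
        raise DatasetValidationError("no samples")
    all_timepoints = sorted(df["timepoint"].unique().tolist())
    samples = []
    for ind_id, group in df.groupby("individual_id", sort=False):
        group = group.sort_values("timepoint")
        tps = group["timepoint"].tolist()
        if tps != all_timepoints:
            missing = sorted(set(all_timepoints) - set(tps))
            raise DatasetValidationError(
                f"individual {ind_id!r} is missing timepoint(s) {missing}: sequences with "
                "missing time points cannot be included"
            )
        genos = group["genotype_id"].unique()
        conds = group["condition"].unique()
        if len(genos) != 1 or len(conds) != 1:
            raise DatasetValidationError(f"individual {ind_id!r} has inconsistent genotype/condition labels")
        imgs = []
        for _, row in group.iterrows():
            path = row["image_path"]
            if image_root is not None:
                path = os.path.join(image_root, path)
            try:
                imgs.append(_load_image(path, image_size, channels))
            except FileNotFoundError as exc:
                raise FileNotFoundError(
                    f"row (individual={ind_id!r}, timepoint={row['timepoint']}): {exc}"
                ) from exc
        samples.append(
            SampleSequence(
                individual_id=str(ind_id),
                genotype_id=str(genos[0]),
                condition=Condition(conds[0]),
                images=np.stack(imgs),
                timepoint_labels=tps,
            )
        )
    image_shape = samples[0].images.shape[1:]
    return Dataset(samples=samples, image_shape=tuple(image_shape))


def save_dataset(dataset: Dataset, out_dir) -> str:
    """Write PNG images plus a manifest CSV; returns the manifest path."""
    out_dir = str(out_dir)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows = []
    for s in dataset.samples:
        for t_idx, tp in enumerate(s.timepoint_labels):
            rel = os.path.join("images", f"{s.individual_id}_t{tp}.png")
            arr = np.clip(s.images[t_idx], 0.0, 1.0)
            if arr.shape[-1] == 1:
                arr = arr[..., 0]
            Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(os.path.join(out_dir, rel))
            rows.append(
                {
                    "individual_id": s.individual_id,
                    "genotype_id": s.genotype_id,
                    "condition": s.condition.value,
                    "timepoint": tp,
                    "image_path": rel,
                }
            )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


@dataclass
class GenotypeMatrix:
    """Biallelic marker matrix; entries are minor-allele counts in {0,1,2}."""

    individual_ids: list
    snp_ids: list
    calls: np.ndarray  # (n_individuals, n_snps) int8
    causal_index: Optional[int] = None

    def __post_init__(self):
        calls = np.asarray(self.calls)
        if calls.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError(f"calls shape {calls.shape} inconsistent with id lists")
        if not np.isin(calls, [0, 1, 2]).all():
            raise ValueError("genotype calls must be in {0, 1, 2} with no missing values")
        self.calls = calls.astype(np.int8)
        if self.causal_index is not None and not (0 <= self.causal_index < len(self.snp_ids)):
            raise ValueError(f"causal_index {self.causal_index} out of range")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.calls, index=gm.individual_ids, columns=gm.snp_ids)
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_genotypes(path, causal_index: Optional[int] = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        calls=df.to_numpy(),
        causal_index=causal_index,
    )
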