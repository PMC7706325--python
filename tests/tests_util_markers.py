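"""Test helper: stamp condition-independent corner markers on a dataset."""

import numpy as np

from lspheno.datamodel import Dataset, SampleSequence


def add_corner_markers(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Give a random half of individuals a static bright 3x3 top-left marker.

    The coin is flipped per individual, independent of condition, so the
    marker carries no treatment information. Marked individuals get an
    ``_marked`` id suffix.
    """
    samples = []
    for s in dataset.samples:
        if rng.random() < 0.5:
            imgs = s.images.copy()
            imgs[:, :3, :3, :] = 1.0
            samples.append(
                SampleSequence(
                    individual_id=s.individual_id + "_marked",
                    genotype_id=s.genotype_id,
                    condition=s.condition,
                    images=imgs,
                    timepoint_labels=list(s.timepoint_labels),
                )
            )
        else:
            samples.append(s)
    return Dataset(samples=samples, image_shape=dataset.image_shape)
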