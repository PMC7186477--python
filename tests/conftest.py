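from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcehabitat import io_cli, kinetics, phantom, segmentation, texture


def disk_mask(shape: tuple[int, int], center=None, radius: float = 10.0) -> np.ndarray:
    h, w = shape
    if center is None:
        center = (h / 2, w / 2)
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def seeded_region(rng):
    """A 64x64 image with a non-degenerate disk mask."""
    image = rng.normal(100.0, 25.0, size=(64, 64))
    mask = disk_mask((64, 64), radius=20)
    return image, mask


def cohort_feature_table(
    config: phantom.PhantomConfig,
    phase: str = "P-2",
    region: str = "whole",
    epsilon_baseline: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """In-memory (features, labels) table for one region/phase, using the
    ground-truth lesion masks (segmentation bypass)."""
    post_index = io_cli.PHASE_MAP[phase] - 1
    rows, labels = [], []
    for idx, (series, truth) in enumerate(phantom.generate_cohort(config)):
        sub = segmentation.subtract_phases(
            series.pre_contrast, series.post_contrast[post_index]
        )
        if region == "whole":
            mask = truth.lesion_mask
        else:
            enh = kinetics.relative_enhancement(series, epsilon_baseline)
            labs = kinetics.partition_subregions(
                kinetics.ttp_map(enh), truth.lesion_mask
            )
            mask = labs.labels == io_cli.REGION_CODES[region]
        rows.append(texture.extract_all(sub, mask))
        labels.append(truth.class_label)
    index = [f"case_{i:03d}" for i in range(len(rows))]
    table = pd.DataFrame(rows, index=index)
    return table, pd.Series(labels, index=index)
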