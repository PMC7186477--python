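"""Pixelwise contrast-enhancement kinetics and habitat partitioning.

Relative enhancement is expressed in percent against the pre-contrast
baseline; the time-to-peak (TTP) of each pixel's enhancement curve drives
the rapid / medium / slow habitat partition of the lesion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, EmptyRegionError

# Label codes for SubregionLabelMap arrays.
BACKGROUND = 0
RAPID = 1
MEDIUM = 2
SLOW = 3

LABEL_NAMES = {BACKGROUND: "background", RAPID: "rapid", MEDIUM: "medium", SLOW: "slow"}

#: TTP phases mapped to each habitat: peaks in the first four phases are
#: rapid, fifth or sixth medium, seventh or eighth slow.
RAPID_PHASES = (1, 2, 3, 4)
MEDIUM_PHASES = (5, 6)
SLOW_PHASES = (7, 8)

DEFAULT_EPSILON_BASELINE = 1.0


@dataclass
class DCESeries:
    """One case: a pre-contrast image plus ordered post-contrast phases.

    ``post_contrast[t - 1]`` is the acquisition at phase ``t`` (1-based),
    matching the convention t = 1..8 for the eight post-contrast scans.
    """

    pre_contrast: np.ndarray
    post_contrast: np.ndarray  # (n_phases, H, W)
    phase_interval_s: float = 80.0

    def __post_init__(self) -> None:
        self.pre_contrast = np.asarray(self.pre_contrast, dtype=float)
        self.post_contrast = np.asarray(self.post_contrast, dtype=float)
        if self.post_contrast.ndim != 3:
            raise DimensionError("post_contrast must be a (n_phases, H, W) stack")
        if self.post_contrast.shape[1:] != self.pre_contrast.shape:
            raise DimensionError(
                f"phase shape {self.post_contrast.shape[1:]} != "
                f"pre-contrast shape {self.pre_contrast.shape}"
            )

    @property
    def n_phases(self) -> int:
        return self.post_contrast.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pre_contrast.shape


@dataclass
class EnhancementSeries:
    """Per-pixel percentage enhancement E(x, y, t), t = 1..n_phases.

    ``valid`` marks pixels whose baseline was at least the epsilon guard;
    enhancement at invalid pixels is NaN.
    """

    enhancement: np.ndarray  # (n_phases, H, W), percent
    valid: np.ndarray  # (H, W) bool

    @property
    def n_phases(self) -> int:
        return self.enhancement.shape[0]


@dataclass
class TTPMap:
    """Per-pixel 1-based phase index of peak enhancement (0 where invalid)."""

    ttp: np.ndarray  # (H, W) int
    valid: np.ndarray  # (H, W) bool


@dataclass
class SubregionLabelMap:
    """Per-pixel habitat label in {background, rapid, medium, slow}."""

    labels: np.ndarray  # (H, W) int codes

    def pixels(self, code: int) -> int:
        return int(np.count_nonzero(self.labels == code))


def relative_enhancement(
    series: DCESeries, epsilon_baseline: float = DEFAULT_EPSILON_BASELINE
) -> EnhancementSeries:
    """Percent enhancement against baseline, pixel by pixel.

    E(x, y, t) = (SI(x, y, t) - SI(x, y, t0)) / SI(x, y, t0) * 100 wherever
    the baseline is at least ``epsilon_baseline``; other pixels are flagged
    invalid rather than raising.
    """
    pre = series.pre_contrast
    valid = pre >= epsilon_baseline
    enhancement = np.full_like(series.post_contrast, np.nan)
    enhancement[:, valid] = (
        (series.post_contrast[:, valid] - pre[valid]) / pre[valid] * 100.0
    )
    return EnhancementSeries(enhancement=enhancement, valid=valid)


def ttp_map(enh: EnhancementSeries) -> TTPMap:
    """Earliest 1-based phase attaining the per-pixel enhancement maximum."""
    # np.argmax returns the first occurrence, which implements the
    # earliest-phase tie rule.
    filled = np.where(np.isnan(enh.enhancement), -np.inf, enh.enhancement)
    ttp = np.argmax(filled, axis=0) + 1
    ttp = np.where(enh.valid, ttp, 0)
    return TTPMap(ttp=ttp.astype(int), valid=enh.valid.copy())


def partition_subregions(ttp: TTPMap, mask) -> SubregionLabelMap:
    """Group lesion pixels by TTP: 1-4 rapid, 5-6 medium, 7-8 slow."""
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if mask_arr.shape != ttp.ttp.shape:
        raise DimensionError("TTP map and lesion mask shapes differ")
    inside = mask_arr & ttp.valid
    labels = np.full(mask_arr.shape, BACKGROUND, dtype=int)
    labels[inside & (ttp.ttp <= 4)] = RAPID
    labels[inside & (ttp.ttp >= 5) & (ttp.ttp <= 6)] = MEDIUM
    labels[inside & (ttp.ttp >= 7)] = SLOW
    return SubregionLabelMap(labels=labels)


def subregion_fractions(labels: SubregionLabelMap) -> tuple[float, float, float]:
    """(rapid, medium, slow) fractions of the labeled lesion area."""
    counts = np.array(
        [labels.pixels(RAPID), labels.pixels(MEDIUM), labels.pixels(SLOW)], dtype=float
    )
    total = counts.sum()
    if total == 0:
        raise EmptyRegionError("label map contains no lesion pixels")
    fr = counts / total
    return float(fr[0]), float(fr[1]), float(fr[2])
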