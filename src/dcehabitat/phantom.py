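"""Synthetic DCE-MRI phantom cohorts with known habitat structure.

Each case is a single-slice dynamic series: a positive-baseline
pre-contrast image plus ``n_phases`` post-contrast images in which lesion
pixels follow a piecewise-linear enhancement curve peaking at a known
per-pixel time-to-peak. Habitat membership (rapid / medium / slow),
lesion mask and class label are returned as ground truth so every
downstream stage can be validated without patient data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import CohortError, DomainError, GeometryError
from .kinetics import DCESeries, MEDIUM, RAPID, SLOW

__all__ = [
    "ClassKinetics",
    "PhantomConfig",
    "PhantomGroundTruth",
    "kinetic_curve",
    "generate_case",
    "generate_cohort",
    "null_config",
    "strong_effect_config",
]


@dataclass(frozen=True)
class ClassKinetics:
    """Per-class sampling ranges for the enhancement curve parameters."""

    amplitude_range: tuple[float, float] = (60.0, 100.0)  # peak enhancement, percent
    washout_slope_range: tuple[float, float] = (3.0, 8.0)  # percent per phase


@dataclass(frozen=True)
class PhantomConfig:
    n_cases: int = 10
    class_balance: float = 0.5  # fraction of positive cases
    image_size: int = 128
    n_phases: int = 8
    lesion_radius_range: tuple[float, float] = (10.0, 14.0)
    habitat_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    kinetic_params_by_class: dict[int, ClassKinetics] = field(
        default_factory=lambda: {0: ClassKinetics(), 1: ClassKinetics()}
    )
    #: Shift of habitat fractions toward rapid for positive cases
    #: (kinetic effect channel); 0 disables it.
    habitat_shift: float = 0.0
    #: Multiplier (>= 0) for the spatial coefficient of variation of the
    #: amplitude field in positive cases (texture effect channel).
    texture_effect: float = 0.0
    #: Baseline spatial coefficient of variation of the amplitude field.
    amplitude_cv: float = 0.10
    noise_sd: float = 0.0
    baseline_range: tuple[float, float] = (90.0, 110.0)
    habitat_geometry: str = "concentric"  # or "blobs"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.habitat_fractions, dtype=float)
        if fr.size != 3 or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise DomainError("habitat_fractions must be >= 0 and sum to 1")
        if self.n_phases < 8:
            raise DomainError("n_phases >= 8 is required by the partition rule")
        if not 0.0 <= self.class_balance <= 1.0:
            raise DomainError("class_balance must lie in [0, 1]")
        if self.texture_effect < 0:
            raise DomainError("texture_effect must be >= 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.habitat_geometry not in ("concentric", "blobs"):
            raise DomainError("habitat_geometry must be 'concentric' or 'blobs'")


@dataclass
class PhantomGroundTruth:
    class_label: int  # 1 positive, 0 negative
    lesion_mask: np.ndarray  # (H, W) bool
    habitat_labels: np.ndarray  # (H, W) int: RAPID/MEDIUM/SLOW inside mask, 0 outside
    true_ttp: np.ndarray  # (H, W) int: 1..8 inside mask, 0 outside


def kinetic_curve(
    ttp_phase: int, amplitude: float, washout_slope: float, n_phases: int = 8
) -> np.ndarray:
    """Piecewise-linear enhancement curve peaking at ``ttp_phase``.

    Linear wash-in from 0 up to ``amplitude`` at ``ttp_phase``, then a
    linear wash-out of ``washout_slope`` per phase, floored at 0. The
    earliest argmax of the returned curve is ``ttp_phase`` and the value
    there equals ``amplitude``.
    """
    if not 1 <= ttp_phase <= n_phases:
        raise DomainError(f"ttp_phase {ttp_phase} outside 1..{n_phases}")
    if amplitude <= 0:
        raise DomainError("amplitude must be > 0")
    if washout_slope < 0:
        raise DomainError("washout_slope must be >= 0")
    t = np.arange(1, n_phases + 1, dtype=float)
    # (t / ttp) first so the peak value is exactly `amplitude`
    curve = np.where(
        t <= ttp_phase,
        amplitude * (t / ttp_phase),
        amplitude - washout_slope * (t - ttp_phase),
    )
    return np.maximum(curve, 0.0)


def _effective_fractions(config: PhantomConfig, class_label: int) -> np.ndarray:
    fr = np.asarray(config.habitat_fractions, dtype=float)
    if class_label == 1 and config.habitat_shift > 0:
        shift = min(config.habitat_shift, 1.0 - fr[0])
        rest = fr[1] + fr[2]
        if rest > 0:
            fr = np.array(
                [fr[0] + shift, fr[1] * (1 - shift / rest), fr[2] * (1 - shift / rest)]
            )
        fr = fr / fr.sum()
    return fr


def _habitat_order(
    config: PhantomConfig, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rank lesion pixels so contiguous prefixes form spatial habitats."""
    rows, cols = np.nonzero(mask)
    if config.habitat_geometry == "concentric":
        cr, cc = rows.mean(), cols.mean()
        key = (rows - cr) ** 2 + (cols - cc) ** 2
    else:  # smooth random field -> blob-wise habitats
        noise = rng.standard_normal(mask.shape)
        field_img = gaussian_filter(noise, sigma=3.0)
        key = field_img[rows, cols]
    return np.argsort(key, kind="stable")


def generate_case(
    config: PhantomConfig, class_label: int, case_seed: int
) -> tuple[DCESeries, PhantomGroundTruth]:
    """Simulate one case; bit-identical for identical arguments."""
    rng = np.random.default_rng(case_seed)
    n = config.image_size
    baseline = rng.uniform(*config.baseline_range, size=(n, n))

    radius = rng.uniform(*config.lesion_radius_range)
    center = n / 2.0
    if radius + 2 > n / 2.0:
        raise GeometryError(
            f"lesion radius {radius:.1f} does not fit a {n}x{n} image"
        )
    rr, cc = np.mgrid[0:n, 0:n]
    mask = (rr - center) ** 2 + (cc - center) ** 2 <= radius**2
    n_pix = int(mask.sum())

    order = _habitat_order(config, mask, rng)
    fr = _effective_fractions(config, class_label)
    n_rapid = int(round(fr[0] * n_pix))
    n_medium = int(round(fr[1] * n_pix))
    n_medium = min(n_medium, n_pix - n_rapid)

    habitat_flat = np.full(n_pix, SLOW, dtype=int)
    habitat_flat[order[:n_rapid]] = RAPID
    habitat_flat[order[n_rapid : n_rapid + n_medium]] = MEDIUM

    ttp_flat = np.empty(n_pix, dtype=int)
    ttp_flat[habitat_flat == RAPID] = rng.integers(
        1, 5, size=int((habitat_flat == RAPID).sum())
    )
    ttp_flat[habitat_flat == MEDIUM] = rng.integers(
        5, 7, size=int((habitat_flat == MEDIUM).sum())
    )
    ttp_flat[habitat_flat == SLOW] = rng.integers(
        7, 9, size=int((habitat_flat == SLOW).sum())
    )

    kin = config.kinetic_params_by_class[class_label]
    base_amplitude = rng.uniform(*kin.amplitude_range)
    washout = rng.uniform(*kin.washout_slope_range)
    cv = config.amplitude_cv * (
        1.0 + (config.texture_effect if class_label == 1 else 0.0)
    )
    amp_flat = base_amplitude * (1.0 + cv * rng.standard_normal(n_pix))
    amp_flat = np.maximum(amp_flat, 1.0)

    # Vectorized piecewise-linear curves for every lesion pixel.
    t = np.arange(1, config.n_phases + 1, dtype=float)[:, None]
    enh = np.where(
        t <= ttp_flat[None, :],
        amp_flat[None, :] * (t / ttp_flat[None, :]),
        amp_flat[None, :] - washout * (t - ttp_flat[None, :]),
    )
    enh = np.maximum(enh, 0.0)

    base_lesion = baseline[mask]
    post = np.repeat(baseline[None, :, :], config.n_phases, axis=0)
    post[:, mask] = base_lesion[None, :] * (1.0 + enh / 100.0)

    pre = baseline.copy()
    if config.noise_sd > 0:
        pre = pre + rng.normal(0.0, config.noise_sd, size=pre.shape)
        post = post + rng.normal(0.0, config.noise_sd, size=post.shape)

    habitat_labels = np.zeros((n, n), dtype=int)
    habitat_labels[mask] = habitat_flat
    true_ttp = np.zeros((n, n), dtype=int)
    true_ttp[mask] = ttp_flat

    series = DCESeries(pre_contrast=pre, post_contrast=post)
    truth = PhantomGroundTruth(
        class_label=int(class_label),
        lesion_mask=mask,
        habitat_labels=habitat_labels,
        true_ttp=true_ttp,
    )
    return series, truth


def case_seeds(config: PhantomConfig) -> list[int]:
    """Deterministic per-case seeds derived from the cohort seed."""
    state = np.random.SeedSequence(config.seed).generate_state(config.n_cases)
    return [int(s) for s in state]


def cohort_labels(config: PhantomConfig) -> list[int]:
    """Class labels for a cohort; positives first, count = round(n * balance)."""
    n_pos = int(round(config.n_cases * config.class_balance))
    if config.n_cases < 2 or n_pos == 0 or n_pos == config.n_cases:
        raise CohortError(
            f"degenerate cohort: {n_pos} positives of {config.n_cases} cases"
        )
    return [1] * n_pos + [0] * (config.n_cases - n_pos)


def generate_cohort(
    config: PhantomConfig,
) -> list[tuple[DCESeries, PhantomGroundTruth]]:
    """Simulate a full cohort, a pure function of the config."""
    labels = cohort_labels(config)
    seeds = case_seeds(config)
    return [
        generate_case(config, label, seed) for label, seed in zip(labels, seeds)
    ]


def null_config(
    n_cases: int = 10, image_size: int = 48, noise_sd: float = 2.0, seed: int = 0
) -> PhantomConfig:
    """Cohort with identical class distributions (no separating effect)."""
    kin = ClassKinetics(amplitude_range=(60.0, 100.0), washout_slope_range=(3.0, 8.0))
    return PhantomConfig(
        n_cases=n_cases,
        image_size=image_size,
        kinetic_params_by_class={0: kin, 1: kin},
        habitat_shift=0.0,
        texture_effect=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def strong_effect_config(
    n_cases: int = 10, image_size: int = 48, noise_sd: float = 2.0, seed: int = 0
) -> PhantomConfig:
    """Cohort with strong kinetic + texture class separation."""
    return PhantomConfig(
        n_cases=n_cases,
        image_size=image_size,
        kinetic_params_by_class={
            0: ClassKinetics(amplitude_range=(50.0, 75.0)),
            1: ClassKinetics(amplitude_range=(95.0, 130.0)),
        },
        habitat_shift=0.25,
        texture_effect=1.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def with_seed(config: PhantomConfig, seed: int) -> PhantomConfig:
    return replace(config, seed=seed)
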