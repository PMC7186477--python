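"""The 488-entry texture feature bank for masked image regions.

Four blocks, concatenated in fixed catalogue order:

* histogram moments (4): mean, population variance, skewness, excess
  kurtosis of raw in-mask intensities;
* GLCM (380): 19 co-occurrence statistics over 16 directed offset
  configurations (distances 1-4 x offsets (d,0), (0,d), (d,d), (-d,-d))
  plus 4 per-distance angular means;
* GRLM (44): 11 run-length statistics at 4 angles;
* DWT (60): 20 subband scalars per wavelet (haar, deubechies2, symlet4).

Features that cannot be computed for a region (too few pixels, degenerate
denominators, empty pair sets) are flagged as NaN rather than raised.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dwt import WAVELET_NAMES, dwt2
from .errors import DomainError, EmptyMatrixError, EmptyRegionError

DEFAULT_N_LEVELS = 64
DEFAULT_MIN_REGION_PIXELS = 10

HISTOGRAM_NAMES = ("mean", "variance", "skewness", "kurtosis")

GLCM_STATS = (
    "ACOR", "CON", "COR", "CP", "CS", "DIS", "ENE", "ENT", "HOM", "MP",
    "SOS", "SA", "SV", "SE", "DV", "DE", "IMC", "IDN", "IDMN",
)

GRLM_STATS = (
    "RLN", "GLN", "LRE", "SRE", "FIR",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)
GRLM_ANGLES = (0, 45, 90, 135)

DWT_SUBBANDS = ("HH", "HV", "HD", "L", "D")
DWT_LEVELS = (1, 2, 3, 4)


def glcm_offsets(distance: int) -> list[tuple[int, int]]:
    """The four directed (row, col) offsets at a given distance."""
    d = distance
    return [(d, 0), (0, d), (d, d), (-d, -d)]


def _build_catalogue() -> tuple[str, ...]:
    names: list[str] = list(HISTOGRAM_NAMES)
    for d in (1, 2, 3, 4):
        for a, b in glcm_offsets(d):
            names.extend(f"{s} ({a},{b})" for s in GLCM_STATS)
    for d in (1, 2, 3, 4):
        names.extend(f"{s} d{d} avg" for s in GLCM_STATS)
    for angle in GRLM_ANGLES:
        names.extend(f"{angle}°{s}" for s in GRLM_STATS)
    for wavelet in WAVELET_NAMES:
        for level in DWT_LEVELS:
            names.extend(f"{wavelet} {sb}_{level}" for sb in DWT_SUBBANDS)
    return tuple(names)


FEATURE_NAMES = _build_catalogue()
assert len(FEATURE_NAMES) == 488, len(FEATURE_NAMES)
assert len(set(FEATURE_NAMES)) == 488


@dataclass
class QuantizedRegion:
    """In-mask intensities mapped linearly onto integer levels 1..n_levels."""

    levels: np.ndarray  # (H, W) int, 0 outside the mask
    mask: np.ndarray  # (H, W) bool
    n_levels: int
    intensity_range: tuple[float, float]


def quantize(
    image: np.ndarray, mask: np.ndarray, n_levels: int = DEFAULT_N_LEVELS
) -> QuantizedRegion:
    """Linear min-max binning of in-mask intensities to 1..n_levels."""
    if n_levels < 2:
        raise DomainError("n_levels must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    vals = image[mask]
    if vals.size == 0:
        raise EmptyRegionError("cannot quantize an empty region")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=int)
    if hi == lo:
        levels[mask] = 1
    else:
        scaled = np.floor((image[mask] - lo) / (hi - lo) * n_levels).astype(int) + 1
        levels[mask] = np.clip(scaled, 1, n_levels)
    return QuantizedRegion(
        levels=levels, mask=mask, n_levels=n_levels, intensity_range=(lo, hi)
    )


# ---------------------------------------------------------------------------
# Histogram block
# ---------------------------------------------------------------------------


def histogram_features(
    image: np.ndarray,
    mask: np.ndarray,
    min_region_pixels: int = DEFAULT_MIN_REGION_PIXELS,
) -> dict[str, float]:
    """Mean, population variance, skewness, excess kurtosis of raw values."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    vals = image[mask]
    if vals.size < min_region_pixels:
        return dict.fromkeys(HISTOGRAM_NAMES, float("nan"))
    mean = float(vals.mean())
    centered = vals - mean
    var = float((centered**2).mean())
    if var == 0:
        skew = kurt = float("nan")
    else:
        skew = float((centered**3).mean() / var**1.5)
        kurt = float((centered**4).mean() / var**2 - 3.0)
    return {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt}


# ---------------------------------------------------------------------------
# GLCM block
# ---------------------------------------------------------------------------


def glcm(q: QuantizedRegion, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one (row, col) offset.

    Only pairs with both pixels inside the mask are counted; each pair is
    counted in both directions.
    """
    a, b = offset
    h, w = q.levels.shape
    if abs(a) >= h or abs(b) >= w:
        raise EmptyMatrixError(f"offset {offset} exceeds region extent")
    src_r = slice(0, h - a) if a >= 0 else slice(-a, h)
    dst_r = slice(a, h) if a >= 0 else slice(0, h + a)
    src_c = slice(0, w - b) if b >= 0 else slice(-b, w)
    dst_c = slice(b, w) if b >= 0 else slice(0, w + b)

    both = q.mask[src_r, src_c] & q.mask[dst_r, dst_c]
    i = q.levels[src_r, src_c][both]
    j = q.levels[dst_r, dst_c][both]
    if i.size == 0:
        raise EmptyMatrixError(f"no in-mask pixel pairs at offset {offset}")
    mat = np.zeros((q.n_levels, q.n_levels), dtype=float)
    np.add.at(mat, (i - 1, j - 1), 1.0)
    mat = mat + mat.T
    return mat / mat.sum()


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_features(matrix: np.ndarray) -> dict[str, float]:
    """The 19 co-occurrence statistics of a normalized GLCM.

    Haralick definitions with the Soh-Tsatsoulis/Clausi additions (IMC as
    IMC1, inverse difference (moment) normalized); natural logarithms,
    0 log 0 := 0; degenerate denominators give limit value 0.
    """
    p = np.asarray(matrix, dtype=float)
    n = p.shape[0]
    levels = np.arange(1, n + 1, dtype=float)
    i_grid, j_grid = np.meshgrid(levels, levels, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((levels * px).sum())
    mu_y = float((levels * py).sum())
    sd_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((levels - mu_y) ** 2 * py).sum()))

    acor = float((i_grid * j_grid * p).sum())
    contrast = float(((i_grid - j_grid) ** 2 * p).sum())
    correlation = 0.0 if sd_x * sd_y == 0 else (acor - mu_x * mu_y) / (sd_x * sd_y)

    # p_{x+y} over k = 2..2n and p_{x-y} over k = 0..n-1
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, (i_grid + j_grid).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(i_grid - j_grid).astype(int).ravel(), p.ravel())

    k_sum = np.arange(2 * n + 1, dtype=float)
    k_diff = np.arange(n, dtype=float)
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-_xlogx(p_sum).sum())
    diff_mean = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    diff_ent = float(-_xlogx(p_diff).sum())

    entropy = float(-_xlogx(p).sum())
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    pxpy = px[:, None] * py[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log(pxpy), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    imc = 0.0 if max(hx, hy) == 0 else (entropy - hxy1) / max(hx, hy)

    return {
        "ACOR": acor,
        "CON": contrast,
        "COR": correlation,
        "CP": float(((i_grid + j_grid - mu_x - mu_y) ** 4 * p).sum()),
        "CS": float(((i_grid + j_grid - mu_x - mu_y) ** 3 * p).sum()),
        "DIS": float((np.abs(i_grid - j_grid) * p).sum()),
        "ENE": float((p**2).sum()),
        "ENT": entropy,
        "HOM": float((p / (1.0 + (i_grid - j_grid) ** 2)).sum()),
        "MP": float(p.max()),
        "SOS": float(((i_grid - mu_x) ** 2 * p).sum()),
        "SA": sum_avg,
        "SV": sum_var,
        "SE": sum_ent,
        "DV": diff_var,
        "DE": diff_ent,
        "IMC": imc,
        "IDN": float((p / (1.0 + np.abs(i_grid - j_grid) / n)).sum()),
        "IDMN": float((p / (1.0 + (i_grid - j_grid) ** 2 / n**2)).sum()),
    }


def glcm_feature_block(q: QuantizedRegion) -> dict[str, float]:
    """380 named GLCM features: 16 directed configurations + 4 angular means.

    Offsets with no valid pixel pair produce NaN entries (propagated into
    the corresponding angular means) instead of raising.
    """
    out: dict[str, float] = {}
    per_distance: dict[int, list[dict[str, float]]] = {}
    for d in (1, 2, 3, 4):
        per_distance[d] = []
        for a, b in glcm_offsets(d):
            try:
                stats = glcm_features(glcm(q, (a, b)))
            except EmptyMatrixError:
                stats = dict.fromkeys(GLCM_STATS, float("nan"))
            per_distance[d].append(stats)
            for s in GLCM_STATS:
                out[f"{s} ({a},{b})"] = stats[s]
    for d in (1, 2, 3, 4):
        for s in GLCM_STATS:
            out[f"{s} d{d} avg"] = float(
                np.mean([stats[s] for stats in per_distance[d]])
            )
    return out


# ---------------------------------------------------------------------------
# GRLM block
# ---------------------------------------------------------------------------


def _grlm_lines(levels: np.ndarray, angle: int) -> list[np.ndarray]:
    """Scan lines of the level map along one digital direction.

    Out-of-mask pixels are level 0 and break runs.
    """
    h, w = levels.shape
    if angle == 0:
        return [levels[r, :] for r in range(h)]
    if angle == 90:
        return [levels[:, c] for c in range(w)]
    if angle == 45:
        flipped = levels[:, ::-1]
        return [np.diagonal(flipped, off) for off in range(-(h - 1), w)]
    if angle == 135:
        return [np.diagonal(levels, off) for off in range(-(h - 1), w)]
    raise DomainError(f"unsupported GRLM angle {angle}")


def grlm_matrix(q: QuantizedRegion, angle: int) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] of maximal in-mask runs."""
    rows, cols = np.nonzero(q.mask)
    if rows.size == 0:
        raise EmptyRegionError("cannot build a run-length matrix on an empty region")
    crop = q.levels[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    max_len = max(crop.shape)
    mat = np.zeros((q.n_levels, max_len), dtype=float)
    for line in _grlm_lines(crop, angle):
        current = 0
        length = 0
        for v in line:
            if v == current:
                length += 1
            else:
                if current > 0:
                    mat[current - 1, length - 1] += 1
                current = int(v)
                length = 1
        if current > 0:
            mat[current - 1, length - 1] += 1
    return mat


def _grlm_stats(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_runs = mat.sum()
    if n_runs == 0:
        return dict.fromkeys(GRLM_STATS, float("nan"))
    gl = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    rl = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    return {
        "RLN": float((mat.sum(axis=0) ** 2).sum() / n_runs),
        "GLN": float((mat.sum(axis=1) ** 2).sum() / n_runs),
        "LRE": float((mat * rl**2).sum() / n_runs),
        "SRE": float((mat / rl**2).sum() / n_runs),
        "FIR": float(n_runs / n_pixels),
        "LGRE": float((mat / gl**2).sum() / n_runs),
        "HGRE": float((mat * gl**2).sum() / n_runs),
        "SRLGE": float((mat / (gl**2 * rl**2)).sum() / n_runs),
        "SRHGE": float((mat * gl**2 / rl**2).sum() / n_runs),
        "LRLGE": float((mat * rl**2 / gl**2).sum() / n_runs),
        "LRHGE": float((mat * rl**2 * gl**2).sum() / n_runs),
    }


def grlm_features(q: QuantizedRegion) -> dict[str, float]:
    """44 named run-length features: 11 statistics at 4 angles."""
    n_pixels = int(q.mask.sum())
    out: dict[str, float] = {}
    for angle in GRLM_ANGLES:
        stats = _grlm_stats(grlm_matrix(q, angle), n_pixels)
        for s in GRLM_STATS:
            out[f"{angle}°{s}"] = stats[s]
    return out


# ---------------------------------------------------------------------------
# DWT block
# ---------------------------------------------------------------------------


def dwt_features(
    image: np.ndarray, mask: np.ndarray, wavelet: str
) -> dict[str, float]:
    """20 subband scalars for one wavelet over the masked bounding box.

    The mask-cropped region (zero outside the mask) is padded with zeros
    to a multiple of 16 and decomposed over 4 levels; per level the scalar
    is the mean absolute coefficient over positions whose support overlaps
    the block-downsampled mask, for HH/HV/HD/L, plus a pooled detail
    scalar D over the three detail subbands.
    """
    if wavelet not in WAVELET_NAMES:
        raise DomainError(f"unknown wavelet {wavelet!r}; choose from {WAVELET_NAMES}")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyRegionError("cannot decompose an empty region")
    crop = np.where(mask, image, 0.0)[
        rows.min() : rows.max() + 1, cols.min() : cols.max() + 1
    ]
    mcrop = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    pad_h = (-crop.shape[0]) % 16 if crop.shape[0] >= 16 else 16 - crop.shape[0]
    pad_w = (-crop.shape[1]) % 16 if crop.shape[1] >= 16 else 16 - crop.shape[1]
    a = np.pad(crop, ((0, pad_h), (0, pad_w)))
    m = np.pad(mcrop, ((0, pad_h), (0, pad_w)))

    out: dict[str, float] = {}
    for level in DWT_LEVELS:
        bands = dwt2(a, wavelet)
        m = m.reshape(m.shape[0] // 2, 2, m.shape[1] // 2, 2).any(axis=(1, 3))
        details = []
        for key in ("HH", "HV", "HD"):
            coeffs = np.abs(bands[key][m])
            details.append(coeffs)
            out[f"{wavelet} {key}_{level}"] = float(coeffs.mean())
        out[f"{wavelet} L_{level}"] = float(np.abs(bands["L"][m]).mean())
        out[f"{wavelet} D_{level}"] = float(np.concatenate(details).mean())
        a = bands["L"]
    return out


# ---------------------------------------------------------------------------
# Full catalogue
# ---------------------------------------------------------------------------


def extract_all(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    min_region_pixels: int = DEFAULT_MIN_REGION_PIXELS,
) -> dict[str, float]:
    """All 488 catalogue features for one masked region, in fixed order.

    Regions smaller than ``min_region_pixels`` yield a fully flagged
    (all-NaN) vector.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if int(mask.sum()) < min_region_pixels:
        return dict.fromkeys(FEATURE_NAMES, float("nan"))

    feats: dict[str, float] = {}
    feats.update(histogram_features(image, mask, min_region_pixels))
    q = quantize(image, mask, n_levels)
    feats.update(glcm_feature_block(q))
    feats.update(grlm_features(q))
    for wavelet in WAVELET_NAMES:
        feats.update(dwt_features(image, mask, wavelet))

    ordered = {name: float(feats[name]) for name in FEATURE_NAMES}
    assert len(ordered) == 488
    return ordered
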