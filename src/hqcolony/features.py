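"""Per-pixel feature maps for well-plate images.

Produces the descriptor stack used for colony/background classification:
raw RGB channels, CIE 1976 L*u*v* channels, the four GLCM (gray-level
co-occurrence matrix) Haralick descriptors — contrast, correlation, energy,
homogeneity — computed over a sliding odd-sided window, and the local
Shannon entropy map used to derive ground-truth masks.

The sliding-window maps are computed by vectorized pair enumeration: with a
w x w window and a single displacement there are only (w-|dr|)(w-|dc|)
co-occurring pixel pairs per window, so every descriptor is evaluated
directly from the per-window pair lists without materialising an LxL matrix
per pixel.  The single-window :func:`glcm` / :func:`haralick_descriptors`
pair implements the same definitions explicitly and is the reference the
maps are tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.color import rgb2luv

from .exceptions import InvalidParameterError

__all__ = [
    "GrayImage",
    "GLCM",
    "FeatureMapStack",
    "FEATURE_SETS",
    "rebin_gray",
    "luminance",
    "glcm",
    "haralick_descriptors",
    "sliding_feature_maps",
    "rgb_to_luv",
    "entropy_map",
    "feature_map_stack",
]

#: named feature sets: the two 3-channel colour encodings and the four
#: scalar texture descriptors compared in the colony/background experiment
FEATURE_SETS = {
    "rgb": ("R", "G", "B"),
    "luv": ("L*", "u*", "v*"),
    "contrast": ("contrast",),
    "correlation": ("correlation",),
    "energy": ("energy",),
    "homogeneity": ("homogeneity",),
}


@dataclass
class GrayImage:
    """A quantized 2-D image with values in {0, ..., L-1}."""

    values: np.ndarray
    L: int


@dataclass
class GLCM:
    """Gray-level co-occurrence matrix for one displacement.

    ``counts[i, j]`` is the number of pixel pairs ``(p, p + offset)`` with
    gray levels ``(i, j)``; accumulation is non-symmetric (the reverse pair
    is not added).  ``normalized`` divides by the total pair count.
    """

    counts: np.ndarray
    offset: tuple[int, int]
    normalized: np.ndarray = field(init=False)

    def __post_init__(self):
        total = self.counts.sum()
        self.normalized = (
            self.counts / total if total > 0 else np.zeros_like(self.counts, dtype=float)
        )


@dataclass
class FeatureMapStack:
    """All per-pixel descriptor maps aligned to the source image grid."""

    maps: dict[str, np.ndarray]
    window: int

    @property
    def shape(self):
        return next(iter(self.maps.values())).shape

    def select(self, feature_set: str) -> dict[str, np.ndarray]:
        """Subset of maps for a named feature set (see FEATURE_SETS)."""
        names = FEATURE_SETS[feature_set]
        return {name: self.maps[name] for name in names}


def rebin_gray(image, L: int = 256, value_range=None) -> GrayImage:
    """Histogram rebinning of an intensity image onto L gray levels.

    ``value_range`` fixes the (min, max) of the linear map; by default it is
    taken from the data, which makes the downstream co-occurrence
    descriptors invariant to adding a constant to every pixel.  A constant
    image maps to level 0.
    """
    if L < 2:
        raise InvalidParameterError(f"L must be >= 2, got {L}")
    image = np.asarray(image, dtype=float)
    lo, hi = value_range if value_range is not None else (image.min(), image.max())
    if hi <= lo:
        return GrayImage(np.zeros(image.shape, dtype=np.int64), L)
    binned = np.floor((image - lo) / (hi - lo) * L).astype(np.int64)
    return GrayImage(np.clip(binned, 0, L - 1), L)


def luminance(rgb) -> np.ndarray:
    """ITU-R 601 luma of an RGB image (the gray source for texture maps)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {rgb.shape}")
    return rgb @ np.array([0.299, 0.587, 0.114])


def glcm(window: GrayImage | np.ndarray, offset=(0, 1), L: int | None = None) -> GLCM:
    """Co-occurrence matrix of one window for a single displacement."""
    if isinstance(window, GrayImage):
        values, L = window.values, window.L
    else:
        values = np.asarray(window)
        if L is None:
            L = int(values.max()) + 1 if values.size else 2
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise InvalidParameterError("GLCM offset must be nonzero")
    if values.size == 0:
        raise InvalidParameterError("GLCM window must be non-empty")
    h, w = values.shape
    counts = np.zeros((L, L), dtype=np.int64)
    r0, c0 = max(0, -dr), max(0, -dc)
    he, we = h - abs(dr), w - abs(dc)
    if he > 0 and we > 0:
        i = values[r0 : r0 + he, c0 : c0 + we].ravel()
        j = values[r0 + dr : r0 + dr + he, c0 + dc : c0 + dc + we].ravel()
        np.add.at(counts, (i, j), 1)
    return GLCM(counts=counts, offset=(dr, dc))


def haralick_descriptors(g: GLCM) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM.

    contrast    = sum (i-j)^2 p(i,j)
    correlation = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
    energy      = sum p(i,j)^2
    homogeneity = sum p(i,j) / (1 + |i-j|)

    A window with zero marginal variance has undefined correlation; 0 is
    substituted (with a warning) so downstream standardization never sees
    NaNs.
    """
    p = g.normalized
    L = p.shape[0]
    i, j = np.indices((L, L))
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i <= 0 or var_j <= 0:
        warnings.warn("zero marginal variance: correlation undefined, substituting 0")
        correlation = 0.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p)) / np.sqrt(var_i * var_j)
    return contrast, correlation, energy, homogeneity


def _pair_windows(values: np.ndarray, window: int, offset: tuple[int, int]):
    """Per-pixel lists of co-occurring gray-level pairs.

    Returns (I, J) of shape (H, W, n_pairs): for each output pixel, the gray
    levels of every ordered pair (p, p+offset) with both pixels inside the
    replicate-padded window centred on it.
    """
    dr, dc = offset
    h = window // 2
    padded = np.pad(values, h, mode="edge")
    r0, c0 = max(0, -dr), max(0, -dc)
    hp, wp = padded.shape
    he, we = hp - abs(dr), wp - abs(dc)
    I = padded[r0 : r0 + he, c0 : c0 + we]
    J = padded[r0 + dr : r0 + dr + he, c0 + dc : c0 + dc + we]
    bh, bw = window - abs(dr), window - abs(dc)
    if bh < 1 or bw < 1:
        raise InvalidParameterError(
            f"offset {offset} reaches beyond the {window}x{window} window"
        )
    vi = sliding_window_view(I, (bh, bw)).reshape(values.shape[0], values.shape[1], -1)
    vj = sliding_window_view(J, (bh, bw)).reshape(values.shape[0], values.shape[1], -1)
    return vi.astype(np.int64), vj.astype(np.int64)


def sliding_feature_maps(
    gray: GrayImage, window: int = 5, offset=(0, 1)
) -> dict[str, np.ndarray]:
    """Contrast, correlation, energy and homogeneity maps over a sliding
    window, replicate-padded so every map has the source image shape."""
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(f"window must be odd and >= 3, got {window}")
    vi, vj = _pair_windows(gray.values, window, tuple(offset))
    n = vi.shape[-1]
    diff = vi - vj
    contrast = np.mean(diff.astype(float) ** 2, axis=-1)
    homogeneity = np.mean(1.0 / (1.0 + np.abs(diff)), axis=-1)

    fi, fj = vi.astype(float), vj.astype(float)
    mu_i = fi.mean(axis=-1)
    mu_j = fj.mean(axis=-1)
    var_i = (fi**2).mean(axis=-1) - mu_i**2
    var_j = (fj**2).mean(axis=-1) - mu_j**2
    cov = (fi * fj).mean(axis=-1) - mu_i * mu_j
    denom = np.sqrt(np.clip(var_i, 0, None) * np.clip(var_j, 0, None))
    flat = denom <= 1e-12
    if np.any(flat):
        warnings.warn(
            "windows with zero marginal variance: correlation undefined there, substituting 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(flat, 0.0, cov / np.where(flat, 1.0, denom))

    # energy = sum_cells (count/n)^2 = (#ordered pair-code coincidences)/n^2,
    # computed row-block-wise to bound the (H, W, n, n) comparison tensor
    codes = vi * np.int64(gray.L) + vj
    energy = np.empty(contrast.shape)
    chunk = max(1, int(4e7 // (codes.shape[1] * n * n)))
    for start in range(0, codes.shape[0], chunk):
        c = codes[start : start + chunk]
        eq = c[..., :, None] == c[..., None, :]
        energy[start : start + chunk] = eq.sum(axis=(-1, -2)) / (n * n)

    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def rgb_to_luv(rgb) -> np.ndarray:
    """CIE 1976 L*u*v* (D65 white point, sRGB transfer) of a 24-bit RGB
    image; returns an (H, W, 3) float array with L* in [0, 100]."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {rgb.shape}")
    if rgb.dtype != np.uint8:
        rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    return rgb2luv(rgb)


def entropy_map(gray: GrayImage, window: int = 5) -> np.ndarray:
    """Shannon entropy (bits) of the gray-level histogram in each
    replicate-padded window; ranges over [0, log2 L]."""
    if window % 2 == 0 or window < 1:
        raise InvalidParameterError(f"window must be odd, got {window}")
    values = gray.values
    h = window // 2
    padded = np.pad(values, h, mode="edge")
    wins = sliding_window_view(padded, (window, window)).reshape(
        values.shape[0] * values.shape[1], -1
    )
    n = wins.shape[-1]
    # run-length histogram per window via a single sort
    s = np.sort(wins, axis=-1)
    new_run = np.ones_like(s, dtype=bool)
    new_run[:, 1:] = s[:, 1:] != s[:, :-1]
    # position-indexed run ids -> counts per element, then entropy as a sum
    # of -p log2 p over run starts only
    run_id = np.cumsum(new_run, axis=-1) - 1
    counts = np.zeros_like(s)
    np.add.at(counts, (np.arange(s.shape[0])[:, None], run_id), 1)
    p = counts[np.arange(s.shape[0])[:, None], run_id] / n
    term = np.where(new_run, -(counts[np.arange(s.shape[0])[:, None], run_id] / n) * np.log2(p), 0.0)
    return term.sum(axis=-1).reshape(values.shape)


def feature_map_stack(
    rgb_image, window: int = 5, L: int = 256, offset=(0, 1)
) -> FeatureMapStack:
    """Full descriptor stack for one well image.

    Texture and entropy maps are computed on the ITU-R 601 luminance,
    rebinned to L levels over the data range.
    """
    rgb_image = np.asarray(rgb_image)
    gray = rebin_gray(luminance(rgb_image), L=L)
    texture = sliding_feature_maps(gray, window=window, offset=offset)
    luv = rgb_to_luv(rgb_image)
    maps = {
        "R": rgb_image[..., 0].astype(float),
        "G": rgb_image[..., 1].astype(float),
        "B": rgb_image[..., 2].astype(float),
        "L*": luv[..., 0],
        "u*": luv[..., 1],
        "v*": luv[..., 2],
        **texture,
        "entropy": entropy_map(gray, window=window),
    }
    return FeatureMapStack(maps=maps, window=window)
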