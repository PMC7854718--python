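"""Synthetic well-plate images with paired ground-truth masks.

Emulates crystal-violet-stained 6-well-plate crops: a pale textured plate
background inside a circular well, violet colonies rendered as
radial-falloff blobs whose edge sharpness is set by a *compactness*
parameter and whose stain depth by a *contrast* parameter, plus
multiplicative speckle.  Four named regimes span the difficulty range seen
across cell lines, from compact high-contrast colonies down to diffuse,
faint ("evanescent") ones that take up little stain.

Geometry (colony placement, radii) and noise (texture, speckle) are driven
by two independent random sub-streams spawned from the master seed, so the
ground-truth mask — thresholded on the noise-free colony signal — depends
only on the geometry stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = [
    "WellSpec",
    "REGIMES",
    "generate_well",
    "generate_cell_line_suite",
    "pixel_separability",
]


@dataclass
class WellSpec:
    """Parameters of one synthetic well crop.

    compactness in (0, 1]: 1 gives a hard-edged disc, lower values a
    diffuse blob with heavy speckle.  contrast in (0, 1]: peak stain
    fraction blended over the background.
    """

    side: int = 301
    n_colonies: int = 10
    radius_mean: float = 10.0
    radius_sd: float = 2.0
    contrast: float = 0.9
    compactness: float = 0.9
    background_sd: float = 1.5
    stain_rgb: tuple[int, int, int] = (96, 64, 128)
    background_rgb: tuple[int, int, int] = (226, 221, 230)
    seed: int = 0

    def __post_init__(self):
        if self.side < 64:
            raise ValueError(f"side must be >= 64, got {self.side}")
        if not 0 < self.contrast <= 1:
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if not 0 < self.compactness <= 1:
            raise ValueError(f"compactness must be in (0, 1], got {self.compactness}")


def _place_colonies(spec: WellSpec, rng: np.random.Generator):
    """Colony centres and radii, fully inside the well disc; falls back to
    overlapping placement after bounded retries (real colonies merge too)."""
    centre = (spec.side - 1) / 2.0
    well_radius = 0.48 * spec.side
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_colonies):
        ok = False
        for _attempt in range(200):
            r = float(np.clip(rng.normal(spec.radius_mean, spec.radius_sd), 2.0, well_radius / 2))
            max_offset = well_radius - r
            ang = rng.uniform(0, 2 * np.pi)
            rad = max_offset * np.sqrt(rng.uniform())
            cy = centre + rad * np.sin(ang)
            cx = centre + rad * np.cos(ang)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr) ** 2 for py, px, pr in placed):
                placed.append((cy, cx, r))
                ok = True
                break
        if not ok:
            warnings.warn("could not place colony without overlap; allowing overlap")
            placed.append((cy, cx, r))
    return placed, centre, well_radius


def _colony_field(spec: WellSpec, placed, shape) -> np.ndarray:
    """Noise-free colony signal in [0, 1]: per colony a smoothstep radial
    falloff whose edge width scales with 1 - compactness."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    field = np.zeros(shape)
    edge_frac = 1.05 - spec.compactness  # in (0.05, 1.05)
    for cy, cx, r in placed:
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        u = np.clip((r - dist) / (r * edge_frac), 0.0, 1.0)
        signal = u * u * (3.0 - 2.0 * u)
        np.maximum(field, signal, out=field)
    return field


def generate_well(spec: WellSpec, noise_seed: int | None = None):
    """Render one well: returns ``(image, mask)`` — an (side, side, 3)
    uint8 RGB image and a uint8 mask (1 = colony).

    The mask thresholds the noise-free signal at half its peak, so it is a
    function of the geometry stream only; pass ``noise_seed`` to re-render
    the same geometry with different texture/speckle.
    """
    geom_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(2)
    geom_rng = np.random.default_rng(geom_ss)
    noise_rng = np.random.default_rng(noise_ss if noise_seed is None else noise_seed)

    shape = (spec.side, spec.side)
    placed, centre, well_radius = _place_colonies(spec, geom_rng)
    field = _colony_field(spec, placed, shape)
    mask = (field > 0.5).astype(np.uint8)

    # colonies are granular (densely packed stained cells): multiplicative
    # speckle with a floor, growing as compactness drops toward the diffuse
    # regime; the plate background carries only faint scanner noise
    speckle_sd = 0.12 + 0.30 * (1.0 - spec.compactness)
    stain = field * spec.contrast
    stain = stain * np.clip(1.0 + noise_rng.normal(0.0, speckle_sd, shape), 0.0, None)
    stain = np.clip(stain, 0.0, 1.0)

    bg = np.array(spec.background_rgb, dtype=float)
    fg = np.array(spec.stain_rgb, dtype=float)
    image = bg[None, None, :] * (1.0 - stain[..., None]) + fg[None, None, :] * stain[..., None]
    image += noise_rng.normal(0.0, spec.background_sd, (*shape, 3))
    return np.clip(image, 0, 255).astype(np.uint8), mask


#: per-regime parameter distributions (uniform/integer ranges drawn per well)
REGIMES = {
    "compact": dict(
        n_colonies=(8, 14), radius=(16.0, 3.0), contrast=(0.75, 0.95), compactness=(0.85, 0.95)
    ),
    "evanescent": dict(
        n_colonies=(6, 12), radius=(18.0, 5.0), contrast=(0.12, 0.28), compactness=(0.20, 0.40)
    ),
    "large-merging": dict(
        n_colonies=(5, 9), radius=(26.0, 6.0), contrast=(0.55, 0.80), compactness=(0.65, 0.80)
    ),
    "small-sparse": dict(
        n_colonies=(10, 16), radius=(10.0, 2.0), contrast=(0.60, 0.85), compactness=(0.80, 0.90)
    ),
}


def generate_cell_line_suite(regime: str, n_wells: int = 30, seed: int = 0, side: int = 301):
    """List of ``(image, mask, spec)`` for one cell-line-like regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {sorted(REGIMES)}")
    if n_wells < 1:
        raise ValueError(f"n_wells must be >= 1, got {n_wells}")
    params = REGIMES[regime]
    master = np.random.SeedSequence(seed)
    wells = []
    for child in master.spawn(n_wells):
        rng = np.random.default_rng(child)
        spec = WellSpec(
            side=side,
            n_colonies=int(rng.integers(params["n_colonies"][0], params["n_colonies"][1] + 1)),
            radius_mean=params["radius"][0],
            radius_sd=params["radius"][1],
            contrast=float(rng.uniform(*params["contrast"])),
            compactness=float(rng.uniform(*params["compactness"])),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, mask = generate_well(spec)
        wells.append((image, mask, spec))
    return wells


def pixel_separability(image, mask, seed: int = 0, n_pixels: int = 600) -> float:
    """Accuracy of a fixed simple probe (logistic regression on RGB values
    of a random pixel sample) — a scalar proxy for how linearly separable
    colony and background pixels are in one well."""
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask).ravel()
    rgb = np.asarray(image, dtype=float).reshape(-1, 3)
    if mask.sum() == 0 or mask.sum() == mask.size:
        return 0.5
    idx = rng.choice(mask.size, size=min(n_pixels, mask.size), replace=False)
    X, y = rgb[idx], mask[idx]
    if len(np.unique(y)) < 2:
        return 0.5
    half = len(idx) // 2
    train, test = slice(0, half), slice(half, None)
    if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
        return 0.5
    clf = LogisticRegression(max_iter=200).fit(X[train], y[train])
    return float(np.mean(clf.predict(X[test]) == y[test]))


def well_spec_to_dict(spec: WellSpec) -> dict:
    return asdict(spec)
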