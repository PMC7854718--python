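"""Pixel-table datasets and the pre-processing chain.

A well image plus its binary mask becomes a *pixel table*: one row per
pixel with columns ``x, y, <features...>, label`` (x = column index, y =
row index, both 0-based, rows enumerated in row-major order; label 1 =
colony).  Before classification the table goes through: per-feature affine
normalization to [1, 255], uniform random sampling of a small fraction of
the rows (0.2% of a 301x301 well = 181 pixels), z-score standardization
(population standard deviation), and a label-stratified 80/20
development/test split.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "PixelTable",
    "serialize",
    "mask_from_table",
    "normalize_range",
    "sample",
    "standardize",
    "split",
    "round_half_away",
    "write_pixel_table",
    "read_pixel_table",
]


def round_half_away(value: float) -> int:
    """Round half away from zero (0.002 * 90601 = 181.202 -> 181;
    144.5 -> 145), the convention used for sample and split sizes."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


@dataclass
class PixelTable:
    """One row per pixel: coordinates, feature values, binary label."""

    data: pd.DataFrame
    feature_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.feature_names = tuple(self.feature_names)
        expected = ["x", "y", *self.feature_names, "label"]
        if list(self.data.columns) != expected:
            raise ValueError(f"columns must be {expected}, got {list(self.data.columns)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    def _with(self, data: pd.DataFrame, **prov) -> "PixelTable":
        return PixelTable(data, self.feature_names, {**self.provenance, **prov})


def serialize(maps, mask, provenance: dict | None = None) -> PixelTable:
    """Flatten per-pixel feature maps + mask into a pixel table.

    ``maps`` is an ordered mapping of feature name to 2-D array; all maps
    and the mask must share one shape.  Column order is exactly
    ``x, y, <features...>, label``.
    """
    mask = np.asarray(mask)
    names = list(maps)
    arrays = {name: np.asarray(maps[name]) for name in names}
    for name, arr in arrays.items():
        if arr.shape != mask.shape:
            raise ValueError(f"map {name!r} shape {arr.shape} != mask shape {mask.shape}")
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    data = {"x": xx.ravel(), "y": yy.ravel()}
    for name in names:
        data[name] = arrays[name].ravel().astype(float)
    data["label"] = mask.ravel().astype(int)
    return PixelTable(pd.DataFrame(data), tuple(names), dict(provenance or {}))


def mask_from_table(table: PixelTable, shape=None) -> np.ndarray:
    """Rebuild the binary mask from a (full, unsampled) pixel table."""
    x = table.data["x"].to_numpy()
    y = table.data["y"].to_numpy()
    if shape is None:
        shape = (int(y.max()) + 1, int(x.max()) + 1)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[y, x] = table.data["label"].to_numpy()
    return mask


def normalize_range(table: PixelTable, lo: float = 1.0, hi: float = 255.0) -> PixelTable:
    """Affine per-feature normalization mapping min -> lo and max -> hi.

    A constant feature carries no range information and collapses to lo
    (with a warning)."""
    if len(table) < 1:
        raise InvalidParameterError("normalize_range requires at least one row")
    data = table.data.copy()
    for name in table.feature_names:
        col = data[name].to_numpy(dtype=float)
        vmin, vmax = col.min(), col.max()
        if vmax <= vmin:
            warnings.warn(f"feature {name!r} is constant; normalized to {lo}")
            data[name] = lo
        else:
            data[name] = lo + (col - vmin) * (hi - lo) / (vmax - vmin)
    return table._with(data, normalized_range=[lo, hi])


def sample(table: PixelTable, fraction: float = 0.002, seed: int = 0) -> PixelTable:
    """Uniform sampling without replacement of round(fraction * n) rows."""
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    n = round_half_away(fraction * len(table))
    if n == 0:
        raise InvalidParameterError(
            f"fraction {fraction} of {len(table)} rows rounds to zero rows"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(table), size=n, replace=False))
    return table._with(
        table.data.iloc[idx].reset_index(drop=True), sample_fraction=fraction, sample_seed=seed
    )


def standardize(table: PixelTable, stats: dict | None = None):
    """Z-score standardization per feature (population standard deviation).

    Returns ``(table, stats)``; pass ``stats`` back in to re-apply captured
    means/sds to another table.  A constant feature becomes all zeros (with
    a warning).
    """
    if len(table) < 2 and stats is None:
        raise InvalidParameterError("standardize requires at least two rows")
    data = table.data.copy()
    if stats is None:
        stats = {}
        for name in table.feature_names:
            col = data[name].to_numpy(dtype=float)
            stats[name] = {"mean": float(col.mean()), "sd": float(col.std())}
    for name in table.feature_names:
        col = data[name].to_numpy(dtype=float)
        mean, sd = stats[name]["mean"], stats[name]["sd"]
        if sd <= 0:
            warnings.warn(f"feature {name!r} has zero variance; standardized to 0")
            data[name] = 0.0
        else:
            data[name] = (col - mean) / sd
    return table._with(data, standardized=True), stats


def split(table: PixelTable, dev_fraction: float = 0.8, seed: int = 0):
    """Label-stratified split into (development, test).

    The development size is round-half-away(dev_fraction * n) overall
    (181 rows at 0.8 -> 145 + 36); per-class counts follow the largest
    remainder so proportions hold to within one row.
    """
    if not 0 < dev_fraction < 1:
        raise InvalidParameterError(f"dev_fraction must be in (0, 1), got {dev_fraction}")
    n = len(table)
    n_dev = round_half_away(dev_fraction * n)
    if n_dev == 0 or n_dev == n:
        raise InvalidParameterError(
            f"dev_fraction {dev_fraction} leaves an empty split side for {n} rows"
        )
    labels = table.y
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    ideal = n_dev * counts / n
    base = np.floor(ideal).astype(int)
    remainder = n_dev - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:remainder]] += 1
    dev_idx = []
    for cls, take in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        dev_idx.append(members[:take])
    dev_mask = np.zeros(n, dtype=bool)
    dev_mask[np.concatenate(dev_idx)] = True
    dev = table._with(
        table.data[dev_mask].reset_index(drop=True), split="development", split_seed=seed
    )
    test = table._with(table.data[~dev_mask].reset_index(drop=True), split="test", split_seed=seed)
    return dev, test


def write_pixel_table(table: PixelTable, path) -> None:
    """CSV with header ``x,y,<features...>,label`` plus a sidecar
    ``<path>.json`` recording feature names and provenance."""
    table.data.to_csv(path, index=False)
    sidecar = {"feature_names": list(table.feature_names), "provenance": table.provenance}
    with open(f"{path}.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_pixel_table(path) -> PixelTable:
    data = pd.read_csv(path)
    try:
        with open(f"{path}.json", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        names = tuple(sidecar["feature_names"])
        provenance = sidecar.get("provenance", {})
    except FileNotFoundError:
        names = tuple(c for c in data.columns if c not in ("x", "y", "label"))
        provenance = {}
    return PixelTable(data, names, provenance)
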