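"""Ground-truth colony masks from entropy maps.

The reference segmentation is produced without any classifier: the local
entropy map of the well is clustered into two fuzzy classes by spatial
Fuzzy C-Means (sFCM), the higher-entropy cluster is labelled colony, and
the binary mask is cleaned by morphological opening plus removal of small
connected components (a pixel-area proxy for the >= 50-densely-packed-cells
rule used when scoring colonies by hand).

The sFCM variant used here regularises each membership by the sum of the
memberships in its spatial neighbourhood:

    u'_ij = u_ij^p h_ij^q / sum_k u_kj^p h_kj^q

with h the neighbourhood sum of u.  With q = 0 (or p = 1 and a 1x1
neighbourhood together with q = 0) it reduces to plain FCM.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.morphology import disk, opening, remove_small_objects

from .exceptions import InvalidParameterError

__all__ = ["sfcm_segment", "postprocess_mask", "ground_truth_mask"]


def sfcm_segment(
    feature_map,
    c: int = 2,
    fuzzifier: float = 2.0,
    spatial_window: int = 5,
    p: float = 1.0,
    q: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int | None = None,
    return_membership: bool = False,
):
    """Two-cluster spatial fuzzy c-means segmentation of a scalar map.

    Parameters
    ----------
    feature_map : 2-D array
        Per-pixel scalar feature (the entropy map in the assay pipeline).
    c : int
        Number of clusters; the colony/background split uses 2.
    fuzzifier : float
        FCM exponent (> 1); 2 is the conventional choice.
    spatial_window : int
        Odd side of the neighbourhood over which memberships are summed.
    p, q : float
        Exponents of the membership and of the spatial function in the
        correction; q = 0 disables the spatial term.
    seed : int or None
        Unused by the default percentile initialisation but kept so that a
        randomised initialisation stays reproducible behind one argument.

    Returns
    -------
    mask : 2-D uint8 array
        1 where the pixel belongs to the cluster with the highest centroid
        (highest entropy = colony), 0 elsewhere.  With
        ``return_membership=True``, also the (c, H, W) membership array.
    """
    x = np.asarray(feature_map, dtype=float)
    if x.ndim != 2:
        raise InvalidParameterError(f"feature_map must be 2-D, got shape {x.shape}")
    if fuzzifier <= 1:
        raise InvalidParameterError(f"fuzzifier must be > 1, got {fuzzifier}")
    if spatial_window % 2 == 0 or spatial_window < 1:
        raise InvalidParameterError(f"spatial_window must be odd, got {spatial_window}")

    flat = x.ravel()
    # deterministic spread initialisation: centroids at spaced percentiles
    qs = np.linspace(25, 75, c)
    centroids = np.percentile(flat, qs).astype(float)
    if np.ptp(centroids) == 0:
        centroids = centroids + np.arange(c, dtype=float)

    expo = 2.0 / (fuzzifier - 1.0)

    def memberships(cents):
        d2 = (flat[None, :] - cents[:, None]) ** 2 + 1e-12
        inv = d2 ** (-expo / 2.0)
        u = inv / inv.sum(axis=0, keepdims=True)
        if q != 0.0:
            h = uniform_filter(
                u.reshape(c, *x.shape), size=(1, spatial_window, spatial_window), mode="nearest"
            ).reshape(c, -1) * (spatial_window**2)
            num = np.clip(u, 1e-300, None) ** p * np.clip(h, 1e-300, None) ** q
        else:
            num = np.clip(u, 1e-300, None) ** p
        return num / num.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        u_spatial = memberships(centroids)
        um = u_spatial**fuzzifier
        new_centroids = um @ flat / um.sum(axis=1)
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    u_spatial = memberships(centroids)
    if not converged:
        warnings.warn(
            f"sFCM did not converge within {max_iter} iterations; returning best-so-far"
        )

    labels = u_spatial.argmax(axis=0)
    colony_cluster = int(np.argmax(centroids))
    mask = (labels == colony_cluster).astype(np.uint8).reshape(x.shape)
    if return_membership:
        return mask, u_spatial.reshape(c, *x.shape)
    return mask


def postprocess_mask(mask, min_area: int = 50, opening_radius: int = 1) -> np.ndarray:
    """Morphological opening followed by 8-connected small-component
    removal; never adds foreground.  ``opening_radius=0`` skips the
    opening."""
    mask = np.asarray(mask).astype(bool)
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    if min_area > 0:
        # keep components of area >= min_area (remove strictly smaller)
        mask = remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    return mask.astype(np.uint8)


def ground_truth_mask(
    entropy, min_area: int = 50, opening_radius: int = 1, **sfcm_kwargs
) -> np.ndarray:
    """Entropy map -> sFCM segmentation -> cleaned binary colony mask."""
    return postprocess_mask(
        sfcm_segment(entropy, **sfcm_kwargs), min_area=min_area, opening_radius=opening_radius
    )
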