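"""Tumor-margin delineation from pigment maps, and its evaluation.

The tumor margin is defined by eumelanin/pheomelanin dominance: the
eumelanin fraction F = eu/(eu+ph+ε) is smoothed, thresholded at 0.5
(eumelanin-dominated ⇔ tumor), cleaned of speckle, and its border traced.
Against a ground-truth mask the result is scored with the Dice overlap and
boundary distances (mean nearest-neighbour and Hausdorff, in µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes, gaussian_filter
from scipy.spatial import cKDTree
from skimage.morphology import remove_small_objects

from .unmixing import PigmentMaps

__all__ = [
    "DelineationConfig",
    "MarginResult",
    "eumelanin_fraction",
    "segment_tumor",
    "evaluate",
    "delineate",
]


@dataclass(frozen=True)
class DelineationConfig:
    """Smoothing / thresholding / cleanup parameters of the margin finder.

    Defaults: 2 µm smoothing (≈5 px at the default 0.41 µm pixel) suppresses
    pixel noise without erasing 10 µm cells; 20 µm² minimum object area
    (about a quarter cell) removes speckle while keeping single-cell
    detections.
    """

    fraction_epsilon: float = 1e-6
    smooth_sigma_um: float = 2.0
    fraction_threshold: float = 0.5
    min_object_area_um2: float = 20.0
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if not self.fraction_epsilon > 0:
            raise ValueError("fraction_epsilon must be positive")
        if not 0 < self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must lie in (0, 1)")
        if self.smooth_sigma_um < 0 or self.min_object_area_um2 < 0:
            raise ValueError("smoothing scale and minimum area must be >= 0")


@dataclass(frozen=True)
class MarginResult:
    """Tumor mask, its boundary pixels, and (optionally) scores vs truth."""

    tumor_mask: np.ndarray
    boundary: np.ndarray  # (n, 2) array of (row, col) border pixel coordinates
    dice: float | None = None
    mean_boundary_distance_um: float | None = None
    hausdorff_distance_um: float | None = None


def eumelanin_fraction(maps: PigmentMaps, epsilon: float = 1e-6) -> np.ndarray:
    """Per-pixel eumelanin dominance F = eu/(eu+ph+ε), in [0, 1)."""
    eu, ph = maps.eumelanin, maps.pheomelanin
    if np.any(eu < 0) or np.any(ph < 0):
        raise ValueError("pigment maps must be nonnegative")
    return eu / (eu + ph + epsilon)


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    """8-connected border: mask pixels with a non-mask pixel among 8 neighbours."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    interior = binary_erosion(mask, structure=np.ones((3, 3), dtype=bool), border_value=0)
    return np.argwhere(mask & ~interior)


def segment_tumor(
    fraction: np.ndarray,
    config: DelineationConfig | None = None,
    pixel_size_um: float = 1.0,
) -> MarginResult:
    """Smooth → threshold → clean the eumelanin-fraction map into a tumor mask."""
    config = config if config is not None else DelineationConfig()
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    sigma_px = config.smooth_sigma_um / pixel_size_um
    smoothed = gaussian_filter(fraction, sigma_px, mode="reflect") if sigma_px > 0 else fraction
    mask = smoothed > config.fraction_threshold
    min_px = int(np.ceil(config.min_object_area_um2 / pixel_size_um**2))
    if min_px > 1:
        # drop components with fewer than min_px pixels (max_size is inclusive)
        mask = remove_small_objects(mask, max_size=min_px - 1)
    if config.fill_holes:
        mask = binary_fill_holes(mask)
    return MarginResult(tumor_mask=mask, boundary=_border_pixels(mask))


def evaluate(
    mask: np.ndarray, truth: np.ndarray, pixel_size_um: float = 1.0
) -> tuple[float, float, float]:
    """Score a mask against ground truth.

    Returns (dice, mean_boundary_distance_um, hausdorff_distance_um).
    Dice = 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty and 0
    when exactly one is.  Boundary distances are computed between the two
    border-pixel sets (symmetrised: mean of the two directed means; max of
    the two directed maxima for Hausdorff) and scaled to µm; they are inf
    when exactly one boundary is empty, 0 when both are.
    """
    if mask.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {mask.shape} vs {truth.shape}")
    mask = mask.astype(bool)
    truth = truth.astype(bool)
    a, b = int(mask.sum()), int(truth.sum())
    if a == 0 and b == 0:
        return 1.0, 0.0, 0.0
    dice = 2.0 * int((mask & truth).sum()) / (a + b)

    bm = _border_pixels(mask)
    bt = _border_pixels(truth)
    if bm.size == 0 or bt.size == 0:
        return dice, np.inf, np.inf
    d_m_to_t, _ = cKDTree(bt).query(bm)
    d_t_to_m, _ = cKDTree(bm).query(bt)
    mean_dist = 0.5 * (d_m_to_t.mean() + d_t_to_m.mean()) * pixel_size_um
    hausdorff = max(d_m_to_t.max(), d_t_to_m.max()) * pixel_size_um
    return float(dice), float(mean_dist), float(hausdorff)


def delineate(
    maps: PigmentMaps,
    pixel_size_um: float,
    config: DelineationConfig | None = None,
    truth: np.ndarray | None = None,
) -> MarginResult:
    """Convenience chain: fraction → segment → (evaluate vs truth)."""
    config = config if config is not None else DelineationConfig()
    fraction = eumelanin_fraction(maps, config.fraction_epsilon)
    result = segment_tumor(fraction, config, pixel_size_um)
    if truth is None:
        return result
    dice, mean_dist, hausdorff = evaluate(result.tumor_mask, truth, pixel_size_um)
    return MarginResult(
        tumor_mask=result.tumor_mask,
        boundary=result.boundary,
        dice=dice,
        mean_boundary_distance_um=mean_dist,
        hausdorff_distance_um=hausdorff,
    )
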