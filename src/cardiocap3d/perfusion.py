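"""Perfusion, vascular integrity, hypoxia, diffusion-distance and PAS metrics.

These are the volumetric readouts paired with the structural analysis:

* perfusion percentage — how much of the ICAM2+ vasculature is occupied by
  intravenously injected IB4 (bounded form intersects the two masks; the
  raw form divides the plain areas and can exceed 100%);
* extravascular dextran — tracer outside vessels as a fraction of tissue,
  a barrier-integrity readout;
* hypoxia statistics — mean fluorescence intensity and histogram of a
  pimonidazole-adduct channel over tissue, on the 12-bit 0–4095 scale;
* diffusion distances — the distribution of anisotropy-aware Euclidean
  distances from extravascular tissue to the nearest vessel, an oxygen
  supply proxy (meaningful only under physiological flow);
* PAS-positive area — 2D histochemistry percentage via an RGB interval
  threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = [
    "HypoxiaStats",
    "DiffusionDistanceStats",
    "perfusion_percentage",
    "extravascular_dextran_percentage",
    "hypoxia_stats",
    "diffusion_distance_stats",
    "pas_area_percentage",
]


@dataclass
class HypoxiaStats:
    mfi: float
    bin_edges: np.ndarray
    histogram: np.ndarray  # counts, len = n_bins
    bit_max: int
    n_tissue_voxels: int


@dataclass
class DiffusionDistanceStats:
    mean_um: float
    median_um: float
    p95_um: float
    max_um: float
    distances_um: np.ndarray  # full distribution over extravascular tissue


def _as_bool(grid: VoxelGrid) -> np.ndarray:
    return grid.values.astype(bool)


def perfusion_percentage(
    ib4_mask: VoxelGrid, icam2_mask: VoxelGrid, raw_ratio: bool = False
) -> float:
    """Percentage of ICAM2+ vasculature occupied by IB4.

    The default intersects IB4 with ICAM2 ("vasculature occupied"), which
    bounds the result to [0, 100]; ``raw_ratio`` reproduces the plain
    area-ratio formula, which can exceed 100% when IB4 spills beyond the
    ICAM2 mask.
    """
    if ib4_mask.shape != icam2_mask.shape:
        raise ValueError("shape mismatch between IB4 and ICAM2 masks")
    icam2 = _as_bool(icam2_mask)
    n_icam2 = int(icam2.sum())
    if n_icam2 == 0:
        raise ValueError("empty ICAM2 mask: perfusion percentage undefined")
    ib4 = _as_bool(ib4_mask)
    covered = int(ib4.sum()) if raw_ratio else int((ib4 & icam2).sum())
    return 100.0 * covered / n_icam2


def extravascular_dextran_percentage(
    dextran_mask: VoxelGrid, vessel_mask: VoxelGrid, tissue_mask: VoxelGrid
) -> float:
    """Percentage of tissue occupied by dextran outside the vasculature."""
    if not (dextran_mask.shape == vessel_mask.shape == tissue_mask.shape):
        raise ValueError("mask shapes differ")
    tissue = _as_bool(tissue_mask)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    leak = _as_bool(dextran_mask) & ~_as_bool(vessel_mask) & tissue
    return 100.0 * int(leak.sum()) / n_tissue


def hypoxia_stats(
    intensity: VoxelGrid, tissue_mask: VoxelGrid, n_bins: int = 64
) -> HypoxiaStats:
    """MFI and frequency histogram of hypoxia intensity over tissue voxels.

    The histogram covers the full declared bit range [0, bit_max] with
    ``n_bins`` equal bins; counts sum to the number of tissue voxels.
    """
    if intensity.shape != tissue_mask.shape:
        raise ValueError("intensity and tissue shapes differ")
    tissue = _as_bool(tissue_mask)
    if not tissue.any():
        raise ValueError("empty tissue mask")
    vals = intensity.values[tissue].astype(float)
    bit_max = intensity.bit_max
    hist, edges = np.histogram(vals, bins=n_bins, range=(0, bit_max))
    return HypoxiaStats(
        mfi=float(vals.mean()),
        bin_edges=edges,
        histogram=hist,
        bit_max=bit_max,
        n_tissue_voxels=int(tissue.sum()),
    )


def diffusion_distance_stats(
    vessel_mask: VoxelGrid, tissue_mask: VoxelGrid | None = None
) -> DiffusionDistanceStats:
    """Distances from extravascular tissue voxels to the nearest vessel (µm)."""
    vessels = _as_bool(vessel_mask)
    tissue = (
        np.ones(vessels.shape, dtype=bool) if tissue_mask is None else _as_bool(tissue_mask)
    )
    if not (vessels & tissue).any():
        raise ValueError("no vessels inside the tissue: diffusion distance undefined")
    edt = ndimage.distance_transform_edt(~vessels, sampling=vessel_mask.voxel_size_um)
    dist = edt[tissue & ~vessels]
    return DiffusionDistanceStats(
        mean_um=float(dist.mean()),
        median_um=float(np.median(dist)),
        p95_um=float(np.percentile(dist, 95)),
        max_um=float(dist.max()),
        distances_um=dist,
    )


def pas_area_percentage(
    rgb_image: np.ndarray,
    threshold_rule: dict[str, tuple[float, float]] | tuple,
    tissue_mask_2d: np.ndarray,
) -> float:
    """PAS-positive area percentage from an RGB histochemistry image.

    ``threshold_rule`` gives one inclusive (low, high) interval per
    channel, either as a mapping with keys "r", "g", "b" or as a 3-tuple
    of intervals; a pixel is positive when all three channels fall inside
    their intervals.
    """
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    tissue = np.asarray(tissue_mask_2d, dtype=bool)
    if tissue.shape != img.shape[:2]:
        raise ValueError("tissue mask and image shapes differ")
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    if isinstance(threshold_rule, dict):
        intervals = [threshold_rule[k] for k in ("r", "g", "b")]
    else:
        intervals = list(threshold_rule)
    positive = np.ones(img.shape[:2], dtype=bool)
    for c, (lo, hi) in enumerate(intervals):
        positive &= (img[:, :, c] >= lo) & (img[:, :, c] <= hi)
    return 100.0 * int((positive & tissue).sum()) / n_tissue
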