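"""Endothelial neighbour-density maps from nuclear (ERG) staining.

Mirrors the ImageJ neighbour-analysis macro this readout is based on: a
maximum-intensity projection over three z-planes spanning ~6 µm, a mean
filter plus Otsu threshold, watershed splitting of touching nuclei seeded
at distance-transform maxima, then for every detected nucleus the number
of neighbouring nuclei within a fixed radius (32 µm by default), the
histogram of those counts, and a colour index per nucleus.

Neighbour distances are measured between nucleus centroids in µm, self
excluded, with ties at exactly the radius counting as neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "NucleusDetection",
    "DensityMap",
    "mip_over_planes",
    "segment_nuclei",
    "neighbor_counts",
    "density_histogram",
    "build_density_map",
]

#: Neighbour radius of the published macro, µm.
DEFAULT_NEIGHBOR_RADIUS_UM = 32.0


@dataclass
class NucleusDetection:
    centroid_um: tuple[float, float]  # (y, x)
    area_um2: float


@dataclass
class DensityMap:
    detections: list[NucleusDetection]
    neighbor_counts: np.ndarray  # int per detection
    histogram: dict[int, int]  # neighbour number -> count
    color_index: np.ndarray  # int per detection

    def __post_init__(self) -> None:
        assert sum(self.histogram.values()) == len(self.detections)


def mip_over_planes(
    volume, n_planes: int = 3, start_plane: int = 0, span_um: float | None = None
) -> np.ndarray:
    """Maximum-intensity projection over ``n_planes`` consecutive z-planes.

    When ``span_um`` is given it must be consistent with ``n_planes`` at
    the grid's z spacing ((n_planes-1) z-steps cover span_um).
    """
    nz = volume.shape[0]
    if not 0 <= start_plane < nz or start_plane + n_planes > nz:
        raise ValueError(
            f"planes [{start_plane}, {start_plane + n_planes}) outside volume of {nz} planes"
        )
    if span_um is not None:
        dz = volume.voxel_size_um[0]
        if abs((n_planes - 1) * dz - span_um) > dz:
            raise ValueError(
                f"{n_planes} planes at dz={dz} µm do not span {span_um} µm"
            )
    return volume.values[start_plane : start_plane + n_planes].max(axis=0)


def segment_nuclei(
    image: np.ndarray,
    pixel_size_um: tuple[float, float] = (0.6, 0.6),
    mean_filter_radius_um: float = 2.0,
    min_area_um2: float = 8.0,
    min_seed_separation_um: float = 1.0,
) -> list[NucleusDetection]:
    """Mean filter → Otsu → watershed segmentation of nuclei in a 2D image.

    Touching nuclei are split by a watershed on the inverted internal
    distance transform, seeded at its local maxima (>= 1 µm apart);
    watershed fragments below ``min_area_um2`` are merged into their
    largest touching neighbour, and isolated components below the minimum
    area are dropped.  Centroids are reported in µm, (y, x).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    px = np.asarray(pixel_size_um, dtype=float)
    if img.max() == img.min():
        return []
    size = np.maximum(1, np.round(2 * mean_filter_radius_um / px).astype(int) | 1)
    smoothed = ndimage.uniform_filter(img, size=tuple(size))
    binary = smoothed > threshold_otsu(smoothed)
    if not binary.any():
        return []

    dist = ndimage.distance_transform_edt(binary, sampling=px)
    min_sep_px = max(1, int(round(min_seed_separation_um / min(px))))
    # a light smoothing breaks the flat plateaus of the distance transform,
    # which would otherwise seed one watershed basin per plateau voxel
    seed_field = ndimage.gaussian_filter(dist, sigma=1.0)
    peaks = peak_local_max(
        seed_field, min_distance=min_sep_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=int)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)
        # merge sub-minimum fragments into their largest touching neighbour
        pixel_area = float(px.prod())
        min_px = min_area_um2 / pixel_area
        changed = True
        while changed:
            changed = False
            sizes = np.bincount(labels.ravel())
            for lab in np.flatnonzero((sizes > 0) & (sizes < min_px)):
                if lab == 0:
                    continue
                region = labels == lab
                ring = ndimage.binary_dilation(region) & ~region
                nb = labels[ring]
                nb = nb[nb > 0]
                if len(nb):
                    labels[region] = np.bincount(nb).argmax()
                    changed = True

    pixel_area = float(px.prod())
    detections = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        area = len(ys) * pixel_area
        if len(ys) == 0 or area < min_area_um2:
            continue
        cy, cx = ys.mean() * px[0], xs.mean() * px[1]
        detections.append(NucleusDetection((float(cy), float(cx)), float(area)))
    return detections


def neighbor_counts(centroids_um: np.ndarray, radius_um: float = DEFAULT_NEIGHBOR_RADIUS_UM) -> np.ndarray:
    """Number of other nuclei within ``radius_um`` of each nucleus (<=, self excluded)."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = np.array(
        [len(tree.query_ball_point(p, radius_um)) - 1 for p in pts], dtype=int
    )
    return counts


def density_histogram(
    counts: np.ndarray, palette_length: int = 12
) -> tuple[dict[int, int], np.ndarray]:
    """Histogram of neighbour counts plus a per-nucleus colour index.

    The colour index is the neighbour count clipped to the palette length,
    mirroring the macro's colour coding of local endothelial density.
    """
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    hist = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    color_index = np.clip(counts, 0, palette_length - 1)
    return hist, color_index


def build_density_map(
    volume,
    n_planes: int = 3,
    start_plane: int = 0,
    radius_um: float = DEFAULT_NEIGHBOR_RADIUS_UM,
    **segment_kwargs,
) -> DensityMap:
    """MIP → nucleus segmentation → neighbour counting, end to end."""
    img = mip_over_planes(volume, n_planes=n_planes, start_plane=start_plane)
    detections = segment_nuclei(
        img, pixel_size_um=volume.voxel_size_um[1:], **segment_kwargs
    )
    centroids = np.array([d.centroid_um for d in detections]).reshape(-1, 2)
    counts = neighbor_counts(centroids, radius_um)
    hist, colors = density_histogram(counts)
    return DensityMap(detections, counts, hist, colors)
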