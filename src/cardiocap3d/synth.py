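"""Seeded synthetic 3D multi-channel capillary-bed datasets with ground truth.

Emulates the confocal imaging regime this package targets: 35 µm-thick
myocardial sections sampled every 2 µm in z (~18 planes), volumes of interest
of 350 × 350 × 35 µm containing a dense capillary network of ~2,000–3,000
segments, of which a few percent are *empty sleeves* — basement-membrane
(COL IV+) tubes that have lost their endothelium (ICAM2−), the histological
hallmark of capillary pruning.

Six channels are rendered per dataset:

``endothelium``
    ICAM2-like signal: tubes of every segment that still has endothelium.
``basement_membrane``
    COL IV-like signal: tubes of *all* segments (empty sleeves included),
    with a thin wall margin so the membrane ensheathes the endothelium.
``nuclei``
    ERG-like signal: spheres on vessel walls (endothelial nuclei).
``perfusion``
    IB4-like signal: tubes of perfused segments only.
``dextran``
    Intravascular tracer plus optional planted extravascular leak blobs.
``hypoxia``
    Pimonidazole-like 12-bit intensity increasing with distance from
    perfused vessels.

The network generator is a random space-filling branching process: iterative
midpoint sprouting with degree-3/4 branch nodes and minimum-separation
rejection sampling.  It is not a hemodynamic model; it exists to hit the
target summary statistics (segment count, radius range, sleeve fraction)
with exactly known ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import VoxelGrid, read_channel_tiff, write_channel_tiff

__all__ = [
    "VesselSegmentTruth",
    "TruthNode",
    "VascularGraphTruth",
    "SyntheticDataset",
    "CapacityError",
    "generate_vascular_tree",
    "plant_empty_sleeves",
    "set_perfused_fraction",
    "rasterize",
    "scatter_nuclei",
    "make_hypoxia_field",
    "write_dataset",
    "read_dataset",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = (
    "endothelium",
    "basement_membrane",
    "nuclei",
    "perfusion",
    "dextran",
    "hypoxia",
)

#: COL IV wall margin added to the endothelial tube radius (µm), so empty
#: sleeves are thin-walled membrane tubes around where endothelium was.
BM_WALL_UM = 0.5


class CapacityError(RuntimeError):
    """Requested segment density exceeds what the domain can pack."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class VesselSegmentTruth:
    """One ground-truth capillary segment (a polyline tube)."""

    id: int
    path_um: np.ndarray  # (n, 3) points, (z, y, x) µm
    radius_um: float
    is_empty_sleeve: bool = False
    is_perfused: bool = True

    def __post_init__(self) -> None:
        self.path_um = np.asarray(self.path_um, dtype=float)
        if self.path_um.ndim != 2 or self.path_um.shape[0] < 2 or self.path_um.shape[1] != 3:
            raise ValueError("path must be an (n>=2, 3) array")
        steps = np.linalg.norm(np.diff(self.path_um, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive path points must be distinct")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.is_empty_sleeve and self.is_perfused:
            raise ValueError("an empty sleeve cannot be perfused")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.path_um, axis=0), axis=1).sum())

    @property
    def chord_um(self) -> float:
        return float(np.linalg.norm(self.path_um[-1] - self.path_um[0]))

    @property
    def tortuosity(self) -> float:
        return self.length_um / self.chord_um


@dataclass
class TruthNode:
    id: int
    position_um: np.ndarray  # (3,) µm
    degree: int

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)


@dataclass
class VascularGraphTruth:
    """Ground-truth vascular network: nodes plus polyline segments."""

    nodes: list[TruthNode]
    segments: list[VesselSegmentTruth]
    domain_um: tuple[float, float, float]  # (z, y, x) extent

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_sleeves(self) -> int:
        return sum(s.is_empty_sleeve for s in self.segments)

    @property
    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.segments)

    def node_degrees(self) -> dict[int, int]:
        """Degrees recomputed from segment endpoints (for validation)."""
        pos = np.array([n.position_um for n in self.nodes])
        tree = cKDTree(pos)
        deg = {n.id: 0 for n in self.nodes}
        for seg in self.segments:
            for end in (seg.path_um[0], seg.path_um[-1]):
                d, i = tree.query(end)
                if d > 1e-6:
                    raise ValueError(f"segment {seg.id} endpoint not on a node (off by {d} µm)")
                deg[self.nodes[i].id] += 1
        return deg

    def validate(self) -> None:
        deg = self.node_degrees()
        for n in self.nodes:
            if deg[n.id] != n.degree:
                raise ValueError(f"node {n.id}: stored degree {n.degree} != incident {deg[n.id]}")
        lo = np.min([s.path_um.min(axis=0) for s in self.segments], axis=0)
        hi = np.max([s.path_um.max(axis=0) for s in self.segments], axis=0)
        if np.any(lo < -1e-9) or np.any(hi > np.asarray(self.domain_um) + 1e-9):
            raise ValueError("graph foreground extends outside the stated domain")


@dataclass
class SyntheticDataset:
    """Rendered channels plus the ground truth they were rendered from."""

    channels: dict[str, VoxelGrid]
    truth: VascularGraphTruth
    nuclei_truth: np.ndarray  # (n, 3) µm positions
    seed: int
    true_masks: dict[str, VoxelGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.channels.values()}
        sizes = {g.voxel_size_um for g in self.channels.values()}
        if len(shapes) > 1 or len(sizes) > 1:
            raise ValueError("all channels must share shape and voxel size")

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).voxel_size_um

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


class _GrowingBuffer:
    """Append-only (n, 3) float buffer exposing a contiguous view."""

    def __init__(self, capacity: int = 1024) -> None:
        self._buf = np.empty((capacity, 3))
        self.n = 0

    def append(self, pts: np.ndarray) -> None:
        pts = np.atleast_2d(pts)
        while self.n + len(pts) > len(self._buf):
            self._buf = np.concatenate([self._buf, np.empty_like(self._buf)])
        self._buf[self.n : self.n + len(pts)] = pts
        self.n += len(pts)

    def pop(self) -> None:
        self.n -= 1

    @property
    def view(self) -> np.ndarray:
        return self._buf[: self.n]


class _Packer:
    """Incremental minimum-clearance bookkeeping over centreline samples.

    Recent samples live in a flat pending buffer queried by brute force;
    older samples are periodically folded into a KD-tree.
    """

    _REBUILD_AT = 4000

    def __init__(self, sample_step_um: float) -> None:
        self.step = sample_step_um
        self._all = _GrowingBuffer(4096)
        self._tree: cKDTree | None = None
        self._tree_n = 0

    def add_chord(self, a: np.ndarray, b: np.ndarray) -> None:
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / self.step)) + 1)
        self._all.append(a[None] + np.linspace(0, 1, n)[:, None] * (b - a)[None])
        if self._all.n - self._tree_n > self._REBUILD_AT:
            self._tree = cKDTree(self._all.view.copy())
            self._tree_n = self._all.n

    def min_distance(self, pts: np.ndarray) -> float:
        best = np.inf
        if self._tree is not None:
            best = float(np.min(self._tree.query(pts)[0]))
        pending = self._all.view[self._tree_n :]
        if len(pending):
            diff = pts[:, None, :] - pending[None, :, :]
            best = min(best, float(np.sqrt(np.min(np.einsum("ijk,ijk->ij", diff, diff)))))
        return best


def generate_vascular_tree(
    domain_um: tuple[float, float, float] = (35.0, 350.0, 350.0),
    n_segments_target: int = 2500,
    radius_dist: tuple[float, float] = (2.5, 0.4),
    tortuosity_amplitude: float = 0.5,
    seed: int = 0,
    *,
    segment_length_um: tuple[float, float] = (10.0, 22.0),
    min_separation_um: float = 3.5,
    min_clearance_um: float | None = None,
    quad_fraction: float = 0.08,
    min_branch_angle_deg: float = 20.0,
    path_step_um: float = 2.0,
    max_failures: int = 400,
) -> VascularGraphTruth:
    """Grow a connected capillary network by iterative midpoint sprouting.

    Starting from one seed segment, each growth step either (a) splits a
    random existing segment at its midpoint and sprouts a new terminal branch
    from the split point (creating a degree-3 bifurcation node), or — with
    probability ``quad_fraction`` — (b) sprouts from an existing degree-3
    node, upgrading it to a degree-4 trifurcation.  New branch tips are
    rejection-sampled to stay inside the domain, at least
    ``min_separation_um`` from every existing node, and with centrelines at
    least ``min_clearance_um`` apart from non-adjacent vessels.

    Parameters
    ----------
    domain_um
        (z, y, x) extent of the tissue volume in µm.
    n_segments_target
        Growth stops once the segment count reaches this target, so the
        final count is the target or target+1 (well within ±10%).
    radius_dist
        (mean, sd) of the per-branch Gaussian radius draw, in µm; clamped
        below at 1.0 µm.
    tortuosity_amplitude
        Peak perpendicular bowing of each segment path in µm.  0 gives
        exactly straight polylines.
    min_clearance_um
        Minimum centreline–centreline distance between non-adjacent
        segments.  Default ``2 * radius mean + 1``: endothelial tubes never
        touch, though basement membranes of adjacent vessels may graze, as
        they do in dense myocardial beds.  Raise it (and lower the density)
        to generate well-separated networks.

    Raises
    ------
    CapacityError
        If rejection sampling stalls before reaching 90% of the target:
        the requested density exceeds the domain's packing capacity.
    """
    if n_segments_target < 1:
        raise ValueError("n_segments_target must be >= 1")
    domain = np.asarray(domain_um, dtype=float)
    if np.any(domain <= 0):
        raise ValueError("domain extents must be positive")
    r_mean, r_sd = radius_dist
    if r_mean <= 0:
        raise ValueError("radius mean must be positive")
    if min_clearance_um is None:
        min_clearance_um = 2.0 * r_mean + 1.0

    rng = np.random.default_rng(seed)
    margin = r_mean + BM_WALL_UM + tortuosity_amplitude + 0.5
    lo, hi = np.minimum(margin, domain / 2), np.maximum(domain - margin, domain / 2)

    def draw_radius() -> float:
        return float(max(1.0, rng.normal(r_mean, r_sd)))

    def draw_length() -> float:
        return float(rng.uniform(*segment_length_um))

    # node storage: positions buffer + per-node degree
    positions = _GrowingBuffer(1024)
    degrees: list[int] = []
    # edges as (node_a, node_b, radius)
    edges: list[tuple[int, int, float]] = []
    packer = _Packer(sample_step_um=max(1.0, min_clearance_um / 3))

    # sprout directions are biased toward the imaging plane in slab-like
    # domains (capillaries in a thin section run mostly in-plane), which is
    # also what lets dense networks pack into a 35 µm slab
    dir_scale = domain / np.max(domain)
    dir_scale = np.clip(dir_scale, 0.25, 1.0)

    def draw_direction() -> np.ndarray:
        return _unit(rng.normal(size=3) * dir_scale)

    incident_dirs: list[list[np.ndarray]] = []  # per-node outgoing unit dirs
    cos_min = np.cos(np.deg2rad(min_branch_angle_deg))

    def add_node(p: np.ndarray) -> int:
        positions.append(p)
        degrees.append(0)
        incident_dirs.append([])
        return positions.n - 1

    def add_edge(a: int, b: int, r: float) -> None:
        edges.append((a, b, r))
        degrees[a] += 1
        degrees[b] += 1
        d = _unit(positions.view[b] - positions.view[a])
        incident_dirs[a].append(d)
        incident_dirs[b].append(-d)
        packer.add_chord(positions.view[a].copy(), positions.view[b].copy())

    # seed segment through the domain centre
    p0 = rng.uniform(lo, hi)
    for _ in range(200):
        p1 = p0 + draw_direction() * draw_length()
        if np.all(p1 > lo) and np.all(p1 < hi):
            break
    else:  # pragma: no cover - degenerate domains only
        raise CapacityError("could not place the seed segment inside the domain")
    add_edge(add_node(p0), add_node(p1), draw_radius())

    def try_sprout(origin_idx: int) -> int | None:
        """Sample a new tip from ``origin``; return new node index or None."""
        origin = positions.view[origin_idx].copy()
        for _ in range(20):
            length = draw_length()
            direction = draw_direction()
            # real branch points have wide angles; near-parallel sprouts also
            # defeat skeleton-based recovery, so enforce a minimum angle
            if any(direction @ d > cos_min for d in incident_dirs[origin_idx]):
                continue
            tip = origin + direction * length
            if np.any(tip < lo) or np.any(tip > hi):
                continue
            diff = positions.view - tip
            if np.min(np.einsum("ij,ij->i", diff, diff)) < min_separation_um**2:
                continue
            # clearance: sample the new chord away from its own origin,
            # where contact with the parent vessel is legitimate
            n = max(2, int(np.ceil(length / packer.step)) + 1)
            t = np.linspace(0, 1, n)
            keep = t * length > min_clearance_um + 1e-9
            if keep.any():
                pts = origin[None] + t[keep, None] * (tip - origin)[None]
                if packer.min_distance(pts) < min_clearance_um:
                    continue
            return add_node(tip)
        return None

    failures = 0
    while len(edges) < n_segments_target:
        if failures >= max_failures:
            if len(edges) >= int(np.ceil(0.9 * n_segments_target)):
                warnings.warn(
                    f"packing stalled at {len(edges)} segments "
                    f"(target {n_segments_target}); within 10% of target"
                )
                break
            raise CapacityError(
                f"cannot pack {n_segments_target} segments into domain {tuple(domain)}: "
                f"stalled at {len(edges)}"
            )
        quad_candidates = [i for i, dg in enumerate(degrees) if dg == 3]
        if quad_candidates and rng.random() < quad_fraction:
            # upgrade a bifurcation to a trifurcation (degree 3 -> 4)
            origin = int(rng.choice(quad_candidates))
            tip = try_sprout(origin)
            if tip is None:
                failures += 1
                continue
            add_edge(origin, tip, draw_radius())
        else:
            # split a random edge at its midpoint and sprout from there
            ei = int(rng.integers(len(edges)))
            a, b, r = edges[ei]
            mid = 0.5 * (positions.view[a] + positions.view[b])
            # the split node must honour the full node separation, its own
            # edge endpoints included — only edges >= 2*min_separation split
            diff = positions.view - mid
            if np.min(np.einsum("ij,ij->i", diff, diff)) < min_separation_um**2:
                failures += 1
                continue
            m = add_node(mid)
            tip = try_sprout(m)
            if tip is None:
                positions.pop()
                degrees.pop()
                failures += 1
                continue
            # replace edge (a,b) by (a,m) + (m,b), then add the sprout;
            # the packer already holds samples of the full (a,b) chord
            edges[ei] = (a, m, r)
            edges.append((m, b, r))
            degrees[m] += 2
            axis = _unit(positions.view[b] - positions.view[a])
            incident_dirs[m].extend([-axis, axis])
            add_edge(m, tip, draw_radius())
        failures = 0

    # materialise polyline paths with perpendicular bowing
    nodes = [TruthNode(i, positions.view[i].copy(), degrees[i]) for i in range(positions.n)]
    segments = []
    for sid, (a, b, r) in enumerate(edges):
        pa, pb = positions.view[a].copy(), positions.view[b].copy()
        chord = pb - pa
        clen = np.linalg.norm(chord)
        n_pts = max(2, int(np.ceil(clen / path_step_um)) + 1)
        t = np.linspace(0.0, 1.0, n_pts)
        path = pa[None] + t[:, None] * chord[None]
        if tortuosity_amplitude > 0 and n_pts > 2:
            axis = _unit(chord)
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = _unit(np.cross(axis, ref))
            v = np.cross(axis, u)
            theta = rng.uniform(0, 2 * np.pi)
            bow = tortuosity_amplitude * np.sin(np.pi * t)
            path = path + bow[:, None] * (np.cos(theta) * u + np.sin(theta) * v)[None]
        segments.append(VesselSegmentTruth(sid, path, r))
    return VascularGraphTruth(nodes, segments, tuple(domain))


def generate_well_separated_tree(
    seed: int = 0,
    n_segments_target: int = 16,
    domain_um: tuple[float, float, float] = (40.0, 120.0, 120.0),
    radius_um: float = 2.5,
) -> VascularGraphTruth:
    """A sparse straight-tube network built for exact skeleton recovery.

    Junctions at least 12 µm apart, tubes at least 11 µm between
    centrelines, branch angles >= 40°, no bowing: every junction of the
    rasterised network resolves to an isolated skeleton clump, so graph
    extraction should recover segment and branch counts exactly.
    """
    return generate_vascular_tree(
        domain_um,
        n_segments_target,
        radius_dist=(radius_um, 0.0),
        tortuosity_amplitude=0.0,
        seed=seed,
        segment_length_um=(25.0, 35.0),
        min_separation_um=12.0,
        min_clearance_um=11.0,
        quad_fraction=0.25,
        min_branch_angle_deg=40.0,
    )


def plant_empty_sleeves(
    graph: VascularGraphTruth,
    fraction: float = 0.04,
    seed: int = 0,
    *,
    n_sleeves: int | None = None,
    prefer_bridging: bool = True,
    min_length_um: float = 0.0,
) -> VascularGraphTruth:
    """Flag a seeded subset of segments as empty sleeves (pruning events).

    The number flagged is exactly ``round(fraction * n_segments)`` (half
    away from zero), or ``n_sleeves`` when given explicitly.  When
    ``prefer_bridging`` (default), flagged segments are drawn first from
    *bridging* segments — both endpoints branch nodes of degree >= 3 and
    not shared with an already flagged segment — because pruning removes
    redundant connections between (still) perfused vessels; remaining
    picks fall back to the rest of the network.  ``min_length_um``
    restricts preferred candidates to segments at least that long.
    Flagged segments are never perfused.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = graph.n_segments
    k = n_sleeves if n_sleeves is not None else _round_half_up(fraction * n)
    if k > n:
        raise ValueError(f"cannot flag {k} sleeves among {n} segments")
    rng = np.random.default_rng(seed)

    deg = {nd.id: nd.degree for nd in graph.nodes}
    pos = np.array([nd.position_um for nd in graph.nodes])
    tree = cKDTree(pos) if len(pos) else None

    def endpoint_nodes(seg: VesselSegmentTruth) -> tuple[int, int]:
        return tuple(
            int(tree.query(end)[1]) for end in (seg.path_um[0], seg.path_um[-1])
        )  # type: ignore[return-value]

    seg_nodes = {s.id: endpoint_nodes(s) for s in graph.segments} if tree else {}

    if prefer_bridging and tree is not None:
        def is_bridging(s: VesselSegmentTruth) -> bool:
            a, b = seg_nodes[s.id]
            return (
                deg[graph.nodes[a].id] >= 3
                and deg[graph.nodes[b].id] >= 3
                and s.length_um >= min_length_um
            )

        bridging_ids = [s.id for s in graph.segments if is_bridging(s)]
        other_ids = [s.id for s in graph.segments if not is_bridging(s)]
        order = list(rng.permutation(bridging_ids)) + list(rng.permutation(other_ids))
        # greedy pass: avoid flagging two segments sharing a node, so each
        # sleeve bridges two segments that are themselves not flagged
        flagged: set[int] = set()
        used_nodes: set[int] = set()
        for sid in order:
            if len(flagged) == k:
                break
            a, b = seg_nodes[sid]
            if a in used_nodes or b in used_nodes:
                continue
            flagged.add(sid)
            used_nodes.update((a, b))
        for sid in order:  # relax adjacency if the quota is not met
            if len(flagged) == k:
                break
            flagged.add(sid)
    else:
        flagged = set(rng.permutation(n)[:k].tolist())

    segments = [
        replace(s, is_empty_sleeve=(s.id in flagged), is_perfused=s.id not in flagged)
        for s in graph.segments
    ]
    return VascularGraphTruth(list(graph.nodes), segments, graph.domain_um)


def sleeve_centroids(graph: VascularGraphTruth) -> np.ndarray:
    """Length-weighted centroid (µm) of each empty-sleeve segment's path."""
    out = []
    for s in graph.segments:
        if s.is_empty_sleeve:
            steps = np.linalg.norm(np.diff(s.path_um, axis=0), axis=1)
            mids = 0.5 * (s.path_um[:-1] + s.path_um[1:])
            out.append((mids * steps[:, None]).sum(axis=0) / steps.sum())
    return np.array(out).reshape(-1, 3)


def make_sleeve_benchmark_dataset(
    seed: int = 0,
    n_sleeves: int = 20,
    noise_sd: float = 200.0,
) -> SyntheticDataset:
    """Sleeve-detection benchmark: planted pruning events with clean geometry.

    A moderately dense network (~320 segments, 35 × 240 × 240 µm) with
    long inter-junction segments and >= 9 µm centreline clearance, so each
    planted sleeve is a visually separable COL IV tube — the regime in
    which sleeves are countable at all, by eye or by machine.  Sleeves are
    planted on bridging segments >= 20 µm long.
    """
    rng = np.random.default_rng(seed)
    s_tree, s_sleeve, s_raster = (int(v) for v in rng.integers(0, 2**31 - 1, size=3))
    tree = generate_vascular_tree(
        (35.0, 240.0, 240.0),
        320,
        seed=s_tree,
        segment_length_um=(36.0, 52.0),
        min_separation_um=9.0,
        min_clearance_um=9.0,
    )
    tree = plant_empty_sleeves(
        tree, seed=s_sleeve, n_sleeves=n_sleeves, min_length_um=20.0
    )
    return rasterize(tree, noise_sd=noise_sd, seed=s_raster)


def set_perfused_fraction(
    graph: VascularGraphTruth, perfused_fraction: float, seed: int = 0
) -> VascularGraphTruth:
    """Mark a seeded subset of non-sleeve segments as non-perfused.

    Keeps ``round(perfused_fraction * n_non_sleeve)`` non-sleeve segments
    perfused; used to emulate incomplete microvascular perfusion.
    """
    if not 0.0 <= perfused_fraction <= 1.0:
        raise ValueError("perfused_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    non_sleeve = [s.id for s in graph.segments if not s.is_empty_sleeve]
    keep = _round_half_up(perfused_fraction * len(non_sleeve))
    perfused = set(rng.permutation(non_sleeve)[:keep].tolist())
    segments = [
        replace(s, is_perfused=(s.id in perfused) and not s.is_empty_sleeve)
        for s in graph.segments
    ]
    return VascularGraphTruth(list(graph.nodes), segments, graph.domain_um)


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------


def _paint_tubes(
    out: np.ndarray,
    segments: list[VesselSegmentTruth],
    voxel_size: np.ndarray,
    radius_pad_um: float = 0.0,
) -> None:
    """OR capsule (rounded-cylinder) tubes into a boolean volume.

    Tube membership is evaluated exactly at voxel centres against the
    polyline: a voxel is foreground when its centre lies within
    ``radius + radius_pad`` of any path edge (capsule distance field).
    """
    shape = np.array(out.shape)
    for seg in segments:
        r = seg.radius_um + radius_pad_um
        pts = seg.path_um
        for a, b in zip(pts[:-1], pts[1:]):
            lo_um = np.minimum(a, b) - r
            hi_um = np.maximum(a, b) + r
            lo = np.maximum(0, np.floor(lo_um / voxel_size)).astype(int)
            hi = np.minimum(shape - 1, np.ceil(hi_um / voxel_size)).astype(int)
            if np.any(hi < lo):
                continue
            zz = (np.arange(lo[0], hi[0] + 1) * voxel_size[0])[:, None, None]
            yy = (np.arange(lo[1], hi[1] + 1) * voxel_size[1])[None, :, None]
            xx = (np.arange(lo[2], hi[2] + 1) * voxel_size[2])[None, None, :]
            ab = b - a
            denom = float(ab @ ab)
            dot = (zz - a[0]) * ab[0] + (yy - a[1]) * ab[1] + (xx - a[2]) * ab[2]
            t = np.clip(dot / denom, 0.0, 1.0)
            d2 = (
                (zz - a[0] - t * ab[0]) ** 2
                + (yy - a[1] - t * ab[1]) ** 2
                + (xx - a[2] - t * ab[2]) ** 2
            )
            out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= r * r


def true_tube_mask(
    graph: VascularGraphTruth,
    voxel_size_um: tuple[float, float, float] = (2.0, 0.6, 0.6),
    which: str = "endothelium",
) -> VoxelGrid:
    """Noise-free voxelisation of a channel's tubes (ground-truth mask).

    ``which`` selects the segment subset: ``endothelium`` (non-sleeves),
    ``basement_membrane`` (all segments, radius + wall margin) or
    ``perfusion`` (perfused segments).
    """
    voxel_size = np.asarray(voxel_size_um, dtype=float)
    shape = tuple(int(np.ceil(d / v)) for d, v in zip(graph.domain_um, voxel_size))
    out = np.zeros(shape, dtype=bool)
    if which == "endothelium":
        segs, pad = [s for s in graph.segments if not s.is_empty_sleeve], 0.0
    elif which == "basement_membrane":
        segs, pad = list(graph.segments), BM_WALL_UM
    elif which == "perfusion":
        segs, pad = [s for s in graph.segments if s.is_perfused], 0.0
    else:
        raise ValueError(f"unknown tube channel {which!r}")
    smallest_r = min((s.radius_um for s in segs), default=np.inf) + pad
    if smallest_r < max(voxel_size):
        warnings.warn(
            f"voxel size {tuple(voxel_size)} exceeds the smallest tube radius "
            f"{smallest_r:.2f} µm; thin tubes may vanish from the raster"
        )
    _paint_tubes(out, segs, voxel_size, radius_pad_um=pad)
    return VoxelGrid(out, tuple(voxel_size), channel_name=which)


def scatter_nuclei(
    graph: VascularGraphTruth,
    linear_density_per_um: float = 0.05,
    nucleus_radius_um: float = 2.5,
    seed: int = 0,
    voxel_size_um: tuple[float, float, float] = (2.0, 0.6, 0.6),
) -> tuple[VoxelGrid, np.ndarray]:
    """Scatter endothelial nuclei along vessel walls.

    The nucleus count is Poisson with mean ``density × total non-sleeve
    path length``; each nucleus is a sphere whose centre sits on the wall
    of a length-weighted random segment (empty sleeves carry no nuclei —
    their endothelium is gone).  Returns the rendered mask and the exact
    list of centres; the truth list is independent of rendering overlap.
    """
    if linear_density_per_um < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    voxel_size = np.asarray(voxel_size_um, dtype=float)
    shape = tuple(int(np.ceil(d / v)) for d, v in zip(graph.domain_um, voxel_size))
    segs = [s for s in graph.segments if not s.is_empty_sleeve]
    total = sum(s.length_um for s in segs)
    n = int(rng.poisson(linear_density_per_um * total)) if total > 0 else 0

    centres = []
    if n and segs:
        lengths = np.array([s.length_um for s in segs])
        pick = rng.choice(len(segs), size=n, p=lengths / lengths.sum())
        for si in pick:
            seg = segs[si]
            steps = np.linalg.norm(np.diff(seg.path_um, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(steps)])
            arc = rng.uniform(0, cum[-1])
            e = min(np.searchsorted(cum, arc, side="right") - 1, len(steps) - 1)
            frac = (arc - cum[e]) / steps[e]
            p = seg.path_um[e] + frac * (seg.path_um[e + 1] - seg.path_um[e])
            axis = _unit(seg.path_um[e + 1] - seg.path_um[e])
            perp = _random_unit(rng)
            perp = perp - (perp @ axis) * axis
            nrm = np.linalg.norm(perp)
            perp = perp / nrm if nrm > 1e-9 else _unit(np.cross(axis, [1.0, 0.0, 0.0]))
            centres.append(p + seg.radius_um * perp)
    centres_arr = np.array(centres).reshape(-1, 3)

    out = np.zeros(shape, dtype=bool)
    r = nucleus_radius_um
    for c in centres_arr:
        lo = np.maximum(0, np.floor((c - r) / voxel_size)).astype(int)
        hi = np.minimum(np.array(shape) - 1, np.ceil((c + r) / voxel_size)).astype(int)
        if np.any(hi < lo):
            continue
        zz = (np.arange(lo[0], hi[0] + 1) * voxel_size[0])[:, None, None]
        yy = (np.arange(lo[1], hi[1] + 1) * voxel_size[1])[None, :, None]
        xx = (np.arange(lo[2], hi[2] + 1) * voxel_size[2])[None, None, :]
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= r * r
    return VoxelGrid(out, tuple(voxel_size), channel_name="nuclei"), centres_arr


def make_hypoxia_field(
    vessel_mask: VoxelGrid,
    decay_length_um: float = 25.0,
    max_intensity: float = 3000.0,
) -> VoxelGrid:
    """Saturating-exponential hypoxia intensity from perfused vessels.

    ``I(v) = max_intensity * (1 - exp(-d(v)/decay_length))`` where ``d`` is
    the anisotropy-aware Euclidean distance (µm) to the nearest vessel
    voxel: 0 on vessels, rising monotonically with distance toward the
    ceiling — the oxygen-diffusion-limited pimonidazole pattern.
    """
    if decay_length_um <= 0:
        raise ValueError("decay_length_um must be positive")
    if not 0 <= max_intensity <= vessel_mask.bit_max:
        raise ValueError(f"max_intensity must lie in [0, {vessel_mask.bit_max}]")
    mask = vessel_mask.values.astype(bool)
    if not mask.any():
        warnings.warn("empty vessel mask: hypoxia field is uniformly max_intensity")
        field_ = np.full(mask.shape, float(max_intensity))
    else:
        d = ndimage.distance_transform_edt(~mask, sampling=vessel_mask.voxel_size_um)
        field_ = max_intensity * (1.0 - np.exp(-d / decay_length_um))
    return VoxelGrid(
        field_, vessel_mask.voxel_size_um, channel_name="hypoxia", bit_max=vessel_mask.bit_max
    )


def rasterize(
    graph: VascularGraphTruth,
    voxel_size_um: tuple[float, float, float] = (2.0, 0.6, 0.6),
    psf_sigma_um: float = 0.5,
    noise_sd: float = 200.0,
    background: float = 100.0,
    seed: int = 0,
    *,
    amplitude: float = 2000.0,
    nuclei_density_per_um: float = 0.05,
    nucleus_radius_um: float = 2.5,
    hypoxia_decay_um: float = 25.0,
    n_leak_blobs: int = 0,
    leak_radius_um: float = 4.0,
) -> SyntheticDataset:
    """Render a ground-truth network into the six imaging channels.

    Each structural channel is built as ``blur(tube indicator) * amplitude
    + background + N(0, noise_sd)``, clipped to the 12-bit range [0, 4095]
    and rounded to integer grey levels.  The point-spread function is an
    isotropic Gaussian of ``psf_sigma_um`` applied with per-axis voxel
    scaling.  All randomness comes from one generator seeded with ``seed``
    (draw order: noise per channel in CHANNEL_NAMES order; nuclei placement
    and leak blobs use sub-seeds derived from it).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    voxel_size = np.asarray(voxel_size_um, dtype=float)
    if np.any(voxel_size <= 0):
        raise ValueError("voxel sizes must be positive")
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    masks = {
        name: true_tube_mask(graph, tuple(voxel_size), which=name)
        for name in ("endothelium", "basement_membrane", "perfusion")
    }
    nuc_grid, nuclei_truth = scatter_nuclei(
        graph, nuclei_density_per_um, nucleus_radius_um, int(sub[0]), tuple(voxel_size)
    )
    masks["nuclei"] = nuc_grid

    # dextran: intravascular tracer in perfused vessels + planted leaks
    dextran = masks["perfusion"].values.copy()
    leak_rng = np.random.default_rng(int(sub[1]))
    shape = np.array(dextran.shape)
    outside = ~masks["basement_membrane"].values
    for _ in range(n_leak_blobs):
        for _ in range(200):
            c = leak_rng.uniform(0, np.asarray(graph.domain_um))
            ci = np.minimum(shape - 1, (c / voxel_size).astype(int))
            if outside[tuple(ci)]:
                break
        lo = np.maximum(0, np.floor((c - leak_radius_um) / voxel_size)).astype(int)
        hi = np.minimum(shape - 1, np.ceil((c + leak_radius_um) / voxel_size)).astype(int)
        zz = (np.arange(lo[0], hi[0] + 1) * voxel_size[0])[:, None, None]
        yy = (np.arange(lo[1], hi[1] + 1) * voxel_size[1])[None, :, None]
        xx = (np.arange(lo[2], hi[2] + 1) * voxel_size[2])[None, None, :]
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        dextran[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= (
            d2 <= leak_radius_um**2
        )
    masks["dextran"] = VoxelGrid(dextran, tuple(voxel_size), channel_name="dextran")

    hypoxia_true = make_hypoxia_field(
        masks["perfusion"], decay_length_um=hypoxia_decay_um, max_intensity=3000.0
    )

    sigma_vox = psf_sigma_um / voxel_size

    def render(base: np.ndarray, name: str) -> VoxelGrid:
        img = base.astype(float)
        if psf_sigma_um > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        img = np.round(np.clip(img, 0, 4095))
        return VoxelGrid(img, tuple(voxel_size), channel_name=name)

    channels: dict[str, VoxelGrid] = {}
    for name in CHANNEL_NAMES:
        if name == "hypoxia":
            channels[name] = render(hypoxia_true.values, name)
        else:
            channels[name] = render(masks[name].values * amplitude + background, name)

    return SyntheticDataset(
        channels=channels,
        truth=graph,
        nuclei_truth=nuclei_truth,
        seed=seed,
        true_masks=masks,
    )


def make_dataset(
    seed: int = 0,
    *,
    domain_um: tuple[float, float, float] = (35.0, 350.0, 350.0),
    n_segments_target: int = 2500,
    sleeve_fraction: float = 0.04,
    n_sleeves: int | None = None,
    voxel_size_um: tuple[float, float, float] = (2.0, 0.6, 0.6),
    noise_sd: float = 200.0,
    **raster_kwargs,
) -> SyntheticDataset:
    """Convenience wrapper: tree -> sleeves -> rasterised dataset.

    Defaults reproduce the study conditions: 350 × 350 × 35 µm volumes of
    interest sampled every 2 µm in z, ~2,500 capillary segments of which
    ~4% are empty sleeves, 10%-of-amplitude Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    s_tree, s_sleeve, s_raster = (int(v) for v in rng.integers(0, 2**31 - 1, size=3))
    tree = generate_vascular_tree(domain_um, n_segments_target, seed=s_tree)
    tree = plant_empty_sleeves(tree, sleeve_fraction, seed=s_sleeve, n_sleeves=n_sleeves)
    return rasterize(
        tree, voxel_size_um, noise_sd=noise_sd, seed=s_raster, **raster_kwargs
    )


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def _truth_to_json(truth: VascularGraphTruth) -> dict:
    return {
        "domain_um": list(truth.domain_um),
        "nodes": [
            {"id": n.id, "position_um": n.position_um.tolist(), "degree": n.degree}
            for n in truth.nodes
        ],
        "segments": [
            {
                "id": s.id,
                "path_um": s.path_um.tolist(),
                "radius_um": s.radius_um,
                "is_empty_sleeve": s.is_empty_sleeve,
                "is_perfused": s.is_perfused,
            }
            for s in truth.segments
        ],
    }


def _truth_from_json(d: dict) -> VascularGraphTruth:
    nodes = [TruthNode(n["id"], np.array(n["position_um"]), n["degree"]) for n in d["nodes"]]
    segments = [
        VesselSegmentTruth(
            s["id"],
            np.array(s["path_um"]),
            s["radius_um"],
            s["is_empty_sleeve"],
            s["is_perfused"],
        )
        for s in d["segments"]
    ]
    return VascularGraphTruth(nodes, segments, tuple(d["domain_um"]))


def write_dataset(ds: SyntheticDataset, dir_path: str | Path) -> Path:
    """Write channels (multi-page TIFF + sidecar), truth masks, and truth JSON."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for name, grid in ds.channels.items():
        write_channel_tiff(grid, dir_path / f"{name}.tif")
    for name, grid in ds.true_masks.items():
        write_channel_tiff(grid, dir_path / f"true_{name}.tif")
    payload = {
        "seed": ds.seed,
        "nuclei_truth_um": ds.nuclei_truth.tolist(),
        "truth": _truth_to_json(ds.truth),
        "true_mask_names": sorted(ds.true_masks),
    }
    (dir_path / "truth.json").write_text(json.dumps(payload))
    return dir_path


def read_dataset(dir_path: str | Path) -> SyntheticDataset:
    dir_path = Path(dir_path)
    truth_path = dir_path / "truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(f"missing truth.json in {dir_path}")
    payload = json.loads(truth_path.read_text())
    channels: dict[str, VoxelGrid] = {}
    for name in CHANNEL_NAMES:
        path = dir_path / f"{name}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing channel file for {name!r}: {path}")
        channels[name] = read_channel_tiff(path)
    shapes = {g.shape for g in channels.values()}
    if len(shapes) > 1:
        bad = {n: g.shape for n, g in channels.items()}
        raise ValueError(f"channel shape mismatch on load: {bad}")
    true_masks = {
        name: read_channel_tiff(dir_path / f"true_{name}.tif")
        for name in payload.get("true_mask_names", [])
        if (dir_path / f"true_{name}.tif").exists()
    }
    return SyntheticDataset(
        channels=channels,
        truth=_truth_from_json(payload["truth"]),
        nuclei_truth=np.array(payload["nuclei_truth_um"]).reshape(-1, 3),
        seed=payload["seed"],
        true_masks=true_masks,
    )
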