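# Methods

This note documents the models, algorithms and parameter choices behind
`cardiocap3d`, in the spirit of a methods appendix: what each stage
computes, which knobs matter, and what the synthetic benchmarks do and do
not establish about real data.

## The measurement problem

During postnatal development the coronary microvasculature is remodelled
by *capillary pruning*: poorly perfused segments regress, leaving behind
an **empty sleeve** — a basement-membrane tube (collagen IV positive)
with no endothelium inside (ICAM2 negative). Pruning abundance is small
relative to the network (on the order of 100–150 events against
2,000–3,000 segments in a 350 × 350 × 35 µm myocardial volume, i.e. ~4%),
so the quantities of interest are counts and count ratios extracted from
dense 3D multi-channel fluorescence stacks: sleeve counts, segment and
bifurcation counts, diameters and tortuosity, fractal heterogeneity,
endothelial neighbour density, perfusion and hypoxia intensity.

All volumes are `(z, y, x)` arrays with anisotropic voxel sizes in µm
(default 2.0 × 0.6 × 0.6 µm — optical sections every 2 µm with a ×20
objective). Every distance computation in the package (distance
transforms, dilations, skeleton lengths, neighbour radii) is µm-scaled
per axis; nothing assumes isotropy.

## Synthetic data generator

No public dataset accompanies this kind of experiment, so the generator
is a first-class module: it produces multi-channel volumes with exact
ground truth under the imaging regime above.

**Network.** A random space-filling branching process: a seed segment is
grown by repeatedly either (a) splitting a random segment at its midpoint
and sprouting a new branch from the split point (creating a degree-3
bifurcation) or (b), with probability ~0.08, sprouting from an existing
degree-3 node (creating a degree-4 trifurcation). Tips are
rejection-sampled against four constraints: stay inside the domain,
minimum node separation (default 3.5 µm; a split requires the midpoint to
honour the full separation, so only sufficiently long segments split),
minimum centreline clearance to non-adjacent vessels (default
`2·r_mean + 1` µm — endothelial tubes never touch), and minimum branch
angle (default 20°, since real branch points are wide-angled and
near-parallel sprouts are also unresolvable in any skeleton). Sprout
directions are biased toward the imaging plane in slab-like domains,
which is both what thin-section data looks like and what makes dense
packing of a 35 µm slab feasible. Radii are Gaussian (default
2.5 ± 0.4 µm, clamped at 1 µm); paths are polylines with an optional
perpendicular sinusoidal bow (default amplitude 0.5 µm) giving
tortuosity > 1. Stalling before 90% of the target count raises a
capacity error; between 90% and 100% it returns with a warning.

**Sleeves.** `plant_empty_sleeves` flags exactly `round(fraction ×
n_segments)` segments (default fraction 0.04). Preference order: segments
*bridging* two branch nodes, not sharing a node with an already flagged
segment (pruning removes redundant connections between vessels that stay
perfused); the quota falls back to arbitrary segments if the preferred
pool runs out. Flagged segments are never perfused.

**Rendering.** Channels are capsule (rounded-cylinder) distance fields
evaluated at voxel centres: endothelium = non-sleeve tubes;
basement membrane = all tubes at radius + 0.5 µm (the membrane ensheathes
the endothelium, so sleeves are thin-walled tubes); perfusion = perfused
tubes; nuclei = spheres (default radius 2.5 µm) Poisson-scattered along
non-sleeve vessel walls at 0.05/µm; dextran = perfused tubes plus
optional planted extravascular leak spheres; hypoxia = `I_max·(1 −
exp(−d/λ))` of the µm distance `d` to the nearest perfused vessel
(default λ = 25 µm, `I_max` = 3000 on the 12-bit 0–4095 scale).
Intensity channels are Gaussian-blurred (PSF σ 0.5 µm), scaled to
amplitude 2000 over background 100, corrupted with seeded Gaussian noise
(default SD 200 = 10% of amplitude), clipped to [0, 4095] and rounded to
integer grey levels so that the TIFF round trip is exact. One integer
seed drives every draw in a documented order.

**What the generator does not emulate:** optical anisotropy of the PSF,
depth-dependent attenuation, autofluorescence texture, stain
heterogeneity along a single vessel, or motion/stitching artifacts.
Passing the benchmarks therefore demonstrates correctness of the
*computations* under realistic geometry and noise amplitude, not
robustness to every failure mode of real microscopy.

## Segmentation

`multiscale_multilevel_segment`: for each scale in a µm list, smooth with
a per-axis-scaled Gaussian, apply multilevel Otsu, keep the top classes;
union the per-scale masks; drop 26-connected components below a minimum
volume. The multilevel Otsu is an exhaustive search over 256-bin
histogram cuts (2–4 classes), maximising between-class variance with a
deterministic lowest-threshold tie-break; it is validated against an
independent brute-force enumeration and against scikit-image's
implementation to within one histogram bin.

Defaults: scales {1, 2, 4} µm (spanning capillary radii), 3 classes, top
1 foreground, 50 µm³ minimum component. For the *structural* channels
entering sleeve detection the package uses a deliberately tighter preset
(`STRUCTURAL_SEG_PARAMS`: single 1 µm scale, 2 classes): detection
subtracts one mask from another, so shared small boundary bias matters
more than completeness, and coarse scales inflate both masks and smear
the difference set.

## Skeleton and graph

`skeletonize_mask` wraps the 3D thinning of scikit-image (unit-width,
topology-preserving). `build_graph` classifies skeleton voxels by their
26-neighbour count: junction voxels (≥ 3) are clustered by adjacency into
one node each (centroid position); chain voxels with two neighbours in
one cluster are absorbed into it (they are part of the junction clump);
endpoints are degree-1 nodes. Segments are simple chain walks between
nodes; direct node–node contacts yield one segment per cluster pair;
junction-free cycles become flagged self-loops with chord set to the
minimum voxel spacing. Two cleanups address systematic digitisation
artifacts:

* **junction fusing** (default 2 µm, 5 µm for sparse benchmark networks):
  junction clusters connected by a skeleton path shorter than the
  threshold merge into one node — discrete skeletons split trifurcations
  into two nearby bifurcation clumps;
* **spur pruning** (default 4 µm ≈ one capillary radius): terminal
  segments shorter than the threshold are artifacts of bumpy tube
  surfaces; removal is iterated, and any node left with degree 2 is
  dissolved by merging its two segments (length-weighted diameter).
  The operation is idempotent, and the spur threshold is reported in all
  outputs because it shifts counts.

Geometry per segment: length = sum of µm steps along the voxel path;
chord = µm distance between path endpoints (tortuosity = length/chord ≥ 1
by construction); diameter = twice the mean of the mask's µm distance
transform sampled along the path. On noise-free, well-separated synthetic
trees (radius 2.5 voxels, junctions ≥ 12 µm apart, branch angles ≥ 40°)
segment/bifurcation/trifurcation counts are recovered *exactly* over
seeds, and mean diameter is within ~0.5 µm (well under one voxel
diagonal). Exactness degrades, by design of the underlying geometry, when
junctions approach the tube radius in separation.

## Empty-sleeve detection

Candidates are 26-connected components of `basement_membrane ∖
dilate(endothelium)`. The dilation radius (default 1 µm) absorbs
registration jitter and the membrane wall around intact vessels; its
structuring element is an ellipsoid with semi-axes `radius + voxel/2`
per axis, because voxelisation quantises surfaces by up to half a voxel
per axis — with 2 µm z-steps a literal 1 µm ball would be empty along z
and every vessel would leave a spurious one-voxel membrane rim.
Filters define what counts as a sleeve: principal-axis extent ≥ 5 µm,
equivalent-cross-section diameter ≤ 10 µm (volume/length, exact for
cylinders), elongation ≥ 1.5, and (on by default) a bridging requirement
that both principal-axis extremities lie within the dilation radius plus
one voxel diagonal of the endothelium mask — a pruned connection between
two endothelialised vessels. Events are sorted by centroid, so output is
independent of labelling order. Abundance readouts: events/mm³ (1 mm³ =
10⁹ µm³) and 100 × events/segments.

The detection benchmark plants 20 sleeves in a moderately dense network
(~320 segments in 35 × 240 × 240 µm, centrelines ≥ 9 µm apart, sleeves
on bridging segments ≥ 20 µm long) at 10%-of-amplitude noise; recall and
precision are ≥ 0.9 (typically 1.0) against ground truth with a 5 µm
centroid match. Separation is a genuine physical requirement, not a
convenience: a sleeve whose membrane tube abuts a neighbouring vessel is
not a countable object for a human annotator either.

## Fractal dimension and lacunarity

Box counting uses grid-aligned boxes with the origin fixed at index 0;
FD is minus the slope of the unweighted least-squares line of log N(r)
on log r (default sizes: powers of 2 up to a quarter of the smallest
dimension; a log-log fit with r² < 0.95 logs a warning). Lacunarity is
gliding-box: an r³ window slides with stride 1 over fully contained
positions, masses are exact integer sums via a 3D integral image, and
Λ(r) = 1 + var/mean² (population variance), so Λ ≡ 1 for homogeneous
masks. Boxes are voxel-defined, as in standard implementations; an
optional µm-isotropic resampling pre-step exists for strongly
anisotropic stacks and is off by default. Validation: FD = 3.00/1.00
exactly on cubes/lines, 2.727 on a level-3 Menger sponge (the
similarity dimension log 20/log 3), Λ equal to exhaustive enumeration.
Across-VOI heterogeneity is the sample SD (n−1) plus CV, with SD forced
to exact 0 for identical inputs.

## Density mapping

The neighbour-density map follows the macro it automates: MIP over three
z-planes (~6 µm), mean filter (default radius 2 µm), Otsu threshold,
watershed split of touching nuclei seeded at local maxima of the internal
distance transform (lightly smoothed to break plateau ties; 1 µm minimum
seed separation), fragments under 8 µm² merged into their largest
touching neighbour. Neighbour counts use nucleus centroids in µm with an
inclusive 32 µm radius, self excluded; the histogram and a clipped colour
index per nucleus mirror the macro's output. Counts are validated against
O(n²) enumeration and a Poisson-intensity expectation.

## Perfusion, hypoxia, diffusion distance, PAS

Perfusion = 100 × |IB4 ∧ ICAM2| / |ICAM2|. The plain area ratio (no
intersection) can exceed 100% when tracer spills outside the endothelial
mask; since the quantity of interest is "fraction of vasculature
occupied", the bounded form is the default and `raw_ratio=True`
reproduces the literal ratio. Extravascular dextran = 100 × |dextran ∧
¬vessel ∧ tissue| / |tissue|. Hypoxia statistics are the mean and an
equal-bin histogram over the declared bit range (default 12-bit, 0–4095)
of tissue voxels. Diffusion distances are the µm distance-transform
values of extravascular tissue voxels to the nearest vessel, summarised
by mean/median/p95/max — a supply proxy that is only physiologically
meaningful when the network is actually perfused. PAS area applies an
inclusive per-channel RGB interval rule on 2D histochemistry images.

## Physiology formulas

LV wall strain = 100 × (systolic − diastolic)/systolic thickness,
unclamped. Rate corrections: QRSc = QRS + 0.0125·(1 − RR), QTc = QT +
0.0154·(1 − RR). These constants are only dimensionally coherent with RR
in *seconds* (neonatal mouse RR ≈ 0.1–0.2 s, so the correction is
positive at physiological rates); the package therefore takes all ECG
durations in seconds. Stage differentials are Δ = P7 − P1 and %Δ = 100 ×
Δ/P1. Pearson reports use the exact r with the two-sided p from the
t transform on n − 2 degrees of freedom (validated against a
20,000-draw permutation null); p-values are reported uncorrected.

## End-to-end property

The pipeline-level check mirrors the central biological correlation:
five sibling VOIs are generated with increasing numbers of planted
sleeves (2–12) on bifurcation-bridging segments, the full
segmentation → graph → detection pipeline runs on the rendered channels,
and detected pruning events are correlated with measured bifurcation
counts. Because each sleeve silences a segment bridging two branch
points, heavier pruning depletes bifurcations: r < 0 in ≥ 9 of 10 seeds
(observed 10/10, mean r ≈ −0.95).

## Problem sizes and numerical choices

Benchmarks run on reduced but structurally faithful volumes chosen as
the package's own test conditions: full 350 × 350 × 35 µm networks are
exercised at the ground-truth level (segment counts, sleeve ratios),
while rendered-channel analyses use 150–240 µm lateral fields at the
same voxel size, noise level and vessel geometry — the computations are
identical per voxel, only the field of view is smaller. Otsu uses 256
histogram bins; box sizes must span at least two doublings; spur and
fuse thresholds are reported alongside counts; ties (Otsu maximisers,
component ordering) are broken deterministically. All stochastic stages
take explicit integer seeds; identical seeds reproduce byte-identical
datasets.

## Known limitations

* Graph counts are exact only when junction separation comfortably
  exceeds the tube radius; dense networks (2,000+ segments per VOI) are
  measured, not exactly recovered, and counts there carry
  skeletonisation bias that the spur/fuse thresholds partially control.
* Sleeve detection requires geometric separability (see above); at the
  full in-vivo packing density some sleeves are not resolvable as
  distinct components at this voxel size.
* The nucleus counter in the 3D pipeline merges overlapping nuclei
  (undercounting crowded fields); the 2D density map's watershed handles
  moderate overlap only.
* No flow or oxygen-transport modelling: hypoxia fields and diffusion
  distances are geometric proxies.
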