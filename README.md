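# cardiocap3d

Quantification of the 3D coronary capillary network from multi-channel
fluorescence stacks: automated detection of **capillary pruning events**
(collagen IV–positive / ICAM2-negative *empty sleeves*), vascular graph
morphometrics, fractal heterogeneity, endothelial neighbour-density
maps, and perfusion/oxygenation readouts — plus a seeded synthetic-data
generator that renders ground-truth capillary beds, so every stage of
the pipeline is testable end to end without any imaging data.

**Who it is for.** Vascular and cardiac developmental biologists
quantifying microvascular remodelling in thick-section confocal stacks
(e.g. postnatal mouse hearts: 35 µm sections imaged every 2 µm, volumes
of interest of 350 × 350 × 35 µm containing thousands of capillary
segments, of which a few percent are pruning events).

## What it computes

| Readout | Core definition |
|---|---|
| Empty sleeves | 26-connected components of `COLIV-mask ∖ dilate(ICAM2-mask)` passing length/diameter/elongation/bridging filters; reported per mm³ and as % of segments |
| Vascular graph | 3D skeleton → junction-clustered nodes and segments with µm length, chord, tortuosity = length/chord, diameter from the distance transform |
| Segmentation | multi-scale multilevel (Otsu) thresholding, anisotropy-aware, with exhaustive deterministic threshold search |
| Fractal / lacunarity | grid box counting, FD = −slope of log N(r) vs log r; gliding-box Λ(r) = 1 + var(M)/mean(M)² |
| Density map | MIP → mean filter → Otsu → watershed nuclei, neighbour counts within 32 µm |
| Perfusion / hypoxia | 100·\|IB4 ∧ ICAM2\|/\|ICAM2\|; extravascular dextran %; 12-bit hypoxia MFI and histogram; µm diffusion distances |
| Physiology | LV strain = 100·(sys − dia)/sys; QRSc = QRS + 0.0125·(1 − RR); QTc = QT + 0.0154·(1 − RR); Δ/%Δ stage differentials; Pearson reports |

## Worked example

Generate a synthetic benchmark volume (35 × 240 × 240 µm, ~320 capillary
segments, 20 planted empty sleeves, 10%-of-amplitude noise) and run the
full pipeline on its rendered channels:

```python
from cardiocap3d import synth
from cardiocap3d.pipeline import analyze_dataset

ds = synth.make_sleeve_benchmark_dataset(seed=1, n_sleeves=20)
report = analyze_dataset(ds.channels)
for key in ("n_segments", "n_bifurcations", "n_pruning_events",
            "pruning_segment_ratio_pct", "mean_diameter_um",
            "mean_tortuosity", "perfusion_pct"):
    print(f"{key:28s} {report[key]:.4g}")
```

prints

```
n_segments                   266
n_bifurcations               121
n_pruning_events             20
pruning_segment_ratio_pct    7.519
mean_diameter_um             4.816
mean_tortuosity              1.193
perfusion_pct                98.75
```

All 20 planted sleeves are detected (the dataset's ground truth is in
`ds.truth`); the graph metrics are *measurements* on the segmented,
skeletonised network — segment counts on dense noisy volumes carry
digitisation bias, which is why the exactness guarantees are stated on
well-separated networks (see `docs/methods.md`). Mean diameter ~4.8 µm
and tortuosity ~1.19 match the generator's capillary geometry (radius
2.5 ± 0.4 µm, bowed polyline paths).

The same stages are available from the shell:

```bash
cardiocap3d simulate --seed 3 --out ds/
cardiocap3d segment  --in ds/endothelium.tif --out mask.tif
cardiocap3d graph    --mask mask.tif --out metrics.csv
cardiocap3d pruning  --bm ds/basement_membrane.tif --ec ds/endothelium.tif --out events.csv
cardiocap3d report   --metrics metrics.csv --pairs n_pruning_events:n_bifurcations --out corr.csv
```

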