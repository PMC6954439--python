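# mitoshape

Quantification and classification of mitochondrial network morphology in
calibrated fluorescence microscopy images.

Mitochondria continuously fuse and divide, and the balance shows up in
their shapes: extended filamentous networks, shorter rods, fragmented
puncta, and swollen spheres. Shifts between these classes are a standard
readout for mitochondrial stress and dynamics defects, but scoring them
by eye does not scale. `mitoshape` automates the readout for
MitoTracker-style stainings: it segments mitochondria in 2D images (or
Z-projected stacks), measures each object's shape in physical units, and
assigns every object one of the four classes with rule thresholds given
in micrometres. It is written for cell biologists who have calibrated
TIFFs and per-cell outlines and want per-cell and per-group morphology
statistics as CSV tables.

## Method

Per cell (manually outlined as a label mask or ImageJ ROI), the pipeline is

1. **Preprocess** — rolling-ball background subtraction (ball radius
   2.5 μm, realised as grayscale opening with a spherical-cap element),
   then Laplacian-of-Gaussian sharpening at scale σ = 1 μm followed by
   CLAHE (tile 2.5 μm), output scaled to [0, 1].
2. **Segment** — automatic threshold by Yen's maximum-correlation
   criterion; 8-connected components; objects smaller than 0.04 μm²
   discarded as noise.
3. **Measure** — per object: area *A* (μm²), aspect ratio *AR* (best-fit
   ellipse), circularity *C* = 4π·*A*/*P*², solidity *S*, minimum Feret
   diameter *MLE* (rotating calipers, μm), and extension
   *E* = the longest shortest-path between endpoints of the object's
   skeleton (μm), plus the equivalent-circle radius r_eq = √(*A*/π).
4. **Classify** — sequential rules, first match wins:
   * **punctum** if round (*C* ≥ 0.8 and *AR* ≤ 2) and r_eq < 0.6 μm;
   * **swollen** if round, compact (*S* ≥ 0.9) and r_eq ≥ 0.6 μm;
   * **filament** if *E* > 11 μm;
   * **rod** otherwise (the intermediate phenotype).
5. **Report** — per-cell class counts and percentages, filament/rod
   (*E*, *A*) records, and per-group means ± sd of the percentages.

A synthetic-scene generator (`mitoshape.synthgen`) renders scenes with
planted tubes and discs, realistic brightness variation, optical blur,
haze and shot noise — with exact ground truth, so the whole pipeline can
be validated without microscopy data.

## Worked example

```python
from mitoshape import SceneSpec, generate_scene, z_project, analyze_cell, \
    evaluate_against_truth

spec = SceneSpec(shape=(512, 512), pixel_size=0.1, seed=42)   # 6/6/6/2 objects
stack, region, truth = generate_scene(spec)
result = analyze_cell(z_project(stack), region)

print(f"objects retained: {len(result.objects)}")
for cls, pct in result.summary.percentages.items():
    print(f"  {cls.value:8s} {result.summary.counts[cls]:2d} objects  {pct:5.1f} %")
comparison = evaluate_against_truth(list(result.objects), list(result.classes), truth)
print(f"recovered fraction: {comparison.diagonal_fraction:.2f}")
```

prints

```
objects retained: 20
  filament  6 objects   30.0 %
  rod       6 objects   30.0 %
  punctum   6 objects   30.0 %
  swollen   2 objects   10.0 %
recovered fraction: 1.00
```

All 20 planted objects are found, the per-cell percentages reproduce the
planted 30/30/30/10 class mix, and every object receives its planted
class (confusion-matrix diagonal = 1.00).

## Command line

```sh
mitoshape simulate --out-dir scene/ --seed 1            # synthetic scene + truth
mitoshape analyze scene/scene.tif --regions scene/scene.cells.tif --out-dir out/
mitoshape batch images/ --out-dir out/ --groups groups.csv
mitoshape evaluate scene/ --out-dir eval/               # score against truth
```

`analyze`/`batch` write `objects.csv` (one row per object), `cells.csv`
(one row per cell) and `groups.csv` (per-group mean ± sd of class
percentages), plus a JSON run manifest recording every parameter used.
All physical-unit parameters (`--pixel-size-um`, `--rolling-ball-um`,
`--log-scale-um`, `--clahe-kernel-um`, `--min-area-um2`,
`--filament-min-extension-um`, `--round-radius-um`) can also be set in a
flat YAML config passed with `--config`; flags override the file.

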