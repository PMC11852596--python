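# colmorph

Single-molecule morphometry of collagen-type filaments in atomic force
microscopy (AFM) height images, for researchers who measure the lengths of
individual biopolymers deposited on mica. The package covers the whole
measurement chain:

1. **Synthetic AFM imaging** (`colmorph.synthetic`) — 2-D worm-like chains
   with known contour length, rendered as tip-broadened, noisy heightmaps,
   optionally as 0°/90° scan pairs, with exact ground-truth centerlines.
2. **Centerline tracing** (`colmorph.centerline`) — robust thresholding,
   connected-component labelling, skeletonisation, branch pruning and
   endpoint ordering, with QC flags (`border_touch`, `branched`, `looped`,
   `too_short`).
3. **Geometric length model** (`colmorph.geometry`) — for the centerline
   point set *D*, the axis-aligned bounding box and the **minimum enclosing
   circle** (MEC) built by farthest-point-first iteration; the MEC diameter
   is the molecule-length proxy. A brute-force oracle cross-checks the
   algorithm.
4. **Population statistics** (`colmorph.morphometry`) — per-molecule MEC
   diameter and arc length, pooled histograms, the distribution mode
   ("length pattern") located as the peak of a Gaussian KDE, in-window
   fractions, and parameter-recovery reports against ground truth.
5. **Plate-assay quantification** (`colmorph.assay`) — cell survival
   100·(ODs−ODb)/(ODc−ODb), melanin/TYR content 100·ODs/mean(ODc), and
   relative gene expression by the Livak 2^(−ΔΔCt) method.

## The length model

A traced molecule is an ordered planar point set
*D* = {(x₁,y₁), …, (xₙ,yₙ)} in nm. Its bounding box is
[min x, max x] × [min y, max y]. Its length is the diameter of the smallest
circle containing *D*, constructed by farthest-point-first iteration: start
from the circle whose diameter is the farthest pair of *D*; while any point
lies outside, add the outside point farthest from the current centre to the
working pool and recompute the smallest circle of the pool; the iteration
terminates at the exact minimum enclosing circle. For the near-straight
collagen monomer (theoretical contour 300 nm) the MEC diameter is
essentially the end-to-end span of the molecule.

## Worked example

```python
from colmorph import (FilamentSpec, ImageSpec, analyze_dataset,
                      collagen_analysis_params, generate_dataset)

dataset = generate_dataset(FilamentSpec(), ImageSpec(), n_images=10, seed=42)
result = analyze_dataset(dataset, params=collagen_analysis_params())
d = result.distribution
print(d.n_molecules, round(d.mode, 1), d.window_fraction)
```

Running `python examples/length_distribution.py` (the same computation)
prints:

```
flag-free molecules:   31 (0 excluded by QC)
length mode (KDE):     299.0 nm   <- the 'length pattern'
mean +/- sd:           300.0 +/- 2.2 nm
fraction in 280-320:   1.00
recovery vs truth:     bias -0.04 nm, RMSE 2.18 nm, match rate 1.00
```

31 molecules were traced without QC flags; the mode of their MEC-diameter
distribution is 299.0 nm, all lengths fall in the 280–320 nm window around
the monomer's theoretical 300 nm contour, and comparing each measurement to
its ground-truth filament shows an essentially unbiased pipeline (−0.04 nm
mean error, ~2 nm RMSE from pixelisation and noise).

The other scripts in `examples/` demonstrate one capability each:
simulating datasets with ground truth, tracing and per-molecule
measurement, the bare MEC geometry with its oracle, and the plate-assay
formulas.

## Notes

- Heightmaps are float nm (TIFF or plain-text matrices) plus a pixel size
  in nm/px; coordinates use pixel centres, origin top-left, y down.
- QC-flagged molecules are excluded from population statistics by default
  and the exclusion count is always reported.
- See `docs/methods.md` for the models, parameter defaults and their
  rationale, numerical choices, and known limitations.
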