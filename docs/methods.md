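# Methods

## Scope and model overview

colmorph measures the lengths of individual filamentous molecules —
prototypically the type I collagen monomer, theoretical contour 300 nm —
in AFM topographs, and validates the whole measurement chain on synthetic
images whose ground truth is known exactly. The package also provides the
small closed-form quantifications used alongside such work in
depigmentation assays (viability, melanin/TYR normalisation, 2^(−ΔΔCt)).

## Worm-like-chain generator

A molecule is sampled as a discrete planar worm-like chain: n =
round(L/Δs) segments of equal length Δs = L/n, with successive turning
angles i.i.d. N(0, Δs/ℓp). Under this convention the tangent correlation
decays as exp(−s/2ℓp), the standard form for a polymer equilibrated in two
dimensions, appropriate for molecules deposited and equilibrated on mica.
The polyline's total length equals the contour length L exactly by
construction, and each chain's polyline, contour length and end-to-end
distance are recorded as ground truth.

Collagen-monomer preset (all values are the package's defaults, chosen
once as typical AFM scales for this molecule):

| parameter | default | why |
|---|---|---|
| contour length L | 300 nm | theoretical monomer contour |
| persistence length ℓp | 6000 nm | near-straight rods, as imaged monomers appear; gives RMS end-to-end ≈ 298.7 nm |
| segment Δs | 3 nm | resolves curvature well below pixel scale |
| filament height | 1.5 nm | apparent monomer height on mica |
| tube radius | 1.5 nm | molecular half-width |
| image | 512 px at 2 nm/px | ~1 µm scan, standard for single molecules |
| tip sigma | 4 nm | Gaussian tip-broadening surrogate |
| noise sigma | 0.1 nm | gas-phase AC-mode height noise |
| margin / separation | 20 px / 30 nm | isolated, uncensored molecules |
| filaments per image | 1–5 | sparse deposition |

Rendering: each chain becomes a half-cylindrical height profile
h·sqrt(1−(d/r)²) of the distance d to the polyline; profiles combine by
pixel-wise maximum over a flat substrate; the field is convolved with an
isotropic Gaussian of sigma `tip_sigma` (tip convolution surrogate); i.i.d.
Gaussian height noise is added last. Heights stay float nm end to end (no
integer quantisation), so threshold-based tests are scale-exact. Placement
is rejection sampling — random rigid motions until the chain respects the
margin and the minimum separation — with 100 retries per filament, after
which the filament is dropped and counted, avoiding unbounded loops on
crowded configurations. With `rotate_pairs` each image is also emitted as
its 90° (counter-clockwise) rotation with transformed ground truth,
emulating repeated scans of the same field at two scan angles.

What the generator does *not* emulate: scanner drift and line artifacts,
non-Gaussian tip shapes and tip-sample dilation, molecule overlap and
aggregation, height-dependent contrast. Tests passing on these images
therefore demonstrate correctness of the tracing and measurement chain
under idealised, isolated-molecule imaging, not robustness to every real
AFM artifact.

## Segmentation and centerline extraction

1. **Denoise**: Gaussian smooth of sigma 1 px. Height noise is white while
   the tip-broadened ridge is several pixels wide, so a light smooth
   suppresses the noise floor with negligible ridge erosion.
2. **Threshold**: default is median + k·(1.4826·MAD) of the smoothed
   field, k = 5. Filaments occupy ~1–3% of pixels, so median and MAD are
   background statistics and the threshold tracks the actual noise level.
   Otsu's method is kept as an option but is not the default: with this
   degree of class imbalance its between-class criterion is maximised by a
   split *inside* the background noise, which floods the labelling. A
   fixed threshold in nm is available for controlled experiments.
3. **Label**: 8-connected components; components below `min_area` (20 px)
   are removed; labels are renumbered by first pixel in raster order so
   labelling is reproducible. Components touching the border are flagged
   `border_touch` (their length would be censored).
4. **Skeletonise and prune**: standard thinning, then iterative removal of
   leaf branches shorter than `prune_length` (5 px). The skeleton adjacency
   graph omits diagonal links that shortcut a 4-connected corner, so a
   simple bent path is a path graph and not a chain of 3-cycles.
5. **Order and flag**: a simple open path is ordered endpoint to endpoint
   (Dijkstra between its two leaves, diagonal steps weighted √2). Remaining
   junctions flag `branched`, remaining cycles flag `looped`; in either
   case the longest leaf-to-leaf path is returned. Skeletons shorter than
   `min_centerline_points` flag `too_short`.
6. **Extend ends** (default on): thinning retracts the ends of a blunt rod
   by roughly half its ridge width, a systematic ~1–2 px/end shortening;
   each end is therefore extended pixel by pixel along the local tangent
   while still inside the component mask.

Coordinates are pixel-centre, origin at the image top-left, x rightward, y
downward; all outputs are nm. No subpixel spline smoothing is applied by
default, keeping pixel-metric tests exact.

`collagen_analysis_params()` is the profile used for monomer studies: the
defaults with `min_centerline_points` = 75 (≈150 nm at 2 nm/px, half the
expected contour). Besides rejecting debris, this makes degradation
monotone: a molecule whose ridge breaks in two under heavy noise can
contribute at most one accepted piece, so added noise can only reduce the
number of clean molecules.

## Minimum enclosing circle

For the centerline point set D the farthest pair is found by O(n²) brute
force (traces have at most a few hundred points; no convex-hull
optimisation is warranted). The initial circle has that pair as diameter.
While any point lies outside by more than eps (default 1e-9 of the
farthest-pair distance), the outside point farthest from the centre joins
a working pool, and the smallest circle enclosing the pool is recomputed
exactly (enumerating 2-support diameter circles and 3-support
circumcircles, where the smallest circle of an obtuse triple is its
longest-side diameter circle). Because the pool only grows and the
smallest circle of any subset cannot exceed that of D, the iteration
terminates at the exact MEC, with at most three support points on the
circle. Ties in the farthest outside point resolve to the lowest index;
triples whose circumcircle determinant falls below 1e-12 of the squared
span are treated as collinear and fall back to 2-support. A fully
independent O(n⁴) oracle (`mec_oracle`) enumerates every candidate circle
and is used throughout the tests as the correctness reference; Welzl's
randomised algorithm is deliberately not used, keeping the implementation
the iterative construction it models.

## Measurement and statistics

Per molecule: MEC diameter (headline length by default), centerline arc
length, bounding box, point count, QC flags. QC-flagged traces are refused
unless explicitly overridden and are excluded from population statistics;
the exclusion count is always reported. The arc length of an 8-connected
pixel path systematically exceeds the true contour for oblique molecules
(staircase metric, up to ~8%), which is the package's reason for defaulting
to the MEC diameter; both are always reported.

Population statistics: histogram with 10 nm bins anchored at 0; the
distribution mode ("length pattern") is the argmax of a Gaussian KDE with
Silverman bandwidth evaluated on a 4096-point grid — robust to bin
anchoring, unlike a histogram argmax; the window fraction is the share of
lengths inside [280, 320] nm by default. Recovery reports match
measurements to ground-truth filaments per image by smallest mean
centerline-to-polyline distance (greedy, 20 nm acceptance radius) and give
bias, RMSE and match rate of measured minus true contour length.

## Plate-assay formulas

- Cell survival (%) = 100·(ODs − ODb)/(ODc − ODb), CCK-8 at 450 nm.
- Melanin content (%) = 100·ODs/mean(OD of control group), 405 nm; the
  identical ratio-to-control-mean serves relative TYR activity from
  DOPA-oxidation absorbance, which has no separate printed formula.
- Relative expression = 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference per
  condition and ΔΔCt = ΔCt_treated − ΔCt_control (Livak). The negative
  exponent is the convention under which a later-amplifying treated target
  (higher Ct, less transcript) yields a fold change below 1; replicate Ct
  values are averaged per condition and gene. Replicate dispersion is
  summarised as mean ± SEM; no hypothesis testing is included.

## Validation study sizes

The end-to-end validation generates 50 preset images plus their 90°
partners (100 scans, ~300 molecules) at seed 42 — comfortably more than
the smallest population for which the KDE mode is stable — and asserts
mode recovery within ±5% of the generative 300 nm contour, a ≥60% fraction
in [280, 320] nm, and 0°/90° length agreement within 2 px for ≥95% of
molecule pairs. Geometry is validated on 1000 seeded random point sets
(n ∈ [3, 25], coordinates uniform on [0, 100]²) against the brute-force
oracle at 1e-9.

## Known limitations

- Tracing assumes isolated, non-overlapping, open filaments; crossing or
  touching molecules are flagged and excluded rather than disentangled.
- No tip-shape deconvolution, drift correction or height-weighted (ridge-
  following) tracing.
- The MEC diameter under-reports the contour of visibly curved molecules
  (it measures span, not path); for the near-straight monomer regime the
  difference is within a few nm.
- Arc length inherits the pixel staircase metric; subpixel smoothing is
  deliberately left out of the defaults.
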