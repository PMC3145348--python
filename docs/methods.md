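# Methods

This note documents the models, algorithms, defaults and design choices
behind `assayscreen`, and what the synthetic benchmarks do and do not
demonstrate about real microscopy data.

## Intensity model and conventions

Images are 8- or 16-bit single-plane grayscale; pixel values are divided by
the dtype maximum (255 or 65535) — never by the observed maximum — so all
rasters live on a common [0, 1] scale and intensity features are comparable
across images and bit depths. Coordinates are 0-based, row-major
(row, col). Objects are 4-connected by default; 0 is background and labels
are kept consecutive 1..n.

Control labels in the plate map are matched case-insensitively against an
alias map (`positive ← {positive, pos, p}`, `negative ← {negative, neg,
n}`, anything else → sample). Control wells without a dose default to dose
0 (negative) or the maximum observed dose (positive), flagged on the
record, so dose-series grouping always has endpoints.

## Illumination correction

All images of a channel are averaged and the average is smoothed with a
large square median filter (default 151 px — large enough that individual
cells vanish and only slow shading survives; an odd size keeps the window
centered). The smoothed surface is floored at 1e-6 and normalized to
**mean 1**, and every raw image is divided by it. Mean-1 normalization
(rather than min-1) keeps corrected intensities on the original scale on
average; note this means pixels in dim regions are boosted above their raw
values and bright-region pixels are attenuated. Values above 1 after
division are clipped, with a logged warning when more than 1% of pixels
clip.

Numerical details: averaging uses a per-pixel sort before summation so the
estimate is exactly invariant to the order of the input image list; for
windows larger than 31 px the median runs as a histogram rank filter on a
12-bit quantization of the image (error ≤ 1 gray level of the image's
range, orders of magnitude below shading amplitudes). Median-filter border
bias under reflect padding is accepted; accuracy statements are made for
the central 80% of the field.

## Segmentation and compartments

**Nuclei** — Gaussian pre-smooth (default σ = 1 px), global Otsu threshold
(optionally on log-intensities), hole filling, size filter (default
40–5000 px²), removal of border-touching objects (their compartments would
be truncated and bias intensity features), and optional declumping:
watershed on the negated Euclidean distance transform, seeded at maxima of
the lightly smoothed (σ = 1.5) distance transform with minimum separation
√(min_area)/2. The smoothing prevents a single convex object's EDT ridge
plateau from seeding multiple fragments. An all-background field yields
zero objects, not an error.

**Dilated nucleus / cytoplasm ring** — each nucleus grows to all pixels
within a Euclidean distance d (defaults d ∈ {5, 10, 15} px screened in
parallel, each its own feature namespace); contested pixels go to the
nearest nucleus with exact ties awarded to the lower label (enforced by a
per-label EDT sweep in increasing label order). The ring is the dilated
compartment minus the nucleus; labels are preserved everywhere, so
compartment k always derives from nucleus k and per-cell ratios join by
label.

**Cell** — nuclei propagate through the green-marker foreground
(`green ≥ threshold`, default threshold Otsu of the corrected green image)
along discrete geodesics whose per-unit-length cost is
√(λ + |∇green|²): λ → ∞ reduces to nearest-seed (pure path length), small
λ makes boundaries hug intensity edges. Default λ = 0.05. The cost front is
computed with an 8-connected minimum-cost-path search; labels are assigned
by walking pixels in order of increasing arrival cost and copying the
predecessor's label, so the result matches a multi-source Dijkstra with
edge weight `dist(p,q) · (cost(p)+cost(q))/2` (verified against a
brute-force Dijkstra in the tests). Foreground unreachable from any seed
stays background.

**Speckles** — white top-hat (image minus opening with a disk, default
radius 5 px) enhances bright structures smaller than the element; an Otsu
threshold is then computed *per parent object* from the enhanced pixels
inside that parent (falling back to the global threshold for parents under
64 px or zero variance), making detection robust to per-cell background
differences. Because Otsu always splits its input, a parent containing no
true spots would otherwise get a noise-level threshold; an absolute floor
(`min_threshold`, pipeline default 0.1) keeps spot-free cells clean.
Components outside [min_area, max_area] (defaults 2–200 px²) are dropped
and survivors map to the parent with the largest pixel overlap (ties to
the lower label).

## The feature library

Per compartment (Nucleus, Dilated/Ring at each dilation, Cell) and channel:

* **Intensity** (12): Integrated, Mean, Median, Std (ddof = 1; defined 0
  for single-pixel objects), Max, Min, MAD, and edge statistics
  (IntegratedEdge, MeanEdge, StdEdge, MaxEdge, MinEdge) over the object's
  internal boundary — pixels with an 8-neighbor outside the object.
* **Shape** (7, channel-independent): Area, Perimeter (weighted chain-code
  estimate, as in scikit-image's `regionprops`), FormFactor
  = 4π·Area/Perimeter², Eccentricity, Solidity, Extent,
  EquivalentDiameter.
* **Texture** (13 × offsets {1, 3, 5} px): the 13 Haralick statistics of a
  symmetric, normalized gray-level co-occurrence matrix pooled over the
  four direction offsets at each distance, restricted to pixel pairs both
  inside the object. Pixels are quantized to 8 equal-width levels over the
  *object's own* min–max range, which makes texture invariant to intensity
  scaling (an illumination-robustness trade-off: it also discards absolute
  contrast). Entropies are in bits; Variance centers on the marginal mean;
  SumVariance centers on SumAverage (the literature's erratum of centering
  on SumEntropy is not followed); Correlation is missing when a marginal
  variance vanishes. Objects with zero intensity range or fewer than 4
  pairs are missing.
* **Correlation** (3): Pearson correlation of the two channels over the
  object's pixels, the least-squares slope of one on the other, and the
  Manders-style overlap coefficient; also computed image-wide.
* **Radial distribution** (3 × 4 annuli): each pixel's distance from the
  object centroid is normalized by the maximum in-object distance along its
  angular ray (rays discretized into 36 sectors, values clamped to [0, 1])
  and binned into 4 annuli. FracAtD is the annulus' share of total object
  intensity; MeanFrac divides that by the annulus' pixel share (1
  everywhere for a uniform object); RadialCV is the coefficient of
  variation of per-wedge intensity sums across 8 angular wedges. The
  geometry uses the object's own centroid and boundary — no membrane
  marker is assumed. On a pixel grid RadialCV is only approximately 0 for
  radially uniform objects (wedge populations differ by a few pixels).
* **Counts**: speckles per parent cell and per image.

With the default configuration this yields ~1100 distinct per-cell
features; a single 256² synthetic image measures in roughly a second.

**Derived features** enter the same namespace and are screened
identically: per-cell ratios (default: ring/nucleus mean green intensity
per dilation — cytoplasm over nucleus, so translocation *into* the nucleus
*decreases* the ratio) and per-image classified fractions (share of cells
whose value strictly exceeds a threshold; ties fall below; defaults
{0.5, 1, 2} per ratio, screened in parallel). Per-image aggregation
records the mean and median of every per-cell feature over non-missing
objects, plus object counts.

## Screening

Z′ uses sample SDs and is invalid (missing, never −∞) when the control
means coincide; V uses the mean within-dose-group SD over the extreme-dose
mean range, reducing exactly to Z′ at two groups. A
dose-response-curve-fit variant of V (pooled residual SD around a fitted
4-parameter logistic) is available as `vfactor_fit_residual` but is not
the default ranking statistic — curve fits can fail to converge on
pathological features, and the per-group form has no such edge cases.

The ranking statistic defaults to V when ≥ 3 dose groups exist, else Z′;
both are always reported. Bands follow the conventional cutoffs (> 0.5
excellent, > 0 screenable); constant or all-missing features are invalid
and rank last; ties break deterministically by feature name. Finite scores
below −10 are flagged for suppression in plots.

Because selecting the best of ~2000 features on the same controls is a
multiple-comparisons trap, `split_validate` splits the controls by a
seeded stratified draw, ranks features on the training half, and reports
the top features' Z′ on the held-out half. The tests confirm the expected
regression-to-the-mean on noise-only feature tables.

## Synthetic data

The generator renders elliptical nuclei (non-overlapping, rejection
sampled, ≤ 1000 attempts) inside circular cells on a 256² field (~30
cells/image by Poisson draw). Dose maps to effect e through a Hill curve
(EC50 0.05, slope 2, plateau 0.9); negative controls sit at dose 0,
positives at the top dose.

* **Translocation**: cytoplasm green = baseline + (1−e)·c, nucleus green
  = n + e·(c−n+Δ), defaults c = 0.40, n = 0.08, baseline = 0, Δ = 0.1 —
  at zero effect the nucleus:cytoplasm ratio is exactly n/c; at full
  effect the contrast inverts.
* **Speckle**: diffuse cytoplasm level 0.15 plus K ~ Poisson(8·e)
  Gaussian spots per cell (σ = 1.5 px, amplitude 0.5, centers ≥ 6σ apart,
  truncated at 3σ), K recorded as truth.

Renders are corrupted by a low-order multiplicative shading surface
(default amplitude 0.2–0.3 — strong enough that uncorrected intensity
features degrade measurably) and Gaussian read noise (default SD 0.01),
then quantized to 16-bit TIFF. All randomness flows from one seed;
identical parameters give byte-identical files.

Deliberate simplifications: no photobleaching, no cell-cycle intensity
heterogeneity, no confluency confounds, hard-edged cells, spatially white
noise. Passing tests therefore demonstrate the *mechanics* of the pipeline
(compartment geometry, statistic computation, threshold logic, end-to-end
feature selection) and its statistical behavior under controlled
contrasts — not robustness to the texture, debris and focus variation of
real micrographs.

Verification ties measurements to generator truth: on noise-free,
shading-free renders the measured nucleus and ring mean intensities equal
the generated levels to within 16-bit quantization (segmentation with
declumping and smoothing off recovers the rendered ellipses exactly, and
cells are sized so the 5 px ring stays inside the uniform cytoplasm), and
detected speckle counts equal the planted counts exactly. The end-to-end
acceptance screens use 8 images per dose group, 2 dose groups, ~30
cells/image, noise SD 0.005 — small enough to run in well under a minute
per assay, large enough that the designed readout separates controls
decisively.

## Known limitations

* The propagation algorithm assumes the green marker fills the cell; on
  images where positive controls extinguish cytoplasmic signal the Cell
  compartment can collapse toward the nuclei (the dilated-nucleus
  compartments are the robust fallback, which is why both are screened).
* Per-object min–max texture quantization makes texture features
  incomparable between objects in absolute contrast terms.
* Radial statistics on small objects (≲ 50 px) are noisy: annuli near the
  centroid hold few pixels.
* Z′/V assume roughly symmetric, unimodal group distributions; heavy
  tails deflate both statistics.
* The V factor's dose grouping uses exact dose equality; doses should be
  recorded consistently in the plate map.
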