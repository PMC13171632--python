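# Methods

This note documents the models behind each analysis stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the
problem was genuinely open.

## Data model and conventions

Coordinates are micrometres, origin at the image top-left, y increasing
downward (the raster convention of the microscope images); all
distances are Euclidean. Low-resolution array spots are treated as
points at their centres. Square binning uses half-open intervals
[k·s, (k+1)·s) so each molecule lands in exactly one bin and totals are
conserved in integer arithmetic. Rank aggregation pools taxa that are
unannotated at the requested rank (e.g. reads classified at internal
taxonomy nodes) into a single `unresolved@rank` bucket, again
conserving totals exactly.

The observation-window area A used by Ripley statistics defaults to
the convex hull of the annotated (tissue + lumen) spots; it is
overridable because the delimitation of A is a free choice that scales
K(r) linearly. Rectangular windows are used for simulated point
patterns.

## Demultiplexing and contaminant filtering

A unique molecule is a distinct (barcode, UMI, taxid) triple among
classified reads. No error-tolerant UMI merging is attempted: collapse
is exact string/IDs equality. Unclassified reads and reads with
barcodes outside the section are dropped (the latter with a logged
count); a stream with more than 1% malformed records is rejected rather
than silently cleaned.

The sterile-control filter excludes taxa whose control frequency
reaches `threshold_ppm` (default 1) unique molecules per million. The
inclusive comparison (≥) is the stricter of the two natural readings
and is exposed as a flag. When a taxonomy table is supplied to the
demultiplexer, its full taxid set defines the feature axis, so matrices
from the same taxonomy are always column-aligned.

## Enrichment

Microbial percentage per superkingdom k is
100·UMI_k/(host + all classified UMI); the enrichment fold is the
ratio of percentages between the paired libraries. With host capture
unchanged and bacterial thinning t relating the standard library to the
polyadenylated one, the attainable fold is analytically
(H + tB)/(H + B) · 1/t — it approaches 1/t only when host molecules
dominate (H ≫ B), which is the regime of the generator defaults
(H = 5×10⁶ vs B ≈ 1.2×10⁵ in the enrichment recovery conditions).
A fold is reported as undefined when the standard library has no signal
for a superkingdom.

## Composition

Relative abundance divides each taxon's unique molecules by the total
bacterial molecules (fractions sum to 1 at any rank). Per-spot richness
counts taxa present after removing taxa at ≤ 0.01% of the whole-sample
total — the filter is applied sample-wide before per-spot counting, so
richness is monotone under further taxon exclusion.

The transverse profile orders spots by minimum Euclidean distance to a
reference region and cuts the observed range into equal-width bins
(five by default; equal-width matches the "spot-distance bins" reading,
quantile bins are available). Per-bin percentages are z-scored per
taxon across bins with population SD; taxa with zero across-bin
variance get z = 0, so z-columns always sum to zero. The reference
region defaults to the lumen (the low-resolution convention, where
microbial signal spreads into tissue-covered spots). On synthetic
sections the microbes sit strictly on the lumen side, where the
distance-to-lumen axis is degenerate, so the pipeline profiles against
distance to tissue instead; both axes are one call-site argument apart.

Splice outliers: per coding gene, the residual is the signed
perpendicular distance from (spliced, unspliced) totals to the y = x
diagonal, (u − s)/√2; genes with |residual| > 5 population SDs are
flagged. Perpendicular distance is the literal geometric reading of
"distance from y = x"; population SD (ddof = 0) is the default and is
configurable.

## Saturation

Reads are subsampled by independent per-read Bernoulli thinning at each
fraction (10%…100%), and unique molecules are re-deduplicated at each
level with the same triple rule. Bernoulli thinning (rather than exact
hypergeometric) matches fraction semantics at scale and keeps every
level independent of the others given the seed.

Saturation = 1 − unique/reads is fitted with Michaelis–Menten
y = v_max·x/(k + x) by bounded nonlinear least squares
(`scipy.optimize.curve_fit`), v_max ∈ (0, 1] on the saturation scale
(unbounded for unique-molecules-vs-depth fits unless a feature-space
size is supplied). Initialisation is the standard heuristic
v_max₀ = max(y), k₀ = first depth reaching half of max(y). R² is
1 − RSS/TSS; a zero-variance response reports R² = 1 when the fit
interpolates (RSS ≈ 0) and 0 otherwise. The depth to a target
saturation is the closed form x = k·target/(v_max − target), reported
as unreachable (∞) when target ≥ v_max.

## Spatial statistics

**Moran's I** uses row-standardized k-nearest-neighbour weights
(k = 4), distance ties broken by spot index so lattices are
deterministic. Significance is a one-sided (greater) permutation test
with the +1 correction; the permutation stream is seeded.

**Ripley K/L/H** is the unadjusted estimator printed above — no edge
correction, exactly as defined. The omission biases K downward at radii
comparable to the window size; interpret H well below the window
extent (an optional guard band shrinks the window). The z-score
reference is CSR Monte-Carlo with matched N in the same window
(n_sim = 199 default, seeded); radii where the simulated SD is zero are
masked. When many patterns share N and window (calibration sweeps), a
precomputed null is reused — identical definition, O(n_sim + patterns)
cost.

**Colony radius** is the argmax of H(r). For a Thomas process with
Gaussian dispersion σ this argmax is a cluster-*scale* proxy, not an
estimate of σ: in the high-overlap limit it converges to ≈ 2.24σ
(maximising (1 − e^{−r²/4σ²})/r) and grows toward ≈ 3σ at low parent
intensity. Relative ordering across genera is therefore meaningful and
is what the recovery tests score; absolute values should be read as
aggregation scales. The first-zero-crossing-after-max alternative is
exposed as an option.

**Colony calling** fits HDBSCAN (Euclidean, scikit-learn
implementation) over a grid of min_cluster_size × min_samples, removes
noise points and clusters smaller than min_cluster_size, and scores the
retained points with the silhouette; the chosen setting maximises the
silhouette, ties resolved toward smaller min_cluster_size then smaller
min_samples. Inputs where no setting yields ≥ 2 clusters are flagged
"no colony structure" rather than rejected.

**Colocalization** rasterizes genus counts onto square bins, convolves
with an isotropic Gaussian (σ = 20 µm default, converted to bin units),
and computes Pearson correlations over bins containing annotated
spots. Smoothing correlates neighbouring bins, so the null spread of r
is set by the effective (not nominal) number of independent bins —
null checks are calibrated accordingly. Zero-variance surfaces are
masked (NaN). Correlations are computed on smoothed counts; a log1p
option is available.

**Species–area curve**: for each area in a log-spaced grid
(16 µm²–0.16 mm² by default), unique genus marks are counted in square
quadrats and averaged. Quadrats of different areas are nested
(concentric around shared uniformly-placed anchors, 100 per area by
default), which makes each replicate's count — hence the mean curve —
monotone non-decreasing in area by construction. The exponent is the
least-squares slope of log₁₀(mean genera) on log₁₀(area).

## Boundary geometry

Images are smoothed with a box average whose kernel is specified in µm
and rounded to the nearest odd pixel count (100 µm default), binarized
at an 8-bit threshold (80 for normal, 100 for tumour-laden tissue as
working defaults for the kind of images emulated here — no claim they
generalize), and contours of the foreground mask are traced
(sub-pixel marching squares). Contour runs lying on the image frame
are trimmed by default: a mask clipped by the field of view otherwise
contributes frame segments that are not tissue boundary. Thresholding
a blurred step shifts the traced edge by up to
(0.5 − threshold/255)·kernel from the true interface, so fidelity is
bounded by one kernel width, not one pixel.

Entity distances are exact point-to-segment distances to the traced
polylines (shapely). Density profiles use a Gaussian KDE with Silverman
bandwidth, renormalized on the evaluation grid so the density
integrates to 1 there; a degenerate sample collapses to a point mass.
Genus distance profiles share bin edges across conditions so normal and
tumour-laden profiles are directly comparable.

Cell-position rescaling between sections maps distances x → a·x + b
using a reference cell type (e.g. mature enterocytes): the default
matches medians with b = 0 (pure scaling, since both sections measure
distance from their own boundary where x = 0 is anchored); an affine
mode matching the 25th/75th percentiles is available.

## The synthetic-data generator

The generator emulates what the analyses assume and records everything
it draws in a `GroundTruth`:

- a rectangular section split by a known boundary (line, sinusoid or
  disc), spots on a square lattice (50 µm pitch default) labelled
  tissue/lumen by side;
- per-genus point processes on the lumen side: homogeneous Poisson for
  dispersed taxa and Thomas cluster processes (Poisson parents,
  Poisson(µ) offspring, Gaussian dispersion σ) for colony formers —
  Thomas σ is exactly the dispersion quantity the Ripley analysis
  probes. Defaults mirror the observed colony-size classes: σ = 5 µm
  (small, Lactobacillus-like), 10 µm (medium, Turicimonas-like), 30 µm
  (large, Clostridium-like), plus a dispersed CSR genus and a
  lumen-gradient genus;
- exponential transverse gradients (thinning with distance from the
  boundary, decay length in µm) — monotone and single-parameter;
- read records with 30% UMI duplication by default (per-molecule read
  count 1 + Poisson(d/(1−d))) and 10% unclassified reads, constructed
  so that demultiplexing the records reproduces the taxon matrix
  exactly for every seed;
- a paired "standard" library by per-superkingdom binomial thinning of
  the same unique molecules (bacteria 0.01 default, i.e. the ~100-fold
  regime);
- a host matrix (~2×10⁵ molecules default) with two zonation groups
  (boundary-proximal and crypt-like exponential intensity profiles),
  a biotype mix (8% non-coding) and a 22.5% unspliced fraction applied
  binomially per gene;
- an 8-bit greyscale image of the tissue mask at 2 µm/pixel with
  optional salt-and-pepper noise.

For the species–area analyses, a separate community generator places
independent CSR genera with intensities at quantiles of a truncated
Pareto tail P(λ > x) = (λ_min/x)^z; since the expected genus count in
area a is Σ(1 − e^{−λa}), this yields E[S(a)] ∝ a^z over the span where
1/a lies inside the intensity support. λ_min is solved deterministically
(Brent root-finding on the analytic curve) so the analytic log–log
slope equals the configured target — a closed-form calibration fixed at
construction time.

What the generator does **not** emulate: read sequences and error
models, classifier mistakes beyond a configurable contaminant list,
spot-size convolution (molecules are assigned to nearest spot centres),
diffusion of luminal RNA into tissue, realistic taxonomies, host
biology beyond two zonation groups, or platform-specific artefacts.
Passing recovery tests therefore demonstrates correctness of the
statistics under their stated assumptions, not robustness to the full
messiness of real libraries.

## Problem sizes

The test-suite and acceptance-script simulations are sized for quick,
well-powered checks: sections of 500–1000 µm with 100–400 spots,
10³–10⁵ microbial molecules, 200 CSR patterns of N = 500 against a
shared 199-simulation null, 100 replicate triples for colony-radius
ordering, 100 noisy Michaelis–Menten replicates, and a 250-genus
species–area community (~1.5×10⁴ points). Each statistic's runtime is
seconds at these sizes and scales as documented (Ripley O(N²) in
points, Moran permutations O(n_perm·n·k)).

## Known limitations

- The unadjusted Ripley estimator is negatively biased near the window
  scale; no inhomogeneous-intensity variant is provided.
- The colony radius is an aggregation scale (≥ 2.24σ for Thomas
  processes), not σ; compare genera, do not read it as a physical
  colony diameter.
- Moran's I uses kNN weights only (k configurable); no
  distance-band or contiguity weights.
- The boundary tracer assumes a bright-tissue/dark-lumen greyscale
  convention and a single global threshold.
- The ppm contaminant filter is frequency-based only; it does not model
  classifier false-positive structure.
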