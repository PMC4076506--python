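# Methods

This note records the conventions, parameter choices and numerical details
behind `ordviz`, and what the synthetic-data generator does and does not
emulate.

## Input dialects

The coordinates parser accepts the QIIME 1 principal-coordinates layout: an
optional header line beginning `pc vector number`, one tab-separated row per
sample (ID + d reals), an optional blank line, an `eigvals` row and a
`% variation explained` row. Files are UTF-8 with LF or CRLF endings.
Mapping files are tab-separated with a `#SampleID` header; later lines
starting `#` are comments. Empty or absent metadata cells become the token
`Unknown`, chosen because it is unambiguous in categorical legends. A
column is treated as numeric iff every non-`Unknown` cell parses as a
decimal number; `Unknown` cells are excluded from gradient mapping (they
get a fixed gray, RGB (64,64,64)) and are an error where a value is
mandatory (explicit axes, trajectories). Taxa tables are the classic
taxa-summary TSV: a header row (taxon-column title + sample IDs) and one row
of non-negative abundances per taxon; abundances are converted to
per-sample relative abundances before any geometry (the weighted-average
biplot should reflect composition, not sequencing depth), with all-zero
sample columns left at zero rather than divided.

Samples present in the metadata but absent from the coordinates are
silently dropped — they carry no geometry. The reverse direction is
controlled by the overlap policy: `strict` (default) fails listing the
missing IDs, `ignore_missing` subsets both inputs to the intersection while
preserving the ordination's sample order.

## Geometry

* **Variance scaling** multiplies axis *j* by
  `pct_explained[j] / pct_explained[0]`; the first column is copied
  bit-exactly. It is undefined when the first axis explains 0%.
* **Explicit axes**: value v_i of a numeric column is mapped to
  `(v_i − min)/(max − min) × R` with R the range of PC1, keeping the
  display axis commensurate with ordination units. The new axis is
  prepended with eigenvalue 0 and 0% variance. A zero-range column is an
  error.
* **Parallel coordinates** min-max normalize each of the first `n_axes`
  axes to [0,1] independently; a zero-range axis maps every sample to 0.5
  so polylines stay connected (avoids NaN).
* **Trajectories** group samples by a categorical column and sort each
  group by ascending gradient value, ties broken lexicographically on
  sample ID so output is reproducible. Singleton groups yield degenerate
  one-point trajectories.
* **Biplots** rank taxa by total relative-abundance mass over the retained
  samples (ties broken by taxon ID), keep the top N (default 10), and place
  each kept taxon at its abundance-weighted mean sample position. Zero-mass
  taxa are never kept. The displayed weight is the taxon's mass divided by
  the mass of *all* taxa, so weights over kept taxa sum to at most 1.
  Covariance/correlation-style loading arrows are out of scope — these
  biplots are weighted-average points.
* **Axis flips** negate selected (1-based) axes; PCoA axis signs are
  arbitrary, so this is a pure display operation that preserves all
  pairwise distances.

## Procrustes convention

Both configurations are centered at their centroids and scaled to unit
Frobenius norm; the optimal rotation is `R = U Vᵀ` from the SVD
`Y₀ᵀX₀ = U S Vᵀ`, and the query is additionally rescaled by the
least-squares factor Σᵢ σᵢ. The misfit is the residual sum of squares,
analytically `M² = 1 − (Σᵢ σᵢ)²`, which is the disparity of
`scipy.spatial.procrustes` and the symmetric procrustes statistic of the
ordination literature; it is 0 iff the configurations are
similarity-equivalent and at most 1. With reflections forbidden, the
smallest singular direction's sign is flipped whenever the unconstrained
optimum has determinant −1 (reflections are *allowed* by default because
PCoA axis orientations are arbitrary). Aligned coordinates are reported in
the reference's original frame (`transformed_query × scale_ref +
translation_ref`) so that consensus positions stay in data units.

The test suite checks this route two independent ways: a brute-force grid
search over rotation angle (step 1e-5, with and without reflection) on 2-D
configurations, and scipy's disparity on higher-dimensional ones.

## Jackknife aggregation

Replicates are subset to their common sample IDs, zero-padded to the
largest axis count (an isometry), and aligned onto the first replicate (the
master; at the CLI, the lexicographically first `*.txt` in the replicate
directory). Radii are per-sample per-axis sample standard deviations
(ddof 1) by default, or half the interquartile range with `iqr`; both are
legitimate spread summaries and the default is simply documented rather
than claimed canonical. A single replicate yields zero radii with a
warning. Because alignment itself absorbs a translation, a rotation and a
scale, radii are biased slightly low at small n·d — about √(1 − p/(n·d))
with p = d(d−1)/2 + d + 1 fitted parameters — which is why recovery tests
use n = 60, d = 3, k = 200, where the effect is ~2%.

## Bundle format and size

The bundle (schema in `docs/bundle-schema.md`, version field `"1"`) stores
coordinates once in the points section; metadata is stored column-wise, and
any column whose dictionary encoding (level list + bit-packed base64
indices, ≤ 64 levels) is smaller than the plain value list is stored that
way. All reals are rounded to a fixed number of decimals (default 5,
`--precision` to override; rounded zeros are normalized to `0.0` so output
is byte-stable). Styles are self-describing — a categorical style lists its
per-category RGB entries, a gradient style embeds the colormap stops and
the observed min/max — and are emitted only when requested, so bundle size
is a function of (n, d, m) alone. Trajectories reference sample IDs rather
than repeating coordinates; comparison edges and biplot points carry their
own geometry because those positions exist nowhere else.

Colormap interpolation is piecewise-linear per channel with rounding half
away from zero, making color assignments bit-identical across platforms.
Built-in maps (`blue-red`, `spectral`) and the 24-color categorical palette
are explicit numeric constants; users can load additional ones from a small
plain-text config.

The HTML writer emits one self-contained page that embeds the bundle JSON
verbatim in a script block with id `ordviz-bundle` (the documented
extraction marker) and renders a static per-axis summary table with inline
JavaScript; no external resources are referenced. Metadata values
containing the literal string `</script>` would truncate the embedded
block and are not escaped — a known limitation.

Bundle assembly order: axis flips first; replicate alignment (jackknife or
comparison) on the pure ordination; explicit axes prepended next (so
trajectories and biplot projections see them — a taxon's explicit-axis
coordinate is the abundance-weighted mean of its samples' values); axis
truncation last, applied to points and geometric decorations alike. The
default emitted axis count is min(d, 10): viewers pick 3 at a time, and
shipping extra axes costs little. Explicit axes cannot be combined with
jackknife/comparison modes because partner ordinations carry no metadata
axis.

## Synthetic data

`FixtureSpec` defaults define the study-like conditions used throughout the
tests: 4 clusters (body-habitat analogues) with centroids of magnitude ~2
in the leading axes and isotropic Gaussian spread 0.35 (clear but
overlapping separation), a continuous `Age` gradient spanning 0.5–33
(infant-to-adult years), 12 metadata columns, and 24 taxa of which one per
cluster is cluster-exclusive, one per cluster is 10× enriched, and the rest
are uniform background with one ubiquitous taxon guaranteeing positive
sample totals. Filler metadata columns are low-cardinality categorical
(2–6 levels, binary-heavy), matching the composition of real mapping files.
Axis variances are sorted so eigenvalues decrease and percentages sum to
100. The full-scale demonstration merge uses four cohorts of 1964, 585,
3131 and 60 samples (two-subject multi-site time series, adult
body-habitat survey, healthy-cohort survey, infant gut time series).

One integer seed drives everything through a fixed `SeedSequence` spawn
order (coordinates, mapping, taxa), so any subset of outputs is
reproducible bit-for-bit. Replicate jitter is isotropic Gaussian per
coordinate followed by a uniformly random proper rotation — the simplest
model under which the jackknife estimator's recovery can be judged against
a known σ.

The generator does **not** emulate count compositionality, zero inflation,
rarefaction mechanics, or arch/horseshoe artifacts of real PCoA embeddings;
passing tests demonstrate correctness of the geometry, alignment,
aggregation and serialization machinery on clustered Gaussian data, not
robustness to those phenomena.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 20 random
configurations for the grid-search oracle (n = 10, d = 2, step 1e-5), 100
similarity trials, k = 200 jackknife replicates at σ = 0.05, n = 500
samples × 10 axes for the size-growth measurement, 1000 format round-trip
cases, and one full-scale 5740-sample merge. The whole suite completes in a
few seconds.
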