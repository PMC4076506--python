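# ordviz

Compact, self-contained visualization bundles for 3D ordinations of
microbial community data.

## The problem

Beta-diversity analyses summarize the compositional differences between
microbial communities as a distance matrix, which Principal Coordinates
Analysis (PCoA) embeds into a handful of Euclidean axes ordered by the
fraction of variance each explains. Exploring such an ordination is only
useful together with its sample metadata — body site, subject, age, pH,
time point — and studies now routinely combine thousands of samples with a
hundred or more metadata columns. Tools that bake one static file per
metadata category replicate the coordinates over and over, producing
gigabyte-scale output for what is fundamentally a single point cloud.

`ordviz` reads QIIME-dialect principal-coordinates files and tab-delimited
mapping files and emits one small JSON document (plus a self-contained HTML
page embedding it) in which the coordinates appear exactly once, no matter
how many metadata columns exist or how a viewer later groups them. On top
of the basic point cloud it computes the standard decorations of the field:

* **explicit metadata axes** — a continuous variable (age, time, pH) is
  min-max rescaled to the range of PC1 and prepended as a display axis;
* **gradient trajectories** — each subject's/site's samples connected in
  ascending order of a numeric column;
* **weighted-average biplots** — taxon *t* is placed at
  x_t = Σ_s a_ts · x_s / Σ_s a_ts, where a_ts is its relative abundance in
  sample *s*, so every taxon sphere lies in the convex hull of the samples
  containing it; sphere weight is the taxon's share of total abundance mass;
* **procrustes comparison** — a partner ordination is optimally
  superimposed (translation, uniform scale, orthogonal rotation via SVD;
  reflections allowed by default since PCoA axis signs are arbitrary), with
  misfit M² = 1 − (Σᵢ σᵢ)² where σᵢ are the singular values of the
  cross-product of the unit-norm centered configurations;
* **jackknifed confidence regions** — rarefaction replicates are aligned
  onto a master replicate by procrustes and summarized per sample as a
  consensus position plus per-axis radii (sample standard deviation or half
  the interquartile range);
* **metadata-driven styling** — categorical palette assignment in
  first-appearance order, piecewise-linear gradient colormaps, and
  per-category size/opacity/visibility overrides.

A seeded fixture module (`ordviz.fixtures`) generates realistic clustered
ordinations, mapping files, taxa tables, and jittered replicates, so the
whole pipeline is testable without downloading any study data.

## Worked example

```bash
python - <<'EOF'
from ordviz import write_coords, write_mapping, write_taxa_table
from ordviz.fixtures import FixtureSpec, synth_ordination, synth_mapping, synth_taxa
spec = FixtureSpec(n_samples=40, n_axes=5, seed=7)
open("coords.txt", "w").write(write_coords(synth_ordination(spec)))
open("map.txt", "w").write(write_mapping(synth_mapping(spec)))
open("taxa.txt", "w").write(write_taxa_table(synth_taxa(spec)))
EOF

ordviz -i coords.txt -m map.txt -t taxa.txt -o plot/ \
       --color_by BodySite --add_vectors BodySite,Age --custom_axes Age
```

which logs

```
INFO: read 40 samples x 5 axes, 12 metadata columns
INFO: wrote plot/bundle.json (6463 bytes) and plot/index.html
```

and produces a bundle whose axis list starts with the explicit `Age` axis
(0% variance — it is display-only) followed by the principal coordinates:

```
axes: [('Age', 0.0), ('PC1', 45.8), ('PC2', 39.5), ('PC3', 10.4), ('PC4', 2.2), ('PC5', 2.1)]
points: 40   biplot taxa: 10   trajectories: site_0 site_1 site_2 site_3
```

The 10 most abundant taxa appear as biplot points, e.g.

```json
{"id": "taxon_006",
 "position": [1.99967, 0.05748, -1.22466, 0.6015, 0.02998, -0.11766],
 "weight": 0.10173}
```

`position` is the taxon's abundance-weighted mean sample position (first
entry on the explicit Age axis), and `weight` says this taxon carries about
10.2% of the total abundance mass, which a viewer uses as the sphere
radius. The four trajectories connect each body site's samples in order of
increasing age. `plot/index.html` is a standalone page embedding the same
JSON verbatim in a `<script type="application/json" id="ordviz-bundle">`
block.

Other CLI modes: `--compare other.txt[,third.txt]` adds per-sample edges
across procrustes-aligned ordinations; `--jackknife DIR` aggregates the
replicate coordinate files in `DIR` (lexicographic order, first file is the
master) into consensus points plus ellipsoid radii
(`--jackknife_method stddev|iqr`); `--flip_axes`, `--number_of_axes`,
`--precision` and `--ignore_missing_samples` control the geometry and the
serialization. See `ordviz --help` and `docs/methods.md`.

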