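"""Synthetic data emulating clustered microbial-community ordinations.

The generator produces the same structures the parsers would: an ordination
whose samples fall around per-habitat cluster centroids, a mapping file with
a habitat column, a continuous gradient column (age-like) and filler
metadata columns, a taxa table with cluster-enriched taxa, and jittered
replicate ordinations for exercising jackknife alignment.

Reproducibility: every generator takes a single integer seed; internally a
``numpy.random.SeedSequence`` is spawned into one child stream per output
(coordinates, mapping, taxa — in that fixed order), so the same seed gives
bit-identical results on any platform regardless of which outputs are
requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import special_ortho_group

from .io_formats import MetadataTable, OrdinationResult, TaxaTable, ValidationError

#: Full-scale sample counts for a four-cohort human-microbiome merge
#: (two-subject multi-site time series, adult body-habitat survey,
#: healthy-cohort survey, infant gut time series).
DEMO_COHORT_SIZES: tuple[int, ...] = (1964, 585, 3131, 60)

_DEFAULT_CLUSTERS: tuple[tuple[tuple[float, ...], float], ...] = (
    ((2.5, 0.0, 0.0), 0.35),
    ((-2.0, 1.5, 0.0), 0.35),
    ((0.0, -2.0, 1.0), 0.35),
    ((1.5, 2.0, -1.0), 0.35),
)

#: Level counts cycled through the filler metadata columns; mapping-file
#: metadata in this field is mostly low-cardinality categorical.
_FILLER_LEVELS = (2, 2, 3, 4, 6)


@dataclass
class FixtureSpec:
    """Shape of one synthetic cohort."""

    n_samples: int = 120
    n_axes: int = 5
    n_metadata_columns: int = 12
    n_taxa: int = 24
    cluster_spec: tuple[tuple[tuple[float, ...], float], ...] = _DEFAULT_CLUSTERS
    gradient_spec: tuple[str, tuple[float, float]] = ("Age", (0.5, 33.0))
    cluster_column: str = "BodySite"
    seed: int = 0
    id_prefix: str = "s"

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_axes, self.n_metadata_columns,
               self.n_taxa) < 1:
            raise ValidationError("all fixture counts must be at least 1")
        if any(spread < 0 for _, spread in self.cluster_spec):
            raise ValidationError("cluster spread must be non-negative")
        if self.n_metadata_columns < 2:
            raise ValidationError(
                "need at least 2 metadata columns (cluster + gradient)"
            )
        if self.n_taxa <= len(self.cluster_spec):
            raise ValidationError(
                "n_taxa must exceed the cluster count (one exclusive taxon "
                "per cluster plus at least one background taxon)"
            )


def _streams(spec: FixtureSpec) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(spec.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _ids(spec: FixtureSpec) -> list[str]:
    return [f"{spec.id_prefix}{i:05d}" for i in range(spec.n_samples)]


def _cluster_assignment(spec: FixtureSpec) -> np.ndarray:
    """Contiguous blocks, sizes as even as possible."""
    k = len(spec.cluster_spec)
    base, rem = divmod(spec.n_samples, k)
    sizes = [base + (1 if j < rem else 0) for j in range(k)]
    return np.repeat(np.arange(k), sizes)


def synth_ordination(spec: FixtureSpec) -> OrdinationResult:
    """Clustered sample coordinates with decreasing eigenvalues.

    Samples are drawn isotropically around their cluster centroid; axes are
    then reordered by decreasing centered sum of squares, which becomes the
    eigenvalue, and ``pct_explained`` is the eigenvalue share of the total
    (summing to 100).
    """
    rng = _streams(spec)[0]
    d = spec.n_axes
    assign = _cluster_assignment(spec)
    coords = np.empty((spec.n_samples, d))
    for i, c in enumerate(assign):
        centroid, spread = spec.cluster_spec[c]
        mu = np.zeros(d)
        mu[: min(d, len(centroid))] = centroid[:d]
        coords[i] = mu + rng.normal(0.0, spread, size=d)
    ss = ((coords - coords.mean(axis=0)) ** 2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    coords = coords[:, order]
    eigvals = ss[order]
    total = eigvals.sum()
    if total > 0:
        pct = eigvals / total * 100.0
    else:  # fully degenerate cloud: rank axes arbitrarily but validly
        eigvals = np.arange(d, 0, -1, dtype=float)
        pct = eigvals / eigvals.sum() * 100.0
    return OrdinationResult(_ids(spec), coords, eigvals, pct)


def synth_mapping(spec: FixtureSpec) -> MetadataTable:
    """Metadata matching :func:`synth_ordination`'s sample IDs.

    Columns: the cluster-membership column, the numeric gradient column
    spanning exactly the requested range (values rounded to 4 decimals),
    then categorical filler columns with 2-6 levels each.
    """
    rng = _streams(spec)[1]
    n = spec.n_samples
    assign = _cluster_assignment(spec)
    grad_name, (lo, hi) = spec.gradient_spec
    grad = np.round(np.linspace(lo, hi, n), 4)
    grad = rng.permutation(grad) if n > 1 else grad

    columns = [spec.cluster_column, grad_name]
    cols: list[list[str]] = [
        [f"site_{c}" for c in assign],
        [repr(float(v)) for v in grad],
    ]
    for j in range(spec.n_metadata_columns - 2):
        levels = _FILLER_LEVELS[j % len(_FILLER_LEVELS)]
        columns.append(f"Var{j:02d}")
        cols.append([f"v{t}" for t in rng.integers(0, levels, size=n)])
    rows = [[col[i] for col in cols] for i in range(n)]
    return MetadataTable(_ids(spec), columns, rows)


def synth_taxa(spec: FixtureSpec) -> TaxaTable:
    """Counts with one cluster-exclusive taxon per cluster.

    Taxon *j* (for *j* < number of clusters) occurs only in cluster *j*'s
    samples, so its weighted-average biplot position must land inside that
    cluster.  The next block of taxa is 10x enriched in its cluster, the
    rest is uniform background; the last taxon is ubiquitous (+1 in every
    sample) so no sample column sums to zero.
    """
    rng = _streams(spec)[2]
    n, t = spec.n_samples, spec.n_taxa
    k = len(spec.cluster_spec)
    assign = _cluster_assignment(spec)
    counts = np.zeros((t, n))
    for j in range(t):
        if j < k:  # exclusive
            mask = assign == j
            counts[j, mask] = rng.poisson(20.0, size=mask.sum())
            if counts[j, mask].sum() == 0:
                idx = np.flatnonzero(mask)[0]
                counts[j, idx] = 1.0
        elif j < 2 * k:  # enriched 10x in its cluster
            lam = np.where(assign == (j - k), 50.0, 5.0)
            counts[j] = rng.poisson(lam)
        else:  # background
            counts[j] = rng.poisson(5.0, size=n)
    counts[-1] += 1.0  # ubiquitous taxon keeps every column total positive
    taxa_ids = [f"taxon_{j:03d}" for j in range(t)]
    return TaxaTable(taxa_ids, _ids(spec), counts)


def jitter_replicates(
    ord_res: OrdinationResult,
    k: int,
    sigma: float,
    seed: int,
    rotate: bool = True,
) -> list[OrdinationResult]:
    """k noisy copies of an ordination, each rigidly rotated.

    Independent zero-mean Gaussian noise of scale ``sigma`` is added to
    every coordinate; each copy is then spun by a uniformly random rotation
    (determinant +1) to exercise procrustes alignment.  ``rotate=False``
    keeps the identity rotation.
    """
    if k < 1:
        raise ValidationError("k must be at least 1")
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    d = ord_res.n_axes
    out = []
    for child in np.random.SeedSequence(seed).spawn(k):
        rng = np.random.default_rng(child)
        coords = ord_res.coords + rng.normal(0.0, sigma, size=ord_res.coords.shape)
        if rotate and d >= 2:
            q = special_ortho_group.rvs(dim=d, random_state=rng)
            coords = coords @ q
        out.append(
            OrdinationResult(
                list(ord_res.sample_ids),
                coords,
                ord_res.eigvals.copy(),
                ord_res.pct_explained.copy(),
            )
        )
    return out


def merge_ordinations(ords: list[OrdinationResult]) -> OrdinationResult:
    """Concatenate cohorts (disjoint sample IDs) into one ordination.

    All inputs are zero-padded to the largest axis count.  The merged
    per-axis eigenvalues and percentages are the arithmetic means of the
    inputs' (a display convention; merged cohorts have no joint
    eigendecomposition).
    """
    from .compare import pad_axes

    if not ords:
        raise ValidationError("nothing to merge")
    d = max(o.n_axes for o in ords)
    padded = [pad_axes(o, d) for o in ords]
    ids = [s for o in padded for s in o.sample_ids]
    coords = np.vstack([o.coords for o in padded])
    eig = np.mean([o.eigvals for o in padded], axis=0)
    pct = np.mean([o.pct_explained for o in padded], axis=0)
    return OrdinationResult(ids, coords, eig, pct)


def merge_mappings(metas: list[MetadataTable]) -> MetadataTable:
    """Row-concatenate mapping tables, unioning columns (missing cells get
    the standard missing token)."""
    from .io_formats import MISSING

    if not metas:
        raise ValidationError("nothing to merge")
    columns: list[str] = []
    for m in metas:
        for c in m.column_names:
            if c not in columns:
                columns.append(c)
    ids: list[str] = []
    rows: list[list[str]] = []
    for m in metas:
        idx = {c: j for j, c in enumerate(m.column_names)}
        for sid, row in zip(m.sample_ids, m.values):
            ids.append(sid)
            rows.append([row[idx[c]] if c in idx else MISSING for c in columns])
    return MetadataTable(ids, columns, rows)


def demo_cohorts(
    seed: int,
    sizes: tuple[int, ...] = DEMO_COHORT_SIZES,
    n_axes: int = 5,
) -> tuple[OrdinationResult, MetadataTable]:
    """Generate and merge one cohort per entry of ``sizes``.

    Each cohort gets its own ID prefix and seed stream; the merged pair is
    ready for :func:`ordviz.io_formats.validate_overlap` and bundling.
    """
    specs = [
        FixtureSpec(
            n_samples=n, n_axes=n_axes, seed=seed + i, id_prefix=f"c{i}.s"
        )
        for i, n in enumerate(sizes)
    ]
    ords = [synth_ordination(s) for s in specs]
    metas = [synth_mapping(s) for s in specs]
    return merge_ordinations(ords), merge_mappings(metas)
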