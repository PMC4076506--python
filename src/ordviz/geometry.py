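"""Deterministic coordinate transforms for ordination display.

Everything here is pure geometry on parsed inputs: per-axis variance
scaling, explicit metadata axes, parallel-coordinates normalization,
gradient trajectories, weighted-average taxa biplots and axis sign flips.
No operation reorders or renames samples (trajectories partition them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    MetadataTable,
    OrdinationResult,
    TaxaTable,
    ValidationError,
)


@dataclass
class GradientTrajectory:
    """One subject's/site's ordered path along a continuous variable.

    ``gradient_values`` are non-decreasing; ``polyline`` holds the samples'
    ordination coordinates in the same order.
    """

    label: str
    ordered_sample_ids: list[str]
    gradient_values: np.ndarray
    polyline: np.ndarray

    def __post_init__(self) -> None:
        self.gradient_values = np.asarray(self.gradient_values, dtype=float)
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        if len(self.ordered_sample_ids) != self.polyline.shape[0]:
            raise ValidationError("trajectory IDs and polyline length differ")
        if np.any(np.diff(self.gradient_values) < 0):
            raise ValidationError("trajectory gradient values must not decrease")


@dataclass
class BiplotPoint:
    """A taxon placed at the abundance-weighted mean of sample positions.

    ``weight`` is the taxon's share of total relative-abundance mass over the
    retained samples, in [0, 1]; it drives the displayed sphere radius.
    """

    taxon_id: str
    position: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            raise ValidationError("biplot weight outside [0, 1]")


def scale_axes_by_variance(ord_res: OrdinationResult) -> np.ndarray:
    """Rescale each axis by its share of variance relative to the first.

    Column *j* of the result is column *j* of the coordinates multiplied by
    ``pct_explained[j] / pct_explained[0]``; the first column is untouched.
    """
    pct = ord_res.pct_explained
    if pct[0] <= 0:
        raise ValidationError(
            "first axis explains no variance; cannot scale against it"
        )
    scaled = ord_res.coords * (pct / pct[0])
    scaled[:, 0] = ord_res.coords[:, 0]  # keep the reference axis bit-exact
    return scaled


def flip_axes(ord_res: OrdinationResult, axes: Iterable[int]) -> OrdinationResult:
    """Negate the listed (1-based) axes; eigenvalues/percentages unchanged."""
    axes = sorted(set(axes))
    d = ord_res.n_axes
    for a in axes:
        if not 1 <= a <= d:
            raise ValidationError(f"axis {a} out of range 1..{d}")
    coords = ord_res.coords.copy()
    for a in axes:
        coords[:, a - 1] = -coords[:, a - 1]
    return OrdinationResult(
        list(ord_res.sample_ids),
        coords,
        ord_res.eigvals.copy(),
        ord_res.pct_explained.copy(),
    )


def make_explicit_axis(
    ord_res: OrdinationResult,
    meta: MetadataTable,
    column: str,
) -> OrdinationResult:
    """Prepend a display axis built from a continuous metadata column.

    The column value for each sample is min-max rescaled to the range of the
    first principal coordinate, so the metadata axis is commensurate with
    ordination units.  The new axis carries eigval 0 and explains 0% of the
    variance (display-only); the original axes are unchanged.
    """
    sub = meta.subset(ord_res.sample_ids)
    vals = sub.strict_numeric_column(column)
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        raise ValidationError(
            f"column {column!r} has zero range; cannot form an axis"
        )
    pc1 = ord_res.coords[:, 0]
    r = pc1.max() - pc1.min()
    new_axis = (vals - vmin) / (vmax - vmin) * r
    coords = np.column_stack([new_axis, ord_res.coords])
    return OrdinationResult(
        list(ord_res.sample_ids),
        coords,
        np.concatenate([[0.0], ord_res.eigvals]),
        np.concatenate([[0.0], ord_res.pct_explained]),
    )


def parallel_coordinates(ord_res: OrdinationResult, n_axes: int) -> np.ndarray:
    """Per-sample polylines over the first ``n_axes`` axes, each axis
    independently min-max normalized to [0, 1].

    An axis with zero range maps every sample to 0.5 so polylines stay
    connected.  Returns an ``(n, n_axes)`` array.
    """
    d = ord_res.n_axes
    if not 2 <= n_axes <= d:
        raise ValidationError(f"n_axes must be in 2..{d}, got {n_axes}")
    block = ord_res.coords[:, :n_axes]
    lo = block.min(axis=0)
    hi = block.max(axis=0)
    rng = hi - lo
    out = np.empty_like(block)
    for j in range(n_axes):
        if rng[j] == 0:
            out[:, j] = 0.5
        else:
            out[:, j] = (block[:, j] - lo[j]) / rng[j]
    return out


def make_trajectories(
    ord_res: OrdinationResult,
    meta: MetadataTable,
    trajectory_column: str,
    gradient_column: str,
) -> list[GradientTrajectory]:
    """Group samples by a categorical column and order each group along a
    numeric gradient (ties broken by sample-ID lexicographic order)."""
    sub = meta.subset(ord_res.sample_ids)
    grad = sub.strict_numeric_column(gradient_column)
    groups = sub.column(trajectory_column)
    order: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        order.setdefault(g, []).append(i)
    trajectories = []
    for label, idxs in order.items():
        idxs = sorted(idxs, key=lambda i: (grad[i], ord_res.sample_ids[i]))
        trajectories.append(
            GradientTrajectory(
                label,
                [ord_res.sample_ids[i] for i in idxs],
                grad[idxs],
                ord_res.coords[idxs],
            )
        )
    return trajectories


def biplot_coords(
    ord_res: OrdinationResult,
    taxa: TaxaTable,
    n_keep: int = 10,
) -> list[BiplotPoint]:
    """Project taxa into sample-ordination space as weighted averages.

    Each taxon is placed at the mean of the sample coordinates weighted by
    its per-sample relative abundance, so every biplot point lies inside the
    convex hull of the samples containing the taxon.  Taxa are ranked by
    total relative-abundance mass and the top ``n_keep`` retained; a taxon's
    ``weight`` is its mass as a fraction of the mass of *all* taxa.
    """
    if n_keep < 1:
        raise ValidationError("n_keep must be at least 1")
    if taxa.n_taxa == 0:
        raise ValidationError("empty taxa table")
    missing = set(ord_res.sample_ids) - set(taxa.sample_ids)
    if missing:
        raise ValidationError(
            "taxa table lacks samples: " + ", ".join(sorted(missing))
        )
    sub = taxa.subset_samples(ord_res.sample_ids)
    rel = sub.relative_abundance()
    mass = rel.sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise ValidationError("taxa table has no positive abundances")
    ranked = sorted(
        (i for i in range(sub.n_taxa) if mass[i] > 0),
        key=lambda i: (-mass[i], sub.taxa_ids[i]),
    )
    points = []
    for i in ranked[:n_keep]:
        position = rel[i] @ ord_res.coords / mass[i]
        points.append(BiplotPoint(sub.taxa_ids[i], position, mass[i] / total))
    return points
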