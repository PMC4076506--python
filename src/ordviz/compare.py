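"""Coordinate comparison across ordinations.

Two families of operations live here:

* **procrustes superimposition** — optimal translation + uniform scaling +
  orthogonal rotation of one configuration onto another, with the M² misfit
  statistic.  Both configurations are centered and scaled to unit Frobenius
  norm, the rotation comes from the SVD of the cross-product matrix, and the
  query is rescaled by the least-squares factor (the sum of singular
  values), giving M² = 1 − (Σσᵢ)², the convention used throughout the
  ordination literature.  PCoA axis signs are arbitrary, so reflections are
  allowed by default.

* **jackknife aggregation** — rarefaction replicates of an ordination are
  procrustes-aligned onto the first (master) replicate and summarized as a
  per-sample consensus position plus per-axis confidence radii (sample
  standard deviation, or half the interquartile range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import OrdinationResult, ValidationError


@dataclass
class ProcrustesResult:
    """Optimal superimposition of a query configuration onto a reference.

    ``transformed_query`` lives in the reference's centered, unit-norm
    frame; :meth:`aligned_query` maps it back into the reference's original
    coordinate system.  ``m_squared`` is the residual sum of squares after
    superimposition, in [0, 1]; 0 iff the configurations are
    similarity-equivalent.
    """

    translation_ref: np.ndarray
    translation_qry: np.ndarray
    scale_ref: float
    scale_qry: float
    rotation: np.ndarray
    ls_scale: float
    m_squared: float
    transformed_query: np.ndarray

    def aligned_query(self) -> np.ndarray:
        """Query coordinates mapped into the reference's original frame."""
        return self.transformed_query * self.scale_ref + self.translation_ref


@dataclass
class JackknifeSummary:
    """Consensus positions and confidence radii across aligned replicates."""

    sample_ids: list[str]
    mean_coords: np.ndarray
    radii: np.ndarray
    method: str = "stddev"


def pad_axes(ord_res: OrdinationResult, d_target: int) -> OrdinationResult:
    """Zero-pad an ordination to ``d_target`` axes (an isometry)."""
    d = ord_res.n_axes
    if d_target < d:
        raise ValidationError(
            f"cannot pad a {d}-axis ordination down to {d_target} axes"
        )
    if d_target == d:
        return ord_res
    n = ord_res.n_samples
    extra = d_target - d
    return OrdinationResult(
        list(ord_res.sample_ids),
        np.hstack([ord_res.coords, np.zeros((n, extra))]),
        np.concatenate([ord_res.eigvals, np.zeros(extra)]),
        np.concatenate([ord_res.pct_explained, np.zeros(extra)]),
    )


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mu = coords.mean(axis=0)
    centered = coords - mu
    norm = float(np.linalg.norm(centered))
    if norm == 0:
        raise ValidationError(
            "configuration is degenerate (all samples at one point)"
        )
    return centered / norm, mu, norm


def procrustes(
    reference: OrdinationResult,
    query: OrdinationResult,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """Superimpose ``query`` onto ``reference`` and report the M² misfit.

    The two ordinations must cover the same sample-ID set (the query is
    reordered to the reference's order) and have the same axis count (use
    :func:`pad_axes` first if they differ).  With ``allow_reflection`` off,
    the rotation is constrained to determinant +1 by flipping the smallest
    singular direction when the unconstrained optimum is a reflection.
    """
    ref_set, qry_set = set(reference.sample_ids), set(query.sample_ids)
    if ref_set != qry_set:
        diff = sorted(ref_set ^ qry_set)
        raise ValidationError(
            "sample-ID sets differ; symmetric difference: " + ", ".join(diff)
        )
    if reference.n_axes != query.n_axes:
        raise ValidationError(
            f"axis counts differ ({reference.n_axes} vs {query.n_axes}); "
            "pad_axes first"
        )
    if reference.n_samples < 2:
        raise ValidationError("procrustes needs at least 2 samples")
    query = query.subset(reference.sample_ids)

    x0, mu_x, nx = _center_scale(reference.coords)
    y0, mu_y, ny = _center_scale(query.coords)

    m = y0.T @ x0
    u, s, vt = np.linalg.svd(m)
    signs = np.ones(len(s))
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        signs[-1] = -1.0
    rotation = (u * signs) @ vt
    ls_scale = float((s * signs).sum())
    transformed = ls_scale * (y0 @ rotation)
    m_squared = float(((x0 - transformed) ** 2).sum())
    return ProcrustesResult(
        translation_ref=mu_x,
        translation_qry=mu_y,
        scale_ref=nx,
        scale_qry=ny,
        rotation=rotation,
        ls_scale=ls_scale,
        m_squared=m_squared,
        transformed_query=transformed,
    )


def _common_ids(ordinations: Sequence[OrdinationResult]) -> list[str]:
    common = set(ordinations[0].sample_ids)
    for o in ordinations[1:]:
        common &= set(o.sample_ids)
    if not common:
        raise ValidationError("no sample IDs shared by all ordinations")
    return [s for s in ordinations[0].sample_ids if s in common]


def _aligned_stack(ordinations: Sequence[OrdinationResult]) -> tuple[list[str], np.ndarray]:
    """Subset to common IDs, pad to a common axis count, and align everything
    onto the first ordination in its original frame."""
    ids = _common_ids(ordinations)
    d_max = max(o.n_axes for o in ordinations)
    subs = [pad_axes(o.subset(ids), d_max) for o in ordinations]
    master = subs[0]
    layers = [master.coords]
    for rep in subs[1:]:
        p = procrustes(master, rep, allow_reflection=True)
        layers.append(p.aligned_query())
    return ids, np.stack(layers)


def jackknife_summary(
    replicates: Sequence[OrdinationResult],
    method: str = "stddev",
) -> JackknifeSummary:
    """Aggregate jackknife/rarefaction replicates of an ordination.

    Replicates 2..k are procrustes-superimposed (reflection allowed) onto
    the first replicate, the master.  ``mean_coords`` is the per-sample
    arithmetic mean of the aligned stack; ``radii`` are per-sample per-axis
    sample standard deviations (``method="stddev"``) or half interquartile
    ranges (``method="iqr"``), both in the master's coordinate units.
    """
    if method not in ("stddev", "iqr"):
        raise ValidationError(f"unknown jackknife method {method!r}")
    if not replicates:
        raise ValidationError("no jackknife replicates given")
    ids, stack = _aligned_stack(replicates)
    mean = stack.mean(axis=0)
    k = stack.shape[0]
    if k == 1:
        warnings.warn(
            "single jackknife replicate: confidence radii are all zero",
            stacklevel=2,
        )
        radii = np.zeros_like(mean)
    elif method == "stddev":
        radii = stack.std(axis=0, ddof=1)
    else:
        q1, q3 = np.percentile(stack, [25, 75], axis=0)
        radii = (q3 - q1) / 2.0
    return JackknifeSummary(ids, mean, radii, method)


def compare_series(
    ordinations: Sequence[OrdinationResult],
) -> list[tuple[str, np.ndarray]]:
    """Connect each sample's positions across a series of ordinations.

    All ordinations are procrustes-superimposed onto the first; the result
    is one ``(sample_id, polyline)`` pair per shared sample, where the
    polyline has one vertex per ordination, in input order, expressed in the
    first ordination's frame.
    """
    if len(ordinations) < 2:
        raise ValidationError("need at least 2 ordinations to compare")
    ids, stack = _aligned_stack(ordinations)
    return [(sid, stack[:, i, :].copy()) for i, sid in enumerate(ids)]
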