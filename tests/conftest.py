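import numpy as np
import pytest

from ordviz import MetadataTable, OrdinationResult


def make_ord(coords, ids=None, eigvals=None, pct=None) -> OrdinationResult:
    """Build a valid ordination from a coordinate matrix with defaults."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n, d = coords.shape
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    if eigvals is None:
        eigvals = np.arange(d, 0, -1, dtype=float)
    if pct is None:
        e = np.asarray(eigvals, dtype=float)
        pct = e / e.sum() * 100.0
    return OrdinationResult(ids, coords, eigvals, pct)


def make_meta(ids, **columns) -> MetadataTable:
    """MetadataTable from keyword columns of per-sample string values."""
    names = list(columns)
    rows = [[str(columns[c][i]) for c in names] for i in range(len(ids))]
    return MetadataTable(list(ids), names, rows)


def grid_oracle_m2(x: np.ndarray, y: np.ndarray, step: float = 1e-4) -> float:
    """Brute-force procrustes misfit for 2-D configurations.

    Centers and unit-norm scales both configurations analytically, then
    grid-searches the rotation angle over [0, 2pi) (with and without a
    reflection) and returns 1 - max(trace)^2, the residual sum of squares
    after least-squares rescaling.  Independent of the SVD route.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    x0 = xc / np.linalg.norm(xc)
    y0 = yc / np.linalg.norm(yc)
    m = y0.T @ x0
    theta = np.arange(0.0, 2.0 * np.pi, step)
    c, s = np.cos(theta), np.sin(theta)
    best = -np.inf
    for refl in (1.0, -1.0):
        mm = m.copy()
        mm[1, :] *= refl
        tr = c * (mm[0, 0] + mm[1, 1]) + s * (mm[1, 0] - mm[0, 1])
        best = max(best, float(tr.max()))
    return 1.0 - best * best


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
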