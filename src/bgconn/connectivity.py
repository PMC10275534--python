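"""Nuisance-controlled partial-correlation connectivity.

Each parcel's series is residualized on an intercept plus the nuisance
regressors; the ROI-to-ROI matrix is the Pearson correlation of the
residualized series (equivalent to the classical partial-correlation
formula for a shared conditioning set).  Correlations are Fisher-z
transformed before averaging across runs or entering statistics.
"""

from __future__ import annotations

import numpy as np

from .types import ConnectivityMatrix, ParcelTimeSeries

__all__ = [
    "partial_corr_matrix",
    "fisher_z",
    "inverse_fisher_z",
    "to_fisher_z_matrix",
    "average_runs",
    "vectorize_upper",
    "matrix_from_upper",
]

_CLIP = 1.0 - 1e-7


def partial_corr_matrix(
    ts: ParcelTimeSeries, nuisance: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise partial correlations between parcels controlling for the
    nuisance regressors (r scale, unit diagonal).

    With an empty nuisance set this reduces to the plain correlation
    matrix (the intercept is always included, i.e. series are demeaned).
    """
    T = ts.n_volumes
    X = np.ones((T, 1))
    if nuisance is not None and np.size(nuisance) > 0:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != T:
            raise ValueError("nuisance rows must align with time series rows")
        X = np.column_stack([X, nuisance])
    if T <= X.shape[1] + 2:
        raise ValueError(
            f"insufficient degrees of freedom: {T} volumes for "
            f"{X.shape[1]} regressors"
        )
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("a parcel is constant after residualization")
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    return r


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r); |r| = 1 is clipped to keep z finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return out if out.ndim else float(out)


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def to_fisher_z_matrix(
    r: np.ndarray,
    method: str,
    subject_id: str,
    parcel_ids,
    n_volumes_used: int,
) -> ConnectivityMatrix:
    """Wrap an r-scale matrix as a Fisher-z :class:`ConnectivityMatrix`."""
    z = np.asarray(fisher_z(r))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z=z,
        method=method,
        subject_id=subject_id,
        parcel_ids=parcel_ids,
        n_volumes_used=n_volumes_used,
    )


def average_runs(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entrywise mean of per-run Fisher-z matrices (volumes summed).

    Supports subjects with a reduced run count (e.g. three usable runs
    instead of four).
    """
    if not mats:
        raise ValueError("need at least one matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.parcel_ids != first.parcel_ids:
            raise ValueError("mismatched parcel order across runs")
        if m.method != first.method or m.subject_id != first.subject_id:
            raise ValueError("matrices must share method and subject")
    z = np.mean([m.z for m in mats], axis=0)
    return ConnectivityMatrix(
        z=z,
        method=first.method,
        subject_id=first.subject_id,
        parcel_ids=first.parcel_ids,
        n_volumes_used=sum(m.n_volumes_used for m in mats),
    )


def vectorize_upper(mat: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Row-major strict upper triangle: length p(p-1)/2.

    Order is (0,1), (0,2), ..., (0,p-1), (1,2), ... — numpy's
    ``triu_indices`` convention; :func:`matrix_from_upper` inverts it.
    """
    z = mat.z if isinstance(mat, ConnectivityMatrix) else np.asarray(mat)
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu]


def matrix_from_upper(vec: np.ndarray, n_parcels: int) -> np.ndarray:
    """Symmetric matrix (zero diagonal) from a strict-upper-triangle vector."""
    vec = np.asarray(vec, dtype=float)
    expected = n_parcels * (n_parcels - 1) // 2
    if vec.shape[0] != expected:
        raise ValueError(f"expected length {expected}, got {vec.shape[0]}")
    out = np.zeros((n_parcels, n_parcels))
    iu = np.triu_indices(n_parcels, k=1)
    out[iu] = vec
    return out + out.T
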