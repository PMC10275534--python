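"""Removal of task-evoked activity from task runs.

Two methods produce the "background" datasets:

* **LPF** — low-pass filter the run at a 16-s cutoff, discarding the
  12-s trial frequency and everything faster (:func:`lpf_dataset`).
* **FIR** — fit a per-run GLM whose task part is a finite impulse
  response basis (one indicator column per TR of the 12-s post-onset
  window, 6 columns at TR 2 s) alongside the 18 Power nuisance
  regressors and an intercept, and keep the residuals
  (:func:`fir_residuals`).

The FIR basis fits an arbitrary evoked-response shape on the TR grid
without assuming a canonical hemodynamic response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filtering import lowpass
from .types import ConfoundSet, ParcelTimeSeries

__all__ = [
    "FIRDesign",
    "build_fir_design",
    "build_nuisance",
    "fir_residuals",
    "lpf_dataset",
    "NUISANCE_COLUMNS",
]

logger = logging.getLogger(__name__)

FIR_WINDOW_TRS = 6

#: Fixed column order of the nuisance matrix: the 9 signals then their
#: 9 backward-difference derivatives.
NUISANCE_COLUMNS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "csf", "white_matter", "global_signal",
    "trans_x_derivative1", "trans_y_derivative1", "trans_z_derivative1",
    "rot_x_derivative1", "rot_y_derivative1", "rot_z_derivative1",
    "csf_derivative1", "white_matter_derivative1", "global_signal_derivative1",
)


@dataclass
class FIRDesign:
    """FIR basis matrix for one run: column k carries a 1 at volume
    ``onset + k`` for every trial whose k-th window sample is in-run."""

    matrix: np.ndarray
    onset_volumes: tuple[int, ...]
    window_trs: int = FIR_WINDOW_TRS
    run_id: str = "run-1"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.window_trs:
            raise ValueError(f"design must have exactly {self.window_trs} columns")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def build_fir_design(
    onsets_s: list[float] | tuple[float, ...],
    tr_s: float,
    n_volumes: int,
    window_trs: int = FIR_WINDOW_TRS,
) -> FIRDesign:
    """Indicator FIR design with one column per post-onset TR.

    Onsets are mapped to volumes by rounding ``onset / tr_s`` (exact when
    onsets are TR multiples, as in the slow event-related design).  Trials
    whose window extends past the run contribute only in-run rows; an
    onset at or beyond the run end is an error.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    onsets = [float(o) for o in onsets_s]
    if any(o < 0 for o in onsets):
        raise ValueError("onsets must be non-negative")
    if sorted(onsets) != onsets:
        raise ValueError("onsets must be sorted")
    onset_volumes = [int(round(o / tr_s)) for o in onsets]
    beyond = [o for o, v in zip(onsets, onset_volumes) if v >= n_volumes]
    if beyond:
        raise ValueError(f"onsets beyond the run end: {beyond}")
    mat = np.zeros((n_volumes, window_trs))
    for v in onset_volumes:
        for k in range(window_trs):
            if v + k < n_volumes:
                mat[v + k, k] = 1.0
    return FIRDesign(matrix=mat, onset_volumes=tuple(onset_volumes),
                     window_trs=window_trs)


def build_nuisance(conf: ConfoundSet) -> np.ndarray:
    """Volumes x 18 mean-centered nuisance matrix in ``NUISANCE_COLUMNS`` order:
    6 motion parameters, CSF, white matter, global signal, then the 9
    backward-difference derivatives (derivative row 0 is 0 by convention)."""
    mat = np.column_stack([conf.signals(), conf.derivatives()])
    return mat - mat.mean(axis=0, keepdims=True)


def _prune_collinear(X: np.ndarray, names: list[str], tol: float = 1e-10
                     ) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop later columns that are (numerically) linear combinations of
    earlier ones, greedily via QR-style projection."""
    keep: list[int] = []
    dropped: list[str] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            coef, *_ = np.linalg.lstsq(basis, col, rcond=None)
            resid = col - basis @ coef
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, col])
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def fir_residuals(
    ts: ParcelTimeSeries,
    design: FIRDesign,
    nuisance: np.ndarray | None = None,
) -> ParcelTimeSeries:
    """OLS residuals of each parcel on [intercept | FIR basis | nuisance].

    Exactly-collinear columns (e.g. derivatives of constant confounds) are
    pruned with a logged warning; a model that is still rank-deficient
    afterwards is an error naming the offending columns.  Residuals are
    orthogonal to every retained regressor.
    """
    if design.n_volumes != ts.n_volumes:
        raise ValueError("design and time series row counts differ")
    parts = [np.ones((ts.n_volumes, 1)), design.matrix]
    names = ["intercept"] + [f"fir_{k}" for k in range(design.window_trs)]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != ts.n_volumes:
            raise ValueError("nuisance and time series row counts differ")
        parts.append(nuisance)
        names += [f"nuisance_{k}" for k in range(nuisance.shape[1])]
    X = np.column_stack(parts)
    X, kept, dropped = _prune_collinear(X, names)
    if dropped:
        logger.warning("dropped collinear regressors: %s", ", ".join(dropped))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient model after pruning; columns: {kept}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return ts.with_data(ts.data - X @ beta)


def lpf_dataset(ts: ParcelTimeSeries, cutoff_s: float = 16.0) -> ParcelTimeSeries:
    """The LPF background dataset: the run low-pass filtered at 16 s."""
    return lowpass(ts, cutoff_s=cutoff_s)
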