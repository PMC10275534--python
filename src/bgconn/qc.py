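"""Motion/intensity quality control and volume censoring ("scrubbing").

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the six rigid-body parameters, with rotations
converted to arc length on a 50-mm sphere.  DVARS is the parcel-level
root-mean-square of the temporal derivative, expressed as a percentage of
the grand mean absolute signal level so it is invariant to overall signal
scale.  Volumes exceeding either threshold (defaults FD > 0.5 mm,
DVARS > 0.5%) are removed before connectivity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ParcelTimeSeries

__all__ = [
    "QCTrace",
    "framewise_displacement",
    "dvars",
    "compute_qc",
    "scrub",
    "InsufficientDataError",
    "ROTATION_RADIUS_MM",
]

ROTATION_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD_PCT = 0.5


class InsufficientDataError(RuntimeError):
    """Raised when scrubbing leaves too few volumes to analyze the run."""


@dataclass
class QCTrace:
    """Per-volume QC traces; element 0 of each trace is 0 by convention."""

    fd_mm: np.ndarray
    dvars_pct: np.ndarray

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float).reshape(-1)
        self.dvars_pct = np.asarray(self.dvars_pct, dtype=float).reshape(-1)
        if self.fd_mm.shape != self.dvars_pct.shape:
            raise ValueError("fd and dvars traces must have equal length")

    def retain_mask(
        self,
        fd_thresh: float = FD_THRESHOLD_MM,
        dvars_thresh: float = DVARS_THRESHOLD_PCT,
    ) -> np.ndarray:
        return ~((self.fd_mm > fd_thresh) | (self.dvars_pct > dvars_thresh))


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """FD_t = sum|Δtranslation| + 50 mm * sum|Δrotation|; FD_0 = 0.

    ``motion`` is volumes x 6: three translations (mm) then three
    rotations (radians).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be volumes x 6 (3 trans mm, 3 rot rad)")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(ts: ParcelTimeSeries) -> np.ndarray:
    """DVARS_t = RMS over parcels of (x_t - x_{t-1}), as a percentage of
    the grand mean absolute signal; DVARS_0 = 0."""
    grand = np.abs(ts.data).mean()
    if grand == 0:
        raise ValueError("grand mean signal is zero; DVARS percentage undefined")
    rms = np.sqrt((np.diff(ts.data, axis=0) ** 2).mean(axis=1))
    return np.concatenate([[0.0], 100.0 * rms / grand])


def compute_qc(ts: ParcelTimeSeries, motion: np.ndarray) -> QCTrace:
    return QCTrace(fd_mm=framewise_displacement(motion), dvars_pct=dvars(ts))


def scrub(
    ts: ParcelTimeSeries,
    qc: QCTrace,
    fd_thresh: float = FD_THRESHOLD_MM,
    dvars_thresh: float = DVARS_THRESHOLD_PCT,
    min_retained_frac: float = 0.5,
) -> tuple[ParcelTimeSeries, np.ndarray]:
    """Remove volumes exceeding either QC threshold.

    Returns the censored series (remaining volumes concatenated in order)
    and the boolean retain mask for auditing.  Raises
    :class:`InsufficientDataError` when fewer than ``min_retained_frac``
    of the volumes survive — the run is unusable.
    """
    if qc.fd_mm.shape[0] != ts.n_volumes:
        raise ValueError("QC trace length does not match run length")
    mask = qc.retain_mask(fd_thresh, dvars_thresh)
    frac = mask.mean()
    if frac < min_retained_frac:
        raise InsufficientDataError(
            f"only {frac:.0%} of volumes retained after scrubbing "
            f"(minimum {min_retained_frac:.0%})"
        )
    return ts.with_data(ts.data[mask]), mask
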