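"""Zero-phase temporal filtering of parcel time series.

Both filters are 5th-order Butterworth designs applied forward-backward
(:func:`scipy.signal.filtfilt`), which doubles the effective order and
cancels phase shift.  The low-pass cutoff default (16 s) sits below the
12-s trial period of the slow event-related design so that trial-locked
fluctuations fall in the stopband; the high-pass default (100 s) removes
scanner drift.  Reflect-type padding of one cutoff period limits edge
transients.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import ParcelTimeSeries

__all__ = ["highpass", "lowpass", "butter_sos", "frequency_response"]

FILTER_ORDER = 5


def butter_sos(cutoff_s: float, tr_s: float, btype: str) -> np.ndarray:
    """Second-order-sections Butterworth design for a period cutoff."""
    nyquist_hz = 0.5 / tr_s
    wn = (1.0 / cutoff_s) / nyquist_hz
    if not (0 < wn < 1):
        raise ValueError(
            f"cutoff {cutoff_s} s is not representable at TR {tr_s} s "
            f"(normalized frequency {wn:.3f})"
        )
    return sps.butter(FILTER_ORDER, wn, btype=btype, output="sos")


def frequency_response(
    cutoff_s: float, tr_s: float, btype: str, freqs_hz: np.ndarray
) -> np.ndarray:
    """|H(f)| of the forward-backward filter (single-pass response squared)."""
    sos = butter_sos(cutoff_s, tr_s, btype)
    w = 2 * np.pi * np.asarray(freqs_hz) * tr_s
    _, h = sps.sosfreqz(sos, worN=w)
    return np.abs(h) ** 2


def _padlen(cutoff_s: float, tr_s: float, n_volumes: int) -> int:
    want = int(round(cutoff_s / tr_s))
    default = 3 * (2 * FILTER_ORDER + 1)
    return min(max(want, default), n_volumes - 1)


def _check_length(ts: ParcelTimeSeries, cutoff_s: float, kind: str) -> None:
    if ts.duration_s < cutoff_s:
        warnings.warn(
            f"{kind} filter with a {cutoff_s:g}-s cutoff on a "
            f"{ts.duration_s:g}-s run is ill-conditioned",
            RuntimeWarning,
            stacklevel=3,
        )


def highpass(ts: ParcelTimeSeries, cutoff_s: float = 100.0) -> ParcelTimeSeries:
    """Zero-phase high-pass: attenuates fluctuations slower than ``cutoff_s``
    and removes column means."""
    if cutoff_s <= 2 * ts.tr_s:
        raise ValueError("high-pass cutoff must exceed twice the TR")
    _check_length(ts, cutoff_s, "high-pass")
    sos = butter_sos(cutoff_s, ts.tr_s, "highpass")
    demeaned = ts.data - ts.data.mean(axis=0, keepdims=True)
    out = sps.sosfiltfilt(
        sos, demeaned, axis=0, padtype="even", padlen=_padlen(cutoff_s, ts.tr_s, ts.n_volumes)
    )
    out = out - out.mean(axis=0, keepdims=True)
    return ts.with_data(out)


def lowpass(ts: ParcelTimeSeries, cutoff_s: float = 16.0) -> ParcelTimeSeries:
    """Zero-phase low-pass: strongly attenuates fluctuations at and above
    ``1/cutoff_s`` Hz while passing DC and slow fluctuations unchanged.

    The column mean is subtracted before filtering and restored afterwards,
    so a constant input is reproduced exactly.
    """
    if cutoff_s < 2 * ts.tr_s:
        raise ValueError("low-pass cutoff must be at least twice the TR (Nyquist)")
    _check_length(ts, cutoff_s, "low-pass")
    sos = butter_sos(cutoff_s, ts.tr_s, "lowpass")
    mean = ts.data.mean(axis=0, keepdims=True)
    out = sps.sosfiltfilt(
        sos,
        ts.data - mean,
        axis=0,
        padtype="even",
        padlen=_padlen(cutoff_s, ts.tr_s, ts.n_volumes),
    )
    return ts.with_data(out + mean)
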