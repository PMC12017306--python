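"""Trace preprocessing and response-quality indices.

Raw ROI fluorescence traces are detrended with a Savitzky-Golay filter,
normalized to zero pre-stimulus median and unit variance, averaged over
stimulus repeats, and scored with a repeat-reliability (signal-to-noise)
quality index.  A rectified low-pass derivative converts normalized traces
into the nonnegative "event rate" signal used for receptive-field fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt

__all__ = [
    "NormalizedTrace",
    "detrend",
    "normalize",
    "repeat_average",
    "qi_snr",
    "quality_filter",
    "lowpass_gradient",
]


@dataclass
class NormalizedTrace:
    """A preprocessed ROI trace with its intermediate stages."""

    r_raw: np.ndarray
    r_smooth: np.ndarray
    r_detrend: np.ndarray
    r_norm: np.ndarray
    t0: float
    sampling_rate: float


def detrend(r_raw: np.ndarray, sampling_rate: float, window: float = 60.0,
            poly_order: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a slow Savitzky-Golay smooth from a raw trace.

    The default 60-s window is used for all stimuli except the sine-spot,
    which uses 10 s (its whole presentation is short).  Returns
    ``(r_detrend, r_smooth)`` with ``r_detrend = r_raw - r_smooth``.
    """
    r_raw = np.asarray(r_raw, dtype=float)
    win = int(round(window * sampling_rate))
    if win > len(r_raw):
        warnings.warn("trace shorter than detrend window; shrinking window")
        win = len(r_raw)
    if win % 2 == 0:
        win -= 1
    if win < poly_order + 2:
        raise ValueError("window too short for the polynomial order")
    r_smooth = savgol_filter(r_raw, win, poly_order, mode="interp")
    return r_raw - r_smooth, r_smooth


def normalize(r_detrend: np.ndarray, t0: float, sampling_rate: float) -> np.ndarray:
    """Zero the pre-stimulus median and scale to unit variance.

    ``r_norm = (r_detrend - median(r_detrend[t < t0])) / SD[r_detrend]``.

    Raises on a constant (dead) trace.
    """
    r_detrend = np.asarray(r_detrend, dtype=float)
    n_pre = int(round(t0 * sampling_rate))
    if n_pre < 1:
        raise ValueError("no samples before stimulus onset")
    sd = np.std(r_detrend)
    if sd == 0:
        raise ValueError("zero-variance trace cannot be normalized")
    return (r_detrend - np.median(r_detrend[:n_pre])) / sd


def repeat_average(r_norm: np.ndarray, n_repeats: int) -> np.ndarray:
    """Average a normalized trace over equal-length stimulus repeats."""
    r_norm = np.asarray(r_norm, dtype=float)
    n = len(r_norm) // n_repeats
    return r_norm[: n * n_repeats].reshape(n_repeats, n).mean(axis=0)


def qi_snr(C: np.ndarray) -> float:
    """Repeat-reliability quality index of a time-by-repeats response matrix.

    ``QI = Var_t[<C>_r] / <Var_t[C]>_r`` — the variance over time of the
    repeat-averaged response, divided by the repeat-averaged variance over
    time.  Equals 1 for identical repeats; has expectation 1/R for pure
    noise with R repeats.  Invariant to affine rescaling of C.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("C must be time x repeats")
    if C.shape[1] < 2:
        raise ValueError("need at least 2 repeats")
    num = np.var(C.mean(axis=1))
    den = np.var(C, axis=0).mean()
    if den == 0:
        return 1.0
    return float(num / den)


def quality_filter(records: list[dict], mode: str = "dendritic") -> list[dict]:
    """Apply the response-quality inclusion rules.

    dendritic: keep records with local-chirp OR global-chirp QI >= 0.35.
    somatic:   keep records with global-chirp QI >= 0.5 AND color-spot
    QI >= 0.5 (the color-spot QI being computed per color from the 300- and
    400-um spots only, upstream).  Records missing a required QI are
    excluded with a logged reason (``record["exclude_reason"]``).

    The filter is a pure predicate: record order never changes the
    surviving set.
    """
    if mode not in {"dendritic", "somatic"}:
        raise ValueError("mode must be 'dendritic' or 'somatic'")
    kept = []
    for rec in records:
        if mode == "dendritic":
            ql, qg = rec.get("qi_local"), rec.get("qi_global")
            if ql is None and qg is None:
                rec["exclude_reason"] = "missing chirp responses"
                continue
            if (ql is not None and ql >= 0.35) or (qg is not None and qg >= 0.35):
                kept.append(rec)
        else:
            qg, qcs = rec.get("qi_global"), rec.get("qi_colorspot")
            if qg is None or qcs is None:
                rec["exclude_reason"] = "missing global-chirp or color-spot response"
                continue
            if qg >= 0.5 and qcs >= 0.5:
                kept.append(rec)
    return kept


def lowpass_gradient(r_norm: np.ndarray, sampling_rate: float,
                     f_cutoff: float = 3.0) -> np.ndarray:
    """Rectified derivative of a low-pass-filtered trace.

    The trace is filtered with a zero-phase third-order Butterworth low-pass
    (3 Hz for Ca2+, 5 Hz for glutamate), differentiated by central finite
    differences at the native sampling rate, and rectified:
    ``c_dot = max(0, d/dt LP(r_norm))``.
    """
    r_norm = np.asarray(r_norm, dtype=float)
    if f_cutoff >= sampling_rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = butter(3, f_cutoff, fs=sampling_rate, output="sos")
    r_filt = sosfiltfilt(sos, r_norm)
    grad = np.gradient(r_filt) * sampling_rate
    return np.maximum(0.0, grad)
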