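"""Stimulus-derived surround and transience indices.

These indices compare responses to light increments of different spatial
extents (wide vs. small spots/apertures) or at different times after a
step (early vs. late), using per-repeat baseline-subtracted response
amplitudes with the median taken over repeats.  All indices are invariant
to adding a constant to the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IndexWindows",
    "CHIRP_WINDOWS",
    "SINE_SPOT_WINDOWS",
    "COLOR_SPOT_WINDOWS",
    "light_increment_response",
    "si_stimulus",
    "si_colorspots",
    "tri_chirp",
]


@dataclass(frozen=True)
class IndexWindows:
    """Response (dt_r) and baseline (dt_b) window lengths in seconds."""

    dt_r: float
    dt_b: float

    def __post_init__(self):
        if self.dt_r <= 0 or self.dt_b <= 0:
            raise ValueError("window lengths must be positive")


CHIRP_WINDOWS = IndexWindows(dt_r=2.0, dt_b=2.0)
SINE_SPOT_WINDOWS = IndexWindows(dt_r=1.0, dt_b=0.25)
COLOR_SPOT_WINDOWS = IndexWindows(dt_r=1.0, dt_b=1.0)


def light_increment_response(traces: np.ndarray, t_on: float,
                             sampling_rate: float,
                             windows: IndexWindows) -> np.ndarray:
    """Per-repeat light-increment response amplitude.

    ``RI = mean(response over dt_r s after t_on) - median(response over
    dt_b s before t_on)``.  ``traces`` is (repeats, T); returns one RI per
    repeat, sign preserved.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    i_on = int(round(t_on * sampling_rate))
    n_r = int(round(windows.dt_r * sampling_rate))
    n_b = int(round(windows.dt_b * sampling_rate))
    if i_on - n_b < 0 or i_on + n_r > traces.shape[1]:
        raise ValueError("index windows exceed trace bounds")
    resp = traces[:, i_on: i_on + n_r].mean(axis=1)
    base = np.median(traces[:, i_on - n_b: i_on], axis=1)
    return resp - base


def si_stimulus(ri_wide: np.ndarray, ri_small: np.ndarray) -> float:
    """Surround index from wide- vs small-extent light-increment responses.

    ``SI = med[RI_w] - max(0, med[RI_s])`` with the wide response from the
    global chirp step (or large spot) and the small response from the
    local chirp (or small spot).  With this printed orientation a strongly
    surround-suppressed wide response drives SI negative; downstream
    comparisons are ordinal, and the orientation is recorded here so users
    can flip the sign consistently if they prefer larger = more
    suppressed.
    """
    return float(np.median(ri_wide) - max(0.0, float(np.median(ri_small))))


def si_colorspots(ri_1000: np.ndarray, ri_pref: np.ndarray) -> float:
    """Surround index from the largest vs preferred color spot, per color.

    ``SI_CS = med[RI_1000] / max(0, med[RI_pref]) - 1``: 0 when the
    largest spot matches the preferred-size response, -1 when it is fully
    suppressed.  Undefined (NaN) when the preferred response is not
    positive.
    """
    pref = float(np.median(ri_pref))
    if pref <= 0:
        return float("nan")
    return float(np.median(ri_1000) / pref - 1.0)


def tri_chirp(trace_repeats: np.ndarray, t_on: float, sampling_rate: float,
              window_s: float = 1.0, baseline_s: float = 2.0,
              late_offset_s: float = 2.0) -> float:
    """Transience index of the local-chirp step response.

    Per repeat, ``RP`` is the 90th percentile (linear interpolation) of
    the response in a 1-s window minus the local baseline (median of the
    2 s before the increment).  The early window starts at the light
    increment; the late window starts ``late_offset_s`` after it (the last
    second of a 3-s step).  The index is

        TRi = med[ (RP_a - max(0, RP_b)) / (RP_a + max(0, RP_b)) ]_r

    giving 1 for fully transient and 0 for perfectly sustained responses.
    Returns NaN (no index) if RP_a is negative for any repetition.
    """
    traces = np.atleast_2d(np.asarray(trace_repeats, dtype=float))
    i_on = int(round(t_on * sampling_rate))
    n_w = int(round(window_s * sampling_rate))
    n_b = int(round(baseline_s * sampling_rate))
    i_late = i_on + int(round(late_offset_s * sampling_rate))
    if i_on - n_b < 0 or i_late + n_w > traces.shape[1]:
        raise ValueError("index windows exceed trace bounds")
    base = np.median(traces[:, i_on - n_b: i_on], axis=1)
    rp_a = np.percentile(traces[:, i_on: i_on + n_w], 90, axis=1) - base
    rp_b = np.percentile(traces[:, i_late: i_late + n_w], 90, axis=1) - base
    if np.any(rp_a < 0):
        return float("nan")
    rp_b = np.maximum(0.0, rp_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (rp_a - rp_b) / (rp_a + rp_b)
    return float(np.median(ratio))
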