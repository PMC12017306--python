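"""Visual stimulus generators.

Five stimuli are used throughout the pipeline: binary dense noise for
receptive-field mapping, full-field ("global") and 300-um spot ("local")
chirps, a clipped-sine spot sequence, and colored spot flashes of graded
size.  All generators are frame-exact, deterministic under a seed, and
return :class:`StimulusMovie` objects with intensities in [0, 1].

Intensities are normalized display units; photoreceptor-calibrated units
are out of scope.  The background level defaults to 0.5 of range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "StimulusMovie",
    "ChirpSchedule",
    "gen_dense_noise",
    "gen_chirp",
    "gen_sine_spot",
    "gen_color_spots",
    "save_movie",
    "load_movie",
]

BACKGROUND = 0.5


@dataclass
class StimulusMovie:
    """A stimulus clip: frames (time, y, x) plus timing metadata.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Intensities in [0, 1].
    frame_rate : float
        Display rate in Hz.
    pixel_size : float
        Size of one stimulus pixel in um.
    trigger_times : ndarray
        One timestamp (s) per stimulus event, strictly increasing.
    metadata : dict
        Stimulus name and generator parameters.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    trigger_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, y, x)")
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("intensities must lie in [0, 1]")
        if self.trigger_times.size > 1 and np.any(np.diff(self.trigger_times) <= 0):
            raise ValueError("trigger_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Onset time (s) of every frame."""
        return np.arange(self.n_frames) / self.frame_rate


def gen_dense_noise(
    grid_w: int = 20,
    grid_h: int = 15,
    pixel_um: float = 30.0,
    rate: float = 5.0,
    duration: float = 300.0,
    seed: int = 0,
) -> StimulusMovie:
    """Binary dense noise: each pixel shows an independent, exactly balanced
    ON/OFF sequence.

    "Balanced" is implemented as a per-pixel random shuffle of an equal number
    of ON and OFF frames (not an unconstrained Bernoulli draw), so the ON
    count per pixel is exactly ``n_frames / 2`` for every seed.

    Raises
    ------
    ValueError
        If the total frame count is odd (exact balance impossible).
    """
    if grid_w < 1 or grid_h < 1:
        raise ValueError("grid dimensions must be >= 1")
    n_frames = int(round(duration * rate))
    if n_frames == 0:
        return StimulusMovie(
            np.empty((0, grid_h, grid_w)), rate, pixel_um,
            metadata={"name": "dense_noise", "seed": seed},
        )
    if n_frames % 2:
        raise ValueError(
            f"dense noise needs an even frame count for exact ON/OFF balance, got {n_frames}"
        )
    rng = np.random.default_rng(seed)
    base = np.zeros(n_frames)
    base[: n_frames // 2] = 1.0
    frames = np.empty((n_frames, grid_h, grid_w))
    for y in range(grid_h):
        for x in range(grid_w):
            frames[:, y, x] = rng.permutation(base)
    return StimulusMovie(
        frames, rate, pixel_um,
        trigger_times=np.arange(n_frames) / rate,
        metadata={"name": "dense_noise", "seed": seed, "grid": (grid_h, grid_w)},
    )


@dataclass(frozen=True)
class ChirpSchedule:
    """Segment schedule of the chirp stimulus (all durations in s).

    The exact segment durations are a display convention, fixed here as a
    config constant: background, bright step, gray, a frequency sweep from
    ``freq_lo`` to ``freq_hi``, gray, a contrast ramp at ``ramp_freq``, gray.
    Only relative response features are analyzed downstream.  The light
    increment (step onset) occurs at ``t_background`` into each repeat.
    """

    t_background: float = 2.0
    t_step: float = 3.0
    t_gray1: float = 3.0
    t_sweep: float = 8.0
    t_gray2: float = 2.0
    t_ramp: float = 8.0
    t_gray3: float = 2.0
    ramp_freq: float = 2.0

    @property
    def repeat_duration(self) -> float:
        return (self.t_background + self.t_step + self.t_gray1 + self.t_sweep
                + self.t_gray2 + self.t_ramp + self.t_gray3)


def _chirp_trace(schedule: ChirpSchedule, freq_lo: float, freq_hi: float,
                 rate: float) -> np.ndarray:
    """Intensity trace of one chirp repeat, sampled on a global time grid
    (no per-segment frame snapping)."""
    s = schedule
    t = np.arange(int(round(s.repeat_duration * rate))) / rate
    out = np.full(len(t), BACKGROUND)

    b0 = s.t_background
    b1 = b0 + s.t_step
    b2 = b1 + s.t_gray1
    b3 = b2 + s.t_sweep
    b4 = b3 + s.t_gray2
    b5 = b4 + s.t_ramp
    out[(t >= b0) & (t < b1)] = 1.0
    # frequency sweep: linear chirp, instantaneous frequency freq_lo -> freq_hi
    m = (t >= b2) & (t < b3)
    ts = t[m] - b2
    k = (freq_hi - freq_lo) / s.t_sweep
    out[m] = BACKGROUND + BACKGROUND * np.sin(
        2 * np.pi * (freq_lo * ts + 0.5 * k * ts**2))
    m = (t >= b4) & (t < b5)
    ts = t[m] - b4
    amp = BACKGROUND * ts / s.t_ramp
    out[m] = BACKGROUND + amp * np.sin(2 * np.pi * s.ramp_freq * ts)
    return np.clip(out, 0.0, 1.0)


def gen_chirp(
    aperture_diameter: float | None = None,
    freq_lo: float = 0.5,
    freq_hi: float = 8.0,
    frame_rate: float = 31.25,
    repeats: int = 3,
    field_size_um: tuple[float, float] = (600.0, 800.0),
    pixel_um: float = 20.0,
    schedule: ChirpSchedule | None = None,
) -> StimulusMovie:
    """Chirp stimulus: bright step, frequency sweep and contrast ramp.

    ``aperture_diameter=None`` gives the full-field ("global") chirp;
    300 um gives the "local" chirp spot.  Outside the aperture the intensity
    stays at background.  One trigger per repeat onset.
    """
    if not freq_lo < freq_hi:
        raise ValueError("freq_lo must be < freq_hi")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    schedule = schedule or ChirpSchedule()
    h = max(1, int(round(field_size_um[0] / pixel_um)))
    w = max(1, int(round(field_size_um[1] / pixel_um)))
    mask = np.ones((h, w), dtype=bool)
    if aperture_diameter is not None:
        if aperture_diameter >= max(field_size_um):
            warnings.warn("aperture larger than field; treating as full-field")
        else:
            yy, xx = np.mgrid[:h, :w]
            cy, cx = (h - 1) / 2, (w - 1) / 2
            r = np.hypot((yy - cy) * pixel_um, (xx - cx) * pixel_um)
            mask = r <= aperture_diameter / 2

    trace = _chirp_trace(schedule, freq_lo, freq_hi, frame_rate)
    frames = np.full((repeats * len(trace), h, w), BACKGROUND)
    for rep in range(repeats):
        block = frames[rep * len(trace): (rep + 1) * len(trace)]
        block[:, mask] = trace[:, None]
    triggers = np.arange(repeats) * schedule.repeat_duration
    name = "chirp_local" if aperture_diameter is not None else "chirp_global"
    return StimulusMovie(
        frames, frame_rate, pixel_um, trigger_times=triggers,
        metadata={"name": name, "aperture_um": aperture_diameter,
                  "freq_lo": freq_lo, "freq_hi": freq_hi,
                  "schedule": schedule, "step_onset": schedule.t_background},
    )


def gen_sine_spot(
    diams: tuple[float, ...] = (60.0, 300.0),
    amplitude: float = 1.0,
    repeats: int = 6,
    frame_rate: float = 31.25,
    field_size_um: tuple[float, float] = (600.0, 800.0),
    pixel_um: float = 20.0,
) -> StimulusMovie:
    """Clipped-sine spot flashes: per repeat, one 1-s flash per diameter,
    each followed by a 1-s pause.

    The flash intensity is ``background + (1 - background) * max(0, A sin(pi t))``,
    peaking at t = 0.5 s; it never falls below background.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    h = max(1, int(round(field_size_um[0] / pixel_um)))
    w = max(1, int(round(field_size_um[1] / pixel_um)))
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = np.hypot((yy - cy) * pixel_um, (xx - cx) * pixel_um)

    duration = 2.0 * repeats * len(diams)
    n_total = int(round(duration * frame_rate))
    t = np.arange(n_total) / frame_rate
    frames = np.full((n_total, h, w), BACKGROUND)
    triggers = []
    t_cursor = 0.0
    for _ in range(repeats):
        for d in diams:
            mask = r <= d / 2
            in_flash = (t >= t_cursor) & (t < t_cursor + 1.0)
            profile = np.maximum(0.0, amplitude
                                 * np.sin(np.pi * (t[in_flash] - t_cursor)))
            sub = frames[in_flash]
            sub[:, mask] = BACKGROUND + (1 - BACKGROUND) * profile[:, None]
            frames[in_flash] = sub
            triggers.append(t_cursor)
            t_cursor += 2.0
    return StimulusMovie(
        frames, frame_rate, pixel_um,
        trigger_times=np.asarray(triggers),
        metadata={"name": "sine_spot", "diams": tuple(diams),
                  "amplitude": amplitude, "repeats": repeats},
    )


def gen_color_spots(
    sizes: tuple[float, ...] = (100.0, 200.0, 400.0, 600.0, 1000.0),
    block_order: tuple[str, ...] = ("W", "V", "G", "W", "G", "V"),
    seed: int = 0,
    frame_rate: float = 10.0,
    field_size_um: tuple[float, float] = (1000.0, 1000.0),
    pixel_um: float = 25.0,
    n_sequences: int = 2,
) -> StimulusMovie:
    """Colored spot flashes in wavelength blocks (W = white, V = UV, G = green).

    Within each block every size is flashed exactly once (1 s flash, 3 s
    pause) in a seeded pseudo-random order that differs across blocks.  With
    the default order repeated twice, each (size, color) pair appears exactly
    four times.  Color is stored per-frame in metadata; frames encode
    intensity only (spectral modelling is out of scope).
    """
    sizes = tuple(sizes)
    if not sizes:
        raise ValueError("sizes must be nonempty")
    if any(c not in {"W", "V", "G"} for c in block_order):
        raise ValueError("block_order entries must be in {W, V, G}")
    rng = np.random.default_rng(seed)
    h = max(1, int(round(field_size_um[0] / pixel_um)))
    w = max(1, int(round(field_size_um[1] / pixel_um)))
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = np.hypot((yy - cy) * pixel_um, (xx - cx) * pixel_um)

    n_flash = int(round(frame_rate))
    n_pause = int(round(3 * frame_rate))
    blocks, triggers, events = [], [], []
    t_cursor = 0.0
    full_order = tuple(block_order) * n_sequences
    for color in full_order:
        order = rng.permutation(len(sizes))
        for idx in order:
            d = sizes[idx]
            mask = r <= d / 2
            flash = np.full((n_flash, h, w), BACKGROUND)
            flash[:, mask] = 1.0
            blocks.append(flash)
            blocks.append(np.full((n_pause, h, w), BACKGROUND))
            triggers.append(t_cursor)
            events.append({"color": color, "size": d, "t_on": t_cursor})
            t_cursor += 4.0
    return StimulusMovie(
        np.concatenate(blocks), frame_rate, pixel_um,
        trigger_times=np.asarray(triggers),
        metadata={"name": "color_spots", "sizes": sizes,
                  "block_order": full_order, "events": events, "seed": seed},
    )


def save_movie(path: str, movie: StimulusMovie, group: str = "stimulus") -> None:
    """Write a movie to HDF5 (frames dataset + scalar attributes)."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("frames", data=movie.frames, compression="gzip")
        g.create_dataset("trigger_times", data=movie.trigger_times)
        g.attrs["frame_rate"] = movie.frame_rate
        g.attrs["pixel_size"] = movie.pixel_size
        g.attrs["name"] = str(movie.metadata.get("name", ""))


def load_movie(path: str, group: str = "stimulus") -> StimulusMovie:
    with h5py.File(path, "r") as f:
        g = f[group]
        return StimulusMovie(
            g["frames"][()], float(g.attrs["frame_rate"]),
            float(g.attrs["pixel_size"]), g["trigger_times"][()],
            metadata={"name": g.attrs.get("name", "")},
        )
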