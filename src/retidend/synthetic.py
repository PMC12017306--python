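"""Synthetic ground-truth data generators.

Everything the downstream pipeline consumes can be generated here with
known ground truth: dendritic morphologies with region-dependent field
size, imaging recordings whose pixel traces arise from planted
center-surround receptive fields passed through a rectifying
nonlinearity, an indicator kernel and noise, and paired
cricket-present/cricket-removed "eye view" scene clips with per-frame
distance labels.

The forward model of :func:`gen_recording` mirrors the analysis
assumptions: a linear spatiotemporal RF drives a common source signal
``max(0, X . F_true)`` that is convolved with a single-exponential
indicator kernel and distributed to the ROI's pixels with independent
noise and a slow additive drift (to exercise detrending).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dog import dog_image
from .morpho import MorphologySkeleton
from .stimuli import StimulusMovie

__all__ = [
    "GroundTruthRF",
    "SyntheticRecording",
    "SceneClip",
    "gen_morphology",
    "temporal_kernel",
    "gen_recording",
    "gen_cricket_scenes",
    "split_dataset",
]


@dataclass
class GroundTruthRF:
    """A planted center-surround RF: DoG spatial profile and temporal kernel.

    ``center_um`` is relative to the stimulus center; the surround
    covariance is ``surround_scale`` (> 1) times the center covariance and
    its amplitude has the opposite sign.  ``kernel`` has unit peak
    magnitude and is defined on ``lag_offsets`` samples (ascending lag)
    at the trace rate.
    """

    center_um: np.ndarray
    cov_um2: np.ndarray
    surround_scale: float
    amp_center: float
    amp_surround: float
    kernel: np.ndarray
    lag_offsets: np.ndarray
    transient: bool = False

    def __post_init__(self):
        if self.surround_scale <= 1:
            raise ValueError("surround covariance scale must exceed 1")
        peak = np.max(np.abs(self.kernel))
        if peak > 0:
            self.kernel = np.asarray(self.kernel, dtype=float) / peak

    def spatial_map(self, shape: tuple[int, int], pixel_um: float) -> np.ndarray:
        return dog_image(shape, pixel_um, self.center_um, self.cov_um2,
                         self.surround_scale, self.amp_center, self.amp_surround)


@dataclass
class SyntheticRecording:
    """An imaging movie with planted ROI and RF ground truth."""

    movie: np.ndarray              # (T, H, W) fluorescence, a.u.
    roi_truth: np.ndarray          # (H, W) int labels, -1 = background
    rf_truth: list[GroundTruthRF]
    stimulus: StimulusMovie
    sampling_rate: float
    pixel_um: float
    sources: np.ndarray = field(default=None)  # (n_roi, T) noiseless sources


def gen_morphology(region: str = "nasal", seed: int = 0,
                   diameter_mean: float | None = None,
                   diameter_sd: float | None = None,
                   n_primary: int = 6, seg_len: float = 12.0,
                   branch_prob: float = 0.22) -> MorphologySkeleton:
    """Random monostratified dendritic tree with region-dependent field size.

    The convex-hull diameter is drawn near 400 um for nasal and 150 um for
    temporal cells (sd 25 and 10 um by default) and the grown tree is
    rescaled in the plane so its hull diameter equals the draw exactly.
    """
    if region not in {"nasal", "temporal"}:
        raise ValueError("region must be 'nasal' or 'temporal'")
    rng = np.random.default_rng(seed)
    if diameter_mean is None:
        diameter_mean = 400.0 if region == "nasal" else 150.0
    if diameter_sd is None:
        diameter_sd = 25.0 if region == "nasal" else 10.0
    target = float(rng.normal(diameter_mean, diameter_sd))

    nodes = [(1, np.zeros(3), 5.0, -1)]
    next_id = 2
    stack = []
    for i in range(n_primary):
        ang = 2 * np.pi * (i + rng.uniform(-0.2, 0.2)) / n_primary
        d = np.array([np.cos(ang), np.sin(ang), 0.0])
        reach = target / 2 * rng.uniform(0.8, 1.0)
        stack.append((1, np.zeros(3), d, reach))
    while stack:
        parent, pos, d, reach = stack.pop()
        ang = np.arctan2(d[1], d[0]) + rng.normal(0, 0.25)
        step = np.array([np.cos(ang), np.sin(ang), 0.0]) * seg_len
        new = pos + step
        new[2] = rng.normal(0, 0.3)  # single stratum, sub-um jitter
        nid = next_id
        next_id += 1
        nodes.append((nid, new, 1.0, parent))
        if np.linalg.norm(new[:2]) < reach:
            stack.append((nid, new, step / seg_len, reach))
            if rng.random() < branch_prob:
                rot = rng.choice([-1, 1]) * rng.uniform(0.5, 1.0)
                c, s = np.cos(rot), np.sin(rot)
                db = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1], 0.0])
                stack.append((nid, new, db,
                              reach * rng.uniform(0.6, 1.0)))

    ids = np.array([n[0] for n in nodes])
    xyz = np.array([n[1] for n in nodes])
    radius = np.array([n[2] for n in nodes])
    parent = np.array([n[3] for n in nodes])
    skel = MorphologySkeleton(ids, xyz, radius, parent, soma_id=1, region=region)
    from .morpho import hull_metrics

    _, d_now = hull_metrics(skel)
    xyz = xyz.copy()
    xyz[:, :2] *= target / d_now
    return MorphologySkeleton(ids, xyz, radius, parent, soma_id=1, region=region)


def temporal_kernel(n_lags: int, sampling_rate: float = 31.25,
                    t_peak: float = 0.15, biphasic_weight: float = 0.0,
                    t_rebound: float = 0.35) -> np.ndarray:
    """Unit-peak temporal kernel over ascending lags 0 .. (n_lags-1)/rate.

    A gamma-like main lobe peaking at ``t_peak``; with
    ``biphasic_weight > 0`` an opposite-sign lobe at ``t_rebound``
    (larger lag = earlier in time) makes the kernel transient.
    """
    tau = np.arange(n_lags) / sampling_rate
    main = (tau / t_peak) * np.exp(1 - tau / t_peak)
    reb = (tau / t_rebound) ** 2 * np.exp(2 - 2 * tau / t_rebound)
    k = main - biphasic_weight * reb
    return k / np.max(np.abs(k))


def _linear_drive(stimulus: StimulusMovie, rf: GroundTruthRF,
                  sampling_rate: float) -> np.ndarray:
    """x(t) = sum_lags k(lag) * <X(t - lag), Fs_true> at the trace rate."""
    n_up = int(round(stimulus.n_frames / stimulus.frame_rate * sampling_rate))
    src = np.minimum((np.arange(n_up) / sampling_rate
                      * stimulus.frame_rate).astype(int), stimulus.n_frames - 1)
    H, W = stimulus.frames.shape[1:]
    fs = rf.spatial_map((H, W), stimulus.pixel_size).ravel()
    frames = stimulus.frames.reshape(stimulus.n_frames, -1) - 0.5
    sp = frames @ fs  # (T0,)
    sp_up = sp[src]
    out = np.zeros(n_up)
    for o, k in zip(rf.lag_offsets, rf.kernel):
        if o >= 0:
            out[o:] += k * sp_up[: n_up - o] if o else k * sp_up
        else:
            out[:o] += k * sp_up[-o:]
    return out


def _default_rfs(n_rois: int, rng: np.random.Generator, n_lags: int,
                 sampling_rate: float) -> list[GroundTruthRF]:
    rfs = []
    for i in range(n_rois):
        sigma = rng.uniform(40.0, 90.0)
        center = rng.uniform(-60, 60, size=2)
        rfs.append(GroundTruthRF(
            center_um=center, cov_um2=np.eye(2) * sigma**2,
            surround_scale=4.0, amp_center=1.0, amp_surround=-0.15,
            kernel=temporal_kernel(n_lags, sampling_rate,
                                   biphasic_weight=0.0),
            lag_offsets=np.arange(n_lags),
        ))
    return rfs


def gen_recording(
    stimulus: StimulusMovie,
    rf_truth: list[GroundTruthRF] | None = None,
    morph: MorphologySkeleton | None = None,
    n_rois: int = 2,
    indicator_tau: float = 0.35,
    noise_sd: float = 0.1,
    drift_amp: float = 0.0,
    seed: int = 0,
    field_shape: tuple[int, int] = (16, 64),
    pixel_um: float = 0.6,
    sampling_rate: float = 31.25,
    roi_n_pixels: int = 9,
    gain: float = 1.0,
) -> SyntheticRecording:
    """Forward-model an imaging movie from planted RFs.

    Every ROI's pixels share one source: the rectified linear drive of its
    planted RF, convolved with a single-exponential indicator kernel
    (``indicator_tau`` s; OGB-1-like for Ca2+, shorter for glutamate).
    Pixels add independent Gaussian noise and, optionally, a slow sinusoidal
    drift.  Background pixels carry noise (and drift) only.
    """
    rng = np.random.default_rng(seed)
    H, W = field_shape
    if rf_truth is None:
        rf_truth = _default_rfs(n_rois, rng, n_lags=15,
                                sampling_rate=sampling_rate)
    n_rois = len(rf_truth)

    # connected ROI pixel blobs, well separated on the field grid
    labels = np.full(field_shape, -1, dtype=int)
    centers = []
    min_sep = max(4, int(np.sqrt(roi_n_pixels)) + 3)
    attempts = 0
    while len(centers) < n_rois and attempts < 2000:
        attempts += 1
        c = (rng.integers(2, H - 2), rng.integers(2, W - 2))
        if all(max(abs(c[0] - a), abs(c[1] - b)) >= min_sep for a, b in centers):
            centers.append(c)
    if len(centers) < n_rois:
        raise ValueError("could not place ROIs with the requested separation")
    for idx, (cy, cx) in enumerate(centers):
        placed = [(cy, cx)]
        labels[cy, cx] = idx
        while len(placed) < roi_n_pixels:
            py, px = placed[rng.integers(len(placed))]
            dy, dx = ((0, 1), (0, -1), (1, 0), (-1, 0))[rng.integers(4)]
            qy, qx = py + dy, px + dx
            if 0 <= qy < H and 0 <= qx < W and labels[qy, qx] == -1:
                labels[qy, qx] = idx
                placed.append((qy, qx))

    n_up = int(round(stimulus.n_frames / stimulus.frame_rate * sampling_rate))
    t = np.arange(n_up) / sampling_rate
    ind = np.exp(-np.arange(int(5 * indicator_tau * sampling_rate) + 1)
                 / (indicator_tau * sampling_rate))
    ind /= ind.sum()

    sources = np.zeros((n_rois, n_up))
    for i, rf in enumerate(rf_truth):
        drive = np.maximum(0.0, _linear_drive(stimulus, rf, sampling_rate))
        sources[i] = np.convolve(drive, ind)[:n_up]

    movie = rng.normal(0.0, noise_sd, size=(n_up, H, W)) if noise_sd > 0 \
        else np.zeros((n_up, H, W))
    if drift_amp > 0:
        drift = drift_amp * np.sin(2 * np.pi * t / (t[-1] + 1e-9) * 1.5)
        movie += drift[:, None, None]
    for i in range(n_rois):
        movie[:, labels == i] += gain * sources[i][:, None]

    return SyntheticRecording(movie, labels, rf_truth, stimulus,
                              sampling_rate, pixel_um, sources=sources)


@dataclass
class SceneClip:
    """A short eye-view clip, optionally containing a cricket.

    Paired present/removed clips share ``pair_id`` and differ only by the
    rendered cricket; ``distance`` (cm per frame) is defined for present
    clips and mirrored onto the removed copy for evaluation.
    """

    frames: np.ndarray             # (T, 395, 395) in [0, 1]
    cricket_present: bool
    distance: np.ndarray | None
    pair_id: int
    split_tag: str = ""


# retinal magnification: ~31 um of retina per degree of visual angle (mouse);
# a cricket of body length `cricket_cm` at distance d cm subtends
# ~ cricket_cm / d radians -> length_px = 31 um/deg * deg / 5 um/px
_UM_PER_DEG = 31.0


def _cricket_length_px(distance_cm: np.ndarray, cricket_cm: float = 2.0,
                       pixel_um: float = 5.0) -> np.ndarray:
    deg = np.degrees(cricket_cm / np.asarray(distance_cm))
    return _UM_PER_DEG * deg / pixel_um


def gen_cricket_scenes(
    n_clips: int = 20,
    distance_range: tuple[float, float] = (4.0, 50.0),
    cricket_cm: float = 2.0,
    cricket_contrast: float = 0.45,
    background_sigma_px: float = 40.0,
    background_contrast: float = 0.12,
    n_frames: int = 4,
    size: int = 395,
    seed: int = 0,
) -> list[SceneClip]:
    """Paired cricket-present / cricket-removed synthetic eye-view clips.

    The background is low-pass-filtered Gaussian noise around mid-gray
    (arena floor texture); the cricket is a dark, Gaussian-blurred ellipse
    whose pixel size follows a small-angle retinal-magnification mapping of
    its distance, which shrinks slightly within a clip as the animal
    approaches.  Clip ``2i`` is the present copy and ``2i+1`` the removed
    copy of pair ``i``.
    """
    if n_clips % 2:
        raise ValueError("n_clips must be even (present/removed pairs)")
    if distance_range[0] <= 0:
        raise ValueError("distances must be positive")
    rng = np.random.default_rng(seed)
    clips = []
    yy, xx = np.mgrid[:size, :size].astype(float)
    for pair in range(n_clips // 2):
        bg0 = gaussian_filter(rng.standard_normal((size, size)),
                              background_sigma_px)
        bg0 = 0.5 + background_contrast * bg0 / (np.std(bg0) + 1e-12)
        shifts = np.cumsum(rng.integers(-2, 3, size=(n_frames, 2)), axis=0)
        bg = np.stack([np.roll(bg0, tuple(s), axis=(0, 1)) for s in shifts])
        bg = np.clip(bg, 0.0, 1.0)

        d0 = rng.uniform(*distance_range)
        dist = d0 * (1.0 - 0.02) ** np.arange(n_frames)
        length_px = _cricket_length_px(dist, cricket_cm)
        cy = rng.uniform(0.25 * size, 0.75 * size)
        cx = rng.uniform(0.25 * size, 0.75 * size)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)

        present = bg.copy()
        for f in range(n_frames):
            a = max(1.0, length_px[f] / 2)          # semi-major, px
            b = max(0.6, 0.4 * a)                   # semi-minor
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
            alpha = gaussian_filter(mask, 1.0)
            dark = bg[f] * (1.0 - cricket_contrast)
            present[f] = bg[f] * (1 - alpha) + dark * alpha
        present = np.clip(present, 0.0, 1.0)

        clips.append(SceneClip(present.astype(np.float32), True,
                               dist.copy(), pair))
        clips.append(SceneClip(bg.astype(np.float32), False,
                               dist.copy(), pair))
    return clips


def split_dataset(clips: list[SceneClip],
                  fractions: tuple[float, float, float] = (0.785, 0.152, 0.063),
                  seed: int = 0) -> list[SceneClip]:
    """Tag clips train/dev/test at the pair level.

    All clips sharing a ``pair_id`` (the cricket-present clip and its
    removed counterpart) always land in the same split.  Fractions must sum
    to 1; splits with nonzero fraction each receive at least one group.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    groups = sorted({c.pair_id for c in clips})
    names = ["train", "dev", "test"]
    n_needed = sum(f > 0 for f in fractions)
    if len(groups) < n_needed:
        raise ValueError("fewer pair groups than nonzero splits")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    counts = np.floor(np.asarray(fractions) * len(groups)).astype(int)
    for k, f in enumerate(fractions):
        if f > 0 and counts[k] == 0:
            counts[k] = 1
    while counts.sum() > len(groups):
        counts[np.argmax(counts)] -= 1
    counts[0] += len(groups) - counts.sum()
    assignment = {}
    i = 0
    for name, cnt in zip(names, counts):
        for j in range(cnt):
            assignment[groups[order[i]]] = name
            i += 1
    for c in clips:
        c.split_tag = assignment[c.pair_id]
    return clips
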