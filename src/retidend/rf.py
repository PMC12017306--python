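"""Spline-based spatiotemporal receptive-field estimation.

A receptive field (RF) F(x, y, tau) is modelled as a linear-Gaussian
response model on a tensor-product cubic B-spline basis.  Given the
rectified trace derivative ``c_dot`` and the dense-noise stimulus ``X``,
the coefficients ``b`` minimize

    L = mean_t ( c_dot(t) - y0 - X(t) . S b )^2 + beta * ||b||_1

where ``S`` is the spline basis evaluated at the stimulus pixel positions
and lag samples, ``y0`` an intercept and ``beta`` an L1 weight enforcing
sparsity.  The problem is solved by proximal gradient descent (soft
thresholding handles the non-smooth L1 term; optional Nesterov
acceleration), with the step size set from a power-iteration estimate of
the curvature, a minimum/maximum step count and early stopping on loss
plateau; the lowest-loss parameters are returned.

The fitted RF is rendered on a configurable ``rf_dims`` grid, decomposed
into temporal and spatial factors by SVD, and summarized by a separability
quality index, a center outline with equivalent-circle diameter, a
surround index and a transience index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import BSpline
from scipy.signal import find_peaks
from shapely.geometry import Polygon
from skimage.measure import find_contours
from sklearn.base import BaseEstimator, RegressorMixin

from .stimuli import StimulusMovie

__all__ = [
    "RFFitConfig",
    "SpatioTemporalRF",
    "RFDesign",
    "SplineRFEstimator",
    "fit_rf",
    "decompose_rf",
    "rf_outline",
    "surround_index_rf",
    "transience_noise",
]


@dataclass(frozen=True)
class RFFitConfig:
    """Hyperparameters of the spline RF fit.

    ``knots`` are the number of B-spline basis functions per axis
    (x, y, tau); defaults are the Ca2+ settings, glutamate uses
    (10, 16, 12).  ``rf_dims`` is the rendering resolution of the fitted
    RF, decoupled from the stimulus grid.  ``lag_range`` is
    (earliest, latest) lag in seconds; a negative earliest lag admits a
    small acausal window.
    """

    knots: tuple[int, int, int] = (10, 12, 9)
    rf_dims: tuple[int, int, int] = (45, 20, 15)
    beta: float = 0.005
    lag_range: tuple[float, float] = (-0.20, 1.35)
    max_steps: int = 2000
    min_steps: int = 100
    patience: int = 5
    tol: float = 1e-6


@dataclass
class SpatioTemporalRF:
    """A fitted RF and its derived summaries.

    ``F`` is indexed (y, x, lag) with the lag axis ascending from the
    earliest (possibly negative/acausal) to the latest lag.  Scaling
    conventions: ``max|Ft| = 1`` and ``max|Fs| = max|F|``; the spatial
    peak of ``Fs`` is positive (ON convention).
    """

    F: np.ndarray
    Ft: np.ndarray
    Fs: np.ndarray
    lags: np.ndarray
    qi_rf: float
    pixel_um: float
    outline: np.ndarray | None = None
    diameter: float | None = None
    si_rf: float | None = None
    tri_noise: float | None = None
    extras: dict = field(default_factory=dict)


def _bspline_basis(n_basis: int, x: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix with clamped, evenly spaced knots on [0, 1]."""
    if n_basis < 4:
        raise ValueError("need at least 4 cubic B-spline basis functions")
    interior = np.linspace(0, 1, n_basis - 2)
    t = np.r_[[0.0] * 3, interior, [1.0] * 3]
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(x, t, 3).toarray()


class RFDesign:
    """Precomputed spline design for one (stimulus, trace-rate, config) triple.

    Building the design and its Gram matrix costs far more than a single
    fit, so when many ROIs share one stimulus presentation the design is
    built once and passed to every :class:`SplineRFEstimator`.
    """

    def __init__(self, stimulus: StimulusMovie, sampling_rate: float,
                 cfg: RFFitConfig):
        self.cfg = cfg
        self.sampling_rate = float(sampling_rate)
        self.pixel_um = stimulus.pixel_size
        self.grid_shape = stimulus.frames.shape[1:]
        H, W = self.grid_shape

        # zero-order-hold upsampling of the stimulus to the trace rate
        n_up = int(round(stimulus.n_frames / stimulus.frame_rate * sampling_rate))
        src = np.minimum(
            (np.arange(n_up) / sampling_rate * stimulus.frame_rate).astype(int),
            stimulus.n_frames - 1,
        )
        frames = stimulus.frames[src].reshape(n_up, H * W)
        frames = frames - frames.mean(axis=0, keepdims=True)

        kx, ky, kt = cfg.knots
        self._By = _bspline_basis(ky, (np.arange(H) + 0.5) / H)
        self._Bx = _bspline_basis(kx, (np.arange(W) + 0.5) / W)
        B_sp = np.einsum("ri,cj->rcij", self._By, self._Bx).reshape(H * W, ky * kx)
        Z = frames @ B_sp  # (T, ky*kx)

        lag_lo, lag_hi = cfg.lag_range
        o_min = int(round(lag_lo * sampling_rate))
        o_max = int(round(lag_hi * sampling_rate))
        self.lag_offsets = np.arange(o_min, o_max + 1)
        self.lags = self.lag_offsets / sampling_rate
        u = ((self.lags - self.lags[0]) / (self.lags[-1] - self.lags[0])
             if len(self.lags) > 1 else np.zeros(1))
        self._Bt_samples = _bspline_basis(kt, u)  # (L, kt)

        # valid times: all lags in range.  t - o must lie in [0, T).
        t_start = max(0, o_max)
        t_stop = n_up + min(0, o_min)
        if t_stop <= t_start:
            raise ValueError("stimulus too short for the requested lag range")
        self.t_slice = slice(t_start, t_stop)
        Tv = t_stop - t_start
        Ks = ky * kx
        D = np.zeros((Tv, Ks, kt))
        for i, o in enumerate(self.lag_offsets):
            D += Z[t_start - o: t_stop - o, :, None] * self._Bt_samples[i]
        self.D = D.reshape(Tv, Ks * kt)
        self._col_mean = self.D.mean(axis=0)
        self.D -= self._col_mean
        self._gram: np.ndarray | None = None
        self._lmax: float | None = None

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = (self.D.T @ self.D) / self.D.shape[0]
        return self._gram

    @property
    def lipschitz(self) -> float:
        """Largest eigenvalue of the Gram matrix, by power iteration."""
        if self._lmax is None:
            rng = np.random.default_rng(0)
            v = rng.standard_normal(self.gram.shape[0])
            for _ in range(50):
                v = self.gram @ v
                v /= np.linalg.norm(v)
            self._lmax = float(v @ self.gram @ v)
        return self._lmax

    def render(self, b: np.ndarray,
               rf_dims: tuple[int, int, int] | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate F = S b on the rf_dims grid; returns (F, lags_render)."""
        kx, ky, kt = self.cfg.knots
        dx, dy, dt = rf_dims or self.cfg.rf_dims
        By = _bspline_basis(ky, (np.arange(dy) + 0.5) / dy)
        Bx = _bspline_basis(kx, (np.arange(dx) + 0.5) / dx)
        Bt = _bspline_basis(kt, np.linspace(0, 1, dt))
        B = b.reshape(ky, kx, kt)
        F = np.einsum("ai,bj,cl,ijl->abc", By, Bx, Bt, B)
        lags = np.linspace(self.lags[0], self.lags[-1], dt)
        return F, lags

    def render_on_stimulus_grid(self, b: np.ndarray) -> np.ndarray:
        """Evaluate the spatial-temporal RF at the stimulus pixels and lag samples."""
        kx, ky, kt = self.cfg.knots
        B = b.reshape(ky, kx, kt)
        return np.einsum("ai,bj,cl,ijl->abc", self._By, self._Bx,
                         self._Bt_samples, B)


class SplineRFEstimator(BaseEstimator, RegressorMixin):
    """Linear-Gaussian RF model on a cubic B-spline basis with L1 penalty.

    Parameters mirror :class:`RFFitConfig`; ``fit`` accepts either a
    :class:`~retidend.stimuli.StimulusMovie` (the design is built
    internally) or a prebuilt :class:`RFDesign` shared across ROIs.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray — spline coefficients b (ky*kx*kt,)
    intercept_ : float — y0
    F_ : ndarray — RF rendered on the rf_dims grid, (dy, dx, dt)
    Ft_, Fs_, qi_rf_ : SVD decomposition and separability index
    loss_history_ : per-step penalized loss
    n_steps_ : steps taken
    """

    def __init__(self, knots=(10, 12, 9), rf_dims=(45, 20, 15), beta=0.005,
                 lag_range=(-0.20, 1.35), max_steps=2000, min_steps=100,
                 patience=5, tol=1e-6, accelerate=True):
        self.knots = knots
        self.rf_dims = rf_dims
        self.beta = beta
        self.lag_range = lag_range
        self.max_steps = max_steps
        self.min_steps = min_steps
        self.patience = patience
        self.tol = tol
        self.accelerate = accelerate

    def _config(self) -> RFFitConfig:
        return RFFitConfig(tuple(self.knots), tuple(self.rf_dims), self.beta,
                           tuple(self.lag_range), self.max_steps,
                           self.min_steps, self.patience, self.tol)

    def fit(self, X, y, sampling_rate: float = 31.25):
        """Fit the RF to a rectified trace derivative.

        Parameters
        ----------
        X : StimulusMovie or RFDesign
        y : ndarray — c_dot at the trace sampling rate, aligned to t = 0
        sampling_rate : float — trace rate in Hz (ignored for RFDesign input)
        """
        cfg = self._config()
        if isinstance(X, RFDesign):
            design = X
            if (design.cfg.knots != cfg.knots
                    or design.cfg.lag_range != cfg.lag_range):
                raise ValueError("RFDesign built with a different basis")
        elif isinstance(X, StimulusMovie):
            design = RFDesign(X, sampling_rate, cfg)
        else:
            raise TypeError("X must be a StimulusMovie or RFDesign")

        y = np.asarray(y, dtype=float)
        yv = y[design.t_slice]
        if len(yv) != design.D.shape[0]:
            raise ValueError(
                f"trace length {len(y)} does not match the stimulus time base "
                f"(expected {design.t_slice.stop} samples)"
            )
        if not np.all(np.isfinite(yv)):
            raise ValueError("non-finite trace values")

        y_mean = yv.mean()
        yc = yv - y_mean
        G, q = design.gram, (design.D.T @ yc) / len(yc)
        c0 = float(yc @ yc) / len(yc)
        L = design.lipschitz
        step = 1.0 / (2.0 * L) if L > 0 else 1.0
        thr = step * cfg.beta

        def loss(bv: np.ndarray) -> float:
            return c0 - 2 * q @ bv + bv @ (G @ bv) + cfg.beta * np.abs(bv).sum()

        b = np.zeros_like(q)
        z, t_mom = b.copy(), 1.0
        best_b, best_loss = b.copy(), loss(b)
        self.loss_history_ = [best_loss]
        stall = 0
        for it in range(cfg.max_steps):
            grad = 2.0 * (G @ z - q)
            b_new = z - step * grad
            b_new = np.sign(b_new) * np.maximum(np.abs(b_new) - thr, 0.0)
            if self.accelerate:
                t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
                z = b_new + (t_mom - 1) / t_new * (b_new - b)
                t_mom = t_new
            else:
                z = b_new
            b = b_new
            cur = loss(b)
            if not np.isfinite(cur):
                raise RuntimeError("divergent loss during RF fit")
            self.loss_history_.append(cur)
            if cur < best_loss - cfg.tol * max(1.0, abs(best_loss)):
                best_loss, best_b = cur, b.copy()
                stall = 0
            else:
                stall += 1
            if it + 1 >= cfg.min_steps and stall >= cfg.patience:
                break

        self.n_steps_ = len(self.loss_history_) - 1
        self.coef_ = best_b
        # design columns are centered, so on the centered design the
        # intercept is simply the trace mean
        self.intercept_ = float(y_mean)
        self.design_ = design
        self.F_, self.lags_ = design.render(best_b, cfg.rf_dims)
        if np.any(self.F_):
            self.Ft_, self.Fs_, self.qi_rf_ = decompose_rf(self.F_)
        else:
            self.Ft_ = np.zeros(self.F_.shape[2])
            self.Fs_ = np.zeros(self.F_.shape[:2])
            self.qi_rf_ = 0.0
        return self

    def predict(self, X=None) -> np.ndarray:
        """Linear prediction y0 + X . S b on the fitted design's time base."""
        design = self.design_ if X is None else X
        if isinstance(X, StimulusMovie):
            design = RFDesign(X, self.design_.sampling_rate, self._config())
        return design.D @ self.coef_ + self.intercept_

    def score(self, X, y) -> float:  # R^2 on the valid time window
        y = np.asarray(y, dtype=float)[self.design_.t_slice]
        pred = self.predict(X if isinstance(X, RFDesign) else None)
        ss = np.sum((y - pred) ** 2)
        return 1.0 - ss / np.sum((y - y.mean()) ** 2)

    def summarize(self) -> SpatioTemporalRF:
        """Package the fitted RF with outline, diameter, SI and TRi."""
        dx = self.F_.shape[1]
        pixel_um = self.design_.pixel_um * self.design_.grid_shape[1] / dx
        rf = SpatioTemporalRF(self.F_, self.Ft_, self.Fs_, self.lags_,
                              self.qi_rf_, pixel_um)
        res = rf_outline(self.Fs_, pixel_um)
        if res is not None:
            rf.outline, rf.diameter = res
            rf.si_rf = surround_index_rf(self.Fs_, rf.outline, pixel_um)
        rf.tri_noise = transience_noise(self.Ft_)
        return rf


def fit_rf(c_dot: np.ndarray, stimulus: StimulusMovie,
           cfg: RFFitConfig | None = None,
           sampling_rate: float = 31.25) -> SplineRFEstimator:
    """Convenience wrapper: fit a :class:`SplineRFEstimator` with `cfg`."""
    cfg = cfg or RFFitConfig()
    est = SplineRFEstimator(knots=cfg.knots, rf_dims=cfg.rf_dims, beta=cfg.beta,
                            lag_range=cfg.lag_range, max_steps=cfg.max_steps,
                            min_steps=cfg.min_steps, patience=cfg.patience,
                            tol=cfg.tol)
    return est.fit(stimulus, c_dot, sampling_rate=sampling_rate)


def decompose_rf(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Separate an RF into temporal and spatial factors by SVD.

    Returns ``(Ft, Fs, qi_rf)`` with ``max|Ft| = 1``,
    ``max|Fs| = max|F|`` and the sign chosen so the spatial peak of Fs is
    positive (ON convention).  ``qi_rf = 1 - Var[F - Ft Fs_svd] / Var[F]``
    measures space-time separability using the unscaled rank-1 term.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("RF contains non-finite values")
    if not np.any(F):
        raise ValueError("all-zero RF cannot be decomposed")
    ny, nx, nt = F.shape
    M = F.reshape(ny * nx, nt)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    rank1 = s[0] * np.outer(u[:, 0], vt[0])
    qi = 1.0 - np.var(M - rank1) / np.var(M)
    fs = u[:, 0] * s[0]
    ft = vt[0]
    if fs[np.argmax(np.abs(fs))] < 0:
        fs, ft = -fs, -ft
    Ft = ft / np.max(np.abs(ft))
    Fs = fs.reshape(ny, nx)
    Fs = Fs * (np.max(np.abs(F)) / np.max(np.abs(Fs)))
    return Ft, Fs, float(qi)


def _closed_contours(zoomed: np.ndarray, level: float) -> list[Polygon]:
    polys = []
    for c in find_contours(zoomed, level):
        if len(c) >= 4 and np.allclose(c[0], c[-1]):
            p = Polygon(c[:, ::-1])  # (row, col) -> (x, y)
            if p.is_valid and p.area > 0:
                polys.append(p)
    return polys


def rf_outline(Fs: np.ndarray, pixel_um: float, upsample: int = 5,
               levels: tuple[float, ...] = (0.25, 0.3, 0.35),
               consistency: float = 0.8) -> tuple[np.ndarray, float] | None:
    """Estimate the RF center outline and equivalent-circle diameter.

    The peak-normalized spatial RF is linearly upsampled by ``upsample``
    and contoured at the given levels.  The fit is accepted only if, at
    every level, a single closed contour covers at least ``consistency``
    of the union area of all contours (a fragmented, multi-lobed map is
    rejected).  On success returns ``(outline, diameter)`` where
    ``outline`` is an (N, 2) polygon in um relative to the map center and
    ``diameter = 2 sqrt(area / pi)``; otherwise returns None.

    The diameter is invariant to positive rescaling of Fs.
    """
    Fs = np.asarray(Fs, dtype=float)
    peak = np.max(np.abs(Fs))
    if peak == 0:
        return None
    norm = Fs / (Fs.flat[np.argmax(np.abs(Fs))])  # peak -> +1
    ny, nx = norm.shape
    # linear upsampling on a regular grid
    from scipy.ndimage import zoom

    zoomed = zoom(norm, upsample, order=1, grid_mode=True, mode="nearest")
    per_level = {lvl: _closed_contours(zoomed, lvl) for lvl in levels}
    if any(not ps for ps in per_level.values()):
        return None
    # at every level a single contour must dominate the union of that
    # level's contours (fragmented multi-lobe maps are rejected)
    for lvl, ps in per_level.items():
        union_area = shapely.union_all(ps).area
        if max(p.area for p in ps) < consistency * union_area:
            return None
    best = max(per_level[levels[0]], key=lambda p: p.area)
    scale = pixel_um / upsample
    xy = np.asarray(best.exterior.coords)
    center = np.array([(nx * upsample - 1) / 2, (ny * upsample - 1) / 2])
    outline_um = (xy - center) * scale
    area_um2 = best.area * scale**2
    diameter = 2.0 * np.sqrt(area_um2 / np.pi)
    return outline_um, float(diameter)


def surround_index_rf(Fs: np.ndarray, outline_um: np.ndarray, pixel_um: float,
                      surround_gap_um: float = 20.0) -> float:
    """Surround index: signed weight of the RF surround relative to the whole RF.

    ``SI = sum(Fs over surround) / sum(|Fs|)`` where the surround is every
    pixel outside the center outline expanded by ``surround_gap_um``.
    Lies in [-1, 1]; a suppressive (sign-opposed) surround gives SI < 0.
    """
    Fs = np.asarray(Fs, dtype=float)
    ny, nx = Fs.shape
    poly = Polygon(outline_um).buffer(surround_gap_um)
    xs = (np.arange(nx) - (nx - 1) / 2) * pixel_um
    ys = (np.arange(ny) - (ny - 1) / 2) * pixel_um
    XX, YY = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, XX.ravel(), YY.ravel()).reshape(ny, nx)
    total = np.sum(np.abs(Fs))
    if total == 0:
        return 0.0
    return float(np.sum(Fs[~inside]) / total)


def transience_noise(Ft: np.ndarray, min_height: float = 0.2) -> float:
    """Transience index of a temporal RF kernel.

    With the lag axis ascending, the main peak is the |Ft| peak at the
    smallest lag and the pre-peak the next |Ft| peak at larger lag (the
    earlier-in-time lobe of a biphasic kernel):
    ``TRi = 2 A_pre / (A_pre + A_main)``.  Monophasic kernels give 0; a
    balanced biphasic kernel gives 1.  Peaks below ``min_height`` of the
    kernel's global magnitude are ignored (spline ripple in fitted
    kernels would otherwise masquerade as response lobes).
    """
    Ft = np.asarray(Ft, dtype=float)
    a = np.abs(Ft)
    if a.max() == 0:
        return 0.0
    peaks, _ = find_peaks(np.r_[0.0, a, 0.0], height=min_height * a.max())
    peaks = peaks - 1
    if len(peaks) == 0:
        return 0.0
    a_main = a[peaks[0]]
    a_pre = a[peaks[1]] if len(peaks) > 1 else 0.0
    if a_main + a_pre == 0:
        return 0.0
    return float(2.0 * a_pre / (a_pre + a_main))
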