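"""Difference-of-Gaussians (DoG) fits to spatial receptive fields.

The DoG models a center-surround RF as the sum of two concentric
Gaussians with opposite-sign amplitudes.  Center and surround share the
mean and the covariance shape; the surround covariance is a scalar
multiple (> 1) of the center covariance.  Per-cluster parameter averages
of good fits become the bipolar-cell kernels of the population encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = ["DoGFit", "DoGFitter", "fit_dog", "dog_image", "build_bc_kernels"]


@dataclass
class DoGFit:
    """Fitted DoG parameters (um units) and fit quality."""

    mean: np.ndarray            # shared center (x, y), um
    cov: np.ndarray             # center covariance, 2x2, um^2
    surround_scale: float       # surround covariance = scale * cov, scale > 1
    amp_center: float
    amp_surround: float         # opposite sign to amp_center
    qi_dog: float
    converged: bool = True


def dog_image(shape: tuple[int, int], pixel_um: float, mean: np.ndarray,
              cov: np.ndarray, surround_scale: float, amp_center: float,
              amp_surround: float) -> np.ndarray:
    """Rasterize a DoG on a (ny, nx) grid with the origin at the grid center.

    Amplitudes are the peak heights of the two (unnormalized) Gaussians.
    """
    ny, nx = shape
    xs = (np.arange(nx) - (nx - 1) / 2) * pixel_um
    ys = (np.arange(ny) - (ny - 1) / 2) * pixel_um
    XX, YY = np.meshgrid(xs, ys)
    d = np.stack([XX - mean[0], YY - mean[1]], axis=-1)
    ci = np.linalg.inv(cov)
    q = np.einsum("...i,ij,...j->...", d, ci, d)
    return amp_center * np.exp(-0.5 * q) + amp_surround * np.exp(
        -0.5 * q / surround_scale)


def _pack(mean, cov, scale, ac, asur):
    sx, sy = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    rho = cov[0, 1] / (sx * sy)
    return np.array([mean[0], mean[1], np.log(sx), np.log(sy),
                     np.arctanh(np.clip(rho, -0.99, 0.99)),
                     np.log(scale - 1.0), ac, asur])


def _unpack(p):
    mean = p[:2]
    sx, sy = np.exp(p[2]), np.exp(p[3])
    rho = np.tanh(p[4])
    cov = np.array([[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]])
    scale = 1.0 + np.exp(p[5])
    return mean, cov, scale, p[6], p[7]


class DoGFitter(BaseEstimator):
    """Least-squares DoG fit to a spatial RF map.

    ``fit(Fs)`` expects a 2D map; ``pixel_um`` sets the grid scale.  The
    covariances of center and surround are tied up to the scalar
    ``surround_scale``; the fit is multi-started on the amplitude sign
    pattern (ON-center and OFF-center initializations).

    Attributes: ``fit_`` (:class:`DoGFit`), ``model_`` (rasterized fit),
    ``qi_dog_``.
    """

    def __init__(self, pixel_um: float = 30.0, max_nfev: int = 2000):
        self.pixel_um = pixel_um
        self.max_nfev = max_nfev

    def fit(self, Fs: np.ndarray, y=None):
        Fs = np.asarray(Fs, dtype=float)
        if Fs.ndim != 2 or not np.all(np.isfinite(Fs)) or not np.any(Fs):
            raise ValueError("Fs must be a finite, nonzero 2D map")
        ny, nx = Fs.shape
        peak_idx = np.unravel_index(np.argmax(np.abs(Fs)), Fs.shape)
        x0 = (peak_idx[1] - (nx - 1) / 2) * self.pixel_um
        y0 = (peak_idx[0] - (ny - 1) / 2) * self.pixel_um
        peak = Fs[peak_idx]
        span = max(nx, ny) * self.pixel_um

        def residual(p):
            mean, cov, scale, ac, asur = _unpack(p)
            return (dog_image(Fs.shape, self.pixel_um, mean, cov, scale,
                              ac, asur) - Fs).ravel()

        best = None
        for sgn in (1.0, -1.0):
            p0 = _pack((x0, y0), np.eye(2) * (span / 8) ** 2, 3.0,
                       sgn * abs(peak), -sgn * 0.3 * abs(peak))
            try:
                sol = least_squares(residual, p0, max_nfev=self.max_nfev)
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("DoG fit failed from every start")

        mean, cov, scale, ac, asur = _unpack(best.x)
        model = dog_image(Fs.shape, self.pixel_um, mean, cov, scale, ac, asur)
        qi = 1.0 - np.var(Fs - model) / np.var(Fs)
        self.fit_ = DoGFit(np.asarray(mean), cov, float(scale), float(ac),
                           float(asur), float(qi), converged=best.success)
        self.model_ = model
        self.qi_dog_ = float(qi)
        return self

    def predict(self, shape: tuple[int, int] | None = None,
                pixel_um: float | None = None) -> np.ndarray:
        f = self.fit_
        if shape is None:
            return self.model_
        return dog_image(shape, pixel_um or self.pixel_um, f.mean, f.cov,
                         f.surround_scale, f.amp_center, f.amp_surround)


def fit_dog(Fs: np.ndarray, pixel_um: float = 30.0) -> DoGFit:
    """Fit a DoG to a spatial RF; returns the :class:`DoGFit`."""
    return DoGFitter(pixel_um=pixel_um).fit(Fs).fit_


def build_bc_kernels(fits_by_cluster: dict[str, list[DoGFit]],
                     qi_min: float = 0.35, size: int = 65,
                     pixel_um: float = 5.0) -> dict[str, np.ndarray]:
    """Average good DoG fits per functional cluster into bipolar-cell kernels.

    Fits with ``qi_dog < qi_min`` are dropped; the remaining parameters
    (mean, covariance entries, surround scale, amplitudes) are averaged in
    parameter space per cluster, rasterized on a ``size x size`` grid at
    ``pixel_um`` centered on the grid (the shared mean is re-centered to
    zero, kernels are translation templates), and scaled so the maximum
    amplitude is one (after averaging).
    """
    kernels = {}
    for name, fits in fits_by_cluster.items():
        good = [f for f in fits if f.qi_dog >= qi_min]
        if not good:
            raise ValueError(f"cluster {name!r} has no fits with QI >= {qi_min}")
        cov = np.mean([f.cov for f in good], axis=0)
        scale = float(np.mean([f.surround_scale for f in good]))
        ac = float(np.mean([f.amp_center for f in good]))
        asur = float(np.mean([f.amp_surround for f in good]))
        k = dog_image((size, size), pixel_um, np.zeros(2), cov, scale, ac, asur)
        kernels[name] = k / np.max(np.abs(k))
    return kernels
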