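"""Population encoder: bipolar-cell (BC) and ganglion-cell (RGC) layers.

The encoder maps a 395 x 395 px (5 um/px) eye-view frame through:

1. two BC populations — weak (w) and strong (s) surround — each a 2D
   convolution with a 65 x 65 DoG kernel at stride 3 (15 um BC spacing),
   giving 2 x (111 x 111) linear activations;
2. a generalized sigmoid nonlinearity ``f(x) = 3 / (1 + 29 exp(-b(x-d)))``
   per population, calibrated so the mean input maps to 0.1 and the mean
   plus one SD to 0.5 responses per frame;
3. additive Gaussian noise (SD sigma = 0.1, fresh per unit and frame);
4. an RGC dendrite layer pooling the channel-weighted sum of the two BC
   populations through a truncated-Gaussian kernel — nasal: 21 x 21 at
   stride 10 (150 um RGC spacing), temporal: 27 x 27 at stride 5 (75 um).

Standard valid-convolution arithmetic cannot produce the normative 9 x 9
(nasal) and 19 x 19 (temporal) RGC grids from a 111-px BC grid, so the BC
grid is symmetrically cropped to 101 px (nasal) or zero-padded to 117 px
(temporal) before pooling; these offsets are recorded on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .dog import dog_image

__all__ = [
    "SigmoidParams",
    "PopulationModel",
    "calibrate_sigmoid",
    "generalized_sigmoid",
    "truncated_gaussian_kernel",
    "default_bc_kernels",
    "build_population_model",
    "bc_linear",
    "encode",
    "RGC_VARIANTS",
]

BC_KERNEL_SIZE = 65
BC_STRIDE = 3          # 15 um at 5 um/px
PIXEL_UM = 5.0

# variant -> (kernel size, stride, (weight_w, weight_s))
# t = temporal RGC spacing/arbor, n = nasal; mi/wi/si = mixed, weak-only,
# strong-only BC input.  The mixed weights are an even split (the measured
# cluster shares are not part of the model parameterization).
RGC_VARIANTS: dict[str, tuple[int, int, tuple[float, float]]] = {
    "t_mi": (27, 5, (0.5, 0.5)),
    "t_wi": (27, 5, (1.0, 0.0)),
    "t_si": (27, 5, (0.0, 1.0)),
    "n_wi": (21, 10, (1.0, 0.0)),
}


@dataclass(frozen=True)
class SigmoidParams:
    b: float
    d: float


def generalized_sigmoid(x: np.ndarray, p: SigmoidParams) -> np.ndarray:
    """f(x) = 3 / (1 + 29 exp(-b (x - d))): range (0, 3), f(d) = 0.1."""
    return 3.0 / (1.0 + 29.0 * np.exp(-p.b * (x - p.d)))


def calibrate_sigmoid(pre_activations: np.ndarray) -> SigmoidParams:
    """Closed-form calibration of the generalized sigmoid.

    Solves ``f(mean) = 0.1`` and ``f(mean + SD) = 0.5``:
    ``d = mean`` (since f(d) = 3/30 = 0.1) and ``b = ln(29/5) / SD``
    (since f(d + SD) = 0.5 requires exp(-b SD) = 5/29).
    """
    x = np.asarray(pre_activations, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty pre-activation sample")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-SD pre-activation sample")
    return SigmoidParams(b=float(np.log(29.0 / 5.0) / sd), d=float(x.mean()))


def truncated_gaussian_kernel(size: int, um_per_unit: float, scale_um: float,
                              cutoff_um: float) -> np.ndarray:
    """2D Gaussian dendritic-pooling kernel, hard-zero beyond the cutoff
    radius, peak normalized to 1."""
    c = (size - 1) / 2
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(yy - c, xx - c) * um_per_unit
    k = np.exp(-r**2 / (2 * scale_um**2))
    k[r > cutoff_um] = 0.0
    return k / k.max()


def default_bc_kernels(size: int = BC_KERNEL_SIZE,
                       pixel_um: float = PIXEL_UM) -> dict[str, np.ndarray]:
    """Stand-in weak/strong-surround BC kernels (peak 1).

    Used when no measured DoG cluster averages are supplied: a 20-um
    center Gaussian (single-BC RF centers are ~40-70 um in diameter) with
    a 4x-covariance surround.  Surround strength is set by the
    surround/center volume ratio (amplitude x covariance scale): ~-0.2
    for the weak and ~-0.85 for the strong population, so the strong
    surround nearly cancels the uniform-field (DC) response while the
    weak one passes most of it.
    """
    cov = np.eye(2) * 20.0**2
    kern = {}
    for name, amp_s in (("w", -0.05), ("s", -0.2125)):
        k = dog_image((size, size), pixel_um, np.zeros(2), cov, 4.0, 1.0, amp_s)
        kern[name] = k / np.max(np.abs(k))
    return kern


@dataclass
class PopulationModel:
    """Full encoder parameterization for one RGC variant."""

    bc_kernels: dict[str, np.ndarray]
    rgc_variant: str
    rgc_kernel: np.ndarray
    rgc_stride: int
    channel_weights: tuple[float, float]
    sigmoid_params: dict[str, SigmoidParams] | None = None
    noise_sd: float = 0.1
    bc_stride: int = BC_STRIDE
    pad_or_crop: int = 0          # >0: zero-pad each side; <0: crop each side
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if any(w < 0 for w in self.channel_weights):
            raise ValueError("channel weights must be >= 0")


def _rgc_geometry(bc_side: int, kernel_size: int, stride: int,
                  target_k: int) -> int:
    """Symmetric pad (>0) or crop (<0) per side of the BC grid that makes a
    valid strided convolution produce exactly ``target_k`` outputs."""
    for adj in range(0, bc_side):
        for sign in (1, -1) if adj else (1,):
            side = bc_side + 2 * sign * adj
            if side >= kernel_size and (side - kernel_size) % stride == 0 \
                    and (side - kernel_size) // stride + 1 == target_k:
                return sign * adj
    raise ValueError("no symmetric pad/crop yields the target grid")


def build_population_model(
    variant: str,
    bc_kernels: dict[str, np.ndarray] | None = None,
    rgc_scale_um: float | None = None,
    rgc_cutoff_um: float | None = None,
    noise_sd: float = 0.1,
    target_k: int | None = None,
) -> PopulationModel:
    """Assemble a :class:`PopulationModel` for one RGC variant.

    ``rgc_scale_um``/``rgc_cutoff_um`` default to plausible population
    means of the hexagonal dendrite-density fits (temporal: 40/85 um,
    nasal: 95/190 um) and can be replaced by measured values from
    :func:`retidend.morpho.hex_density_fit`.
    """
    if variant not in RGC_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    ksize, stride, weights = RGC_VARIANTS[variant]
    um_per_unit = BC_STRIDE * PIXEL_UM     # 15 um between BC units
    if rgc_scale_um is None:
        rgc_scale_um = 40.0 if variant.startswith("t") else 95.0
    if rgc_cutoff_um is None:
        rgc_cutoff_um = 85.0 if variant.startswith("t") else 190.0
    if target_k is None:
        target_k = 19 if variant.startswith("t") else 9
    kern = bc_kernels or default_bc_kernels()
    rgc_k = truncated_gaussian_kernel(ksize, um_per_unit, rgc_scale_um,
                                      rgc_cutoff_um)
    bc_side = (395 - BC_KERNEL_SIZE) // BC_STRIDE + 1   # 111
    adj = _rgc_geometry(bc_side, ksize, stride, target_k)
    return PopulationModel(kern, variant, rgc_k, stride, weights,
                           noise_sd=noise_sd, pad_or_crop=adj,
                           meta={"rgc_scale_um": rgc_scale_um,
                                 "rgc_cutoff_um": rgc_cutoff_um,
                                 "target_k": target_k})


def _conv_stride(frame: np.ndarray, kernel: np.ndarray, stride: int) -> np.ndarray:
    """Valid cross-correlation with stride (RF weighting, no kernel flip)."""
    full = fftconvolve(frame, kernel[::-1, ::-1], mode="valid")
    return full[::stride, ::stride]


def bc_linear(frames: np.ndarray, model: PopulationModel) -> dict[str, np.ndarray]:
    """Linear BC activations per population: (T, 111, 111) each."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1:] != (395, 395):
        raise ValueError("encoder input frames must be 395 x 395")
    out = {}
    for name, k in model.bc_kernels.items():
        out[name] = np.stack([_conv_stride(f, k, model.bc_stride)
                              for f in frames])
    return out


def calibrate_model(model: PopulationModel,
                    frames: np.ndarray) -> PopulationModel:
    """Set each population's sigmoid from its pre-activation statistics on
    the given (training) frames, interior BC units."""
    lin = bc_linear(frames, model)
    model.sigmoid_params = {
        name: calibrate_sigmoid(act[:, 5:-5, 5:-5]) for name, act in lin.items()
    }
    return model


def encode(frames: np.ndarray, model: PopulationModel,
           seed: int | None = None) -> np.ndarray:
    """Encode frames into the RGC population response, (T, k, k).

    BC linear filtering, sigmoid, additive Gaussian noise (fresh per unit
    and frame; deterministic when ``noise_sd = 0``), channel-weighted sum
    of the two BC populations, then truncated-Gaussian pooling at the
    variant's stride on the padded/cropped BC grid.
    """
    if model.sigmoid_params is None:
        raise ValueError("model not calibrated; run calibrate_model first")
    rng = np.random.default_rng(seed)
    lin = bc_linear(frames, model)
    w_w, w_s = model.channel_weights
    combined = None
    for name, weight in (("w", w_w), ("s", w_s)):
        act = generalized_sigmoid(lin[name], model.sigmoid_params[name])
        if model.noise_sd > 0:
            act = act + rng.normal(0.0, model.noise_sd, size=act.shape)
        combined = weight * act if combined is None else combined + weight * act

    adj = model.pad_or_crop
    if adj > 0:
        combined = np.pad(combined, ((0, 0), (adj, adj), (adj, adj)))
    elif adj < 0:
        combined = combined[:, -adj:adj, -adj:adj]
    return np.stack([_conv_stride(f, model.rgc_kernel, model.rgc_stride)
                     for f in combined])
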