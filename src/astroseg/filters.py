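"""Multiscale orientable filter bank.

The bank is the geometric engine shared by cell detection (directional-ratio
maps), post-processing (orientation profiles) and the constrained encoder of
the segmentation network.

Construction
------------
Each directional kernel is an elongated band-pass: an anisotropic Gaussian
(long axis along the kernel orientation, aspect ratio >= 3:1 by default)
minus an isotropic Gaussian at the long-axis scale.  The difference is
exactly zero-mean after a final mean subtraction, L2-normalized, and rotated
to ``n_orientations`` angles covering [0, 180) degrees.  Scale ``j`` doubles
both the kernel support and the Gaussian standard deviations.  The low-pass
member is a unit-sum isotropic Gaussian at the base scale.

Convention: :func:`apply_bank` computes *correlation* with reflect padding.
All directional kernels are symmetric under 180-degree rotation, so the
directional-ratio statistic downstream is unaffected by the
correlation-vs-convolution choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "DirectionalFilterBank",
    "DirectionalResponseStack",
    "build_filter_bank",
    "apply_bank",
]

#: fraction of the kernel support used as the short-axis Gaussian sigma
DEFAULT_SIGMA_FRACTION = 0.05
DEFAULT_ASPECT_RATIO = 3.0


@dataclass(frozen=True)
class DirectionalFilterBank:
    """Indexed family of oriented band-pass kernels plus one low-pass.

    ``kernels[j][l]`` is the 2D kernel at scale ``j`` and orientation
    ``l * angle_step`` degrees.
    """

    n_scales: int
    n_orientations: int
    kernel_size_per_scale: list[int]
    kernels: list[list[np.ndarray]]
    lowpass: np.ndarray
    aspect_ratio: float = DEFAULT_ASPECT_RATIO

    @property
    def angle_step(self) -> float:
        """Angular spacing between consecutive orientations, in degrees."""
        return 180.0 / self.n_orientations

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.arange(self.n_orientations) * self.angle_step

    def half_width(self, scale: int) -> int:
        """Half support of the kernels at ``scale`` (border margin in px)."""
        return self.kernel_size_per_scale[scale] // 2


@dataclass(frozen=True)
class DirectionalResponseStack:
    """Per-scale arrays of shape (n_orientations, rows, cols)."""

    responses: list[np.ndarray]
    bank: DirectionalFilterBank = field(repr=False)

    @property
    def n_scales(self) -> int:
        return len(self.responses)

    def __getitem__(self, scale: int) -> np.ndarray:
        return self.responses[scale]


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    half = size // 2
    y, x = np.mgrid[-half: half + 1, -half: half + 1].astype(float)
    return y, x


def _oriented_kernel(size: int, sigma_short: float, aspect: float,
                     theta_deg: float) -> np.ndarray:
    y, x = _grid(size)
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) + y * np.sin(th)    # along the orientation
    v = -x * np.sin(th) + y * np.cos(th)   # across it
    s_long = aspect * sigma_short
    g = np.exp(-0.5 * ((u / s_long) ** 2 + (v / sigma_short) ** 2))
    g /= g.sum()
    iso = np.exp(-0.5 * (x * x + y * y) / s_long ** 2)
    iso /= iso.sum()
    k = g - iso
    k -= k.mean()          # exact zero mean despite truncation
    k /= np.linalg.norm(k)
    return k


def _lowpass_kernel(size: int, sigma: float) -> np.ndarray:
    y, x = _grid(size)
    g = np.exp(-0.5 * (x * x + y * y) / sigma ** 2)
    return g / g.sum()


def build_filter_bank(
    n_scales: int = 3,
    n_orientations: int = 20,
    base_kernel_size: int = 15,
    aspect_ratio: float = DEFAULT_ASPECT_RATIO,
    sigma_fraction: float = DEFAULT_SIGMA_FRACTION,
) -> DirectionalFilterBank:
    """Build the multiscale orientable bank.

    Parameters
    ----------
    n_scales : number of dyadic scales; support doubles with each scale.
    n_orientations : orientations uniformly covering [0, 180) degrees.
    base_kernel_size : odd support of the finest-scale kernels, >= 5.
    aspect_ratio : long/short axis ratio of the directional kernels.
    sigma_fraction : short-axis sigma as a fraction of the kernel support.
    """
    if n_scales < 1:
        raise ValueError(f"n_scales must be >= 1, got {n_scales}")
    if n_orientations < 2:
        raise ValueError(f"n_orientations must be >= 2, got {n_orientations}")
    if base_kernel_size < 5 or base_kernel_size % 2 == 0:
        raise ValueError(
            f"base_kernel_size must be an odd integer >= 5, got {base_kernel_size}"
        )
    if aspect_ratio < 1.0:
        raise ValueError("aspect_ratio must be >= 1")

    sizes: list[int] = []
    kernels: list[list[np.ndarray]] = []
    angles = 180.0 * np.arange(n_orientations) / n_orientations
    for j in range(n_scales):
        size = base_kernel_size * 2 ** j
        if size % 2 == 0:
            size += 1
        sigma = sigma_fraction * size
        sizes.append(size)
        kernels.append(
            [_oriented_kernel(size, sigma, aspect_ratio, a) for a in angles]
        )
    lowpass = _lowpass_kernel(base_kernel_size,
                              sigma_fraction * base_kernel_size * aspect_ratio)
    return DirectionalFilterBank(
        n_scales=n_scales,
        n_orientations=n_orientations,
        kernel_size_per_scale=sizes,
        kernels=kernels,
        lowpass=lowpass,
        aspect_ratio=aspect_ratio,
    )


def correlate2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size cross-correlation with reflect boundary handling."""
    pad = kernel.shape[0] // 2
    padded = np.pad(image, pad, mode="reflect")
    # correlation == convolution with the flipped kernel
    return fftconvolve(padded, kernel[::-1, ::-1], mode="valid")


def apply_bank(image: np.ndarray,
               bank: DirectionalFilterBank) -> DirectionalResponseStack:
    """Correlate ``image`` with every directional kernel of ``bank``.

    Returns a stack whose entry ``[j][l]`` has the same spatial shape as
    ``image``; boundaries are handled by reflection.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"image must be a non-empty 2D array, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    responses = []
    for row in bank.kernels:
        responses.append(
            np.stack([correlate2d_reflect(image, k) for k in row])
        )
    return DirectionalResponseStack(responses=responses, bank=bank)
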