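"""Shared Fourier-domain helpers: padding and frequency grids.

All Fourier operations in the pipeline (Fresnel propagation, MBA filter,
Fourier Laplacian) run on mirror-padded images to suppress periodic
wrap-around, and use Nyquist-normalized frequency grids so that filter
parameters are resolution-independent.
"""

from __future__ import annotations

import numpy as np

DEFAULT_PAD_FRACTION = 0.25


def pad_widths(shape: tuple[int, ...], pad_fraction: float) -> list[tuple[int, int]]:
    if pad_fraction < 0:
        raise ValueError("pad_fraction must be >= 0")
    return [(int(round(n * pad_fraction)),) * 2 for n in shape]


def pad_mirror(image: np.ndarray, pad_fraction: float) -> np.ndarray:
    """Symmetric (mirror) padding by ``pad_fraction`` of each dimension per side."""
    if pad_fraction == 0:
        return image
    return np.pad(image, pad_widths(image.shape, pad_fraction), mode="reflect")


def crop_center(image: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Crop ``image`` back to ``shape``, undoing :func:`pad_mirror`."""
    slices = []
    for n_pad, n in zip(image.shape, shape):
        lo = (n_pad - n) // 2
        slices.append(slice(lo, lo + n))
    return image[tuple(slices)]


def nyquist_freq_sq(shape: tuple[int, int]) -> np.ndarray:
    """|kappa|^2 grid in Nyquist-normalized units (|kappa| = 1 at Nyquist)."""
    ky = 2.0 * np.fft.fftfreq(shape[0])
    kx = 2.0 * np.fft.fftfreq(shape[1])
    return ky[:, None] ** 2 + kx[None, :] ** 2


def angular_freq_sq(shape: tuple[int, int], pitch: float) -> np.ndarray:
    """|k_perp|^2 grid in angular spatial frequency (rad/length) units."""
    ky = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=pitch)
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=pitch)
    return ky[:, None] ** 2 + kx[None, :] ** 2
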