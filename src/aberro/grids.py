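"""Real- and Fourier-space pixel grids and the package-wide transform convention.

Conventions (fixed throughout the package):

* Real-space grids carry a physical pixel size in Å/px.  The real-space
  origin (centre of the particle/volume) sits at index ``n // 2`` on every
  axis.
* Fourier grids are stored *centred*: the zero-frequency element sits at
  index ``n // 2``, and the element at index ``m`` on an axis of length
  ``n`` represents the frequency ``(m - n//2) / (n * pixel_size)`` in Å⁻¹.
* The forward transform is un-normalised and the inverse divides by N
  (numpy's default), so a forward/inverse round trip is the identity and
  Parseval's theorem holds with a 1/N factor on the frequency side.

Centring both spaces (``ifftshift`` before the FFT, ``fftshift`` after)
means rotations about the box centre act on Fourier grids without extra
checkerboard phase factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageGrid",
    "VolumeGrid",
    "FourierGrid",
    "fft_centered",
    "ifft_centered",
    "freq_axis",
    "freq_grids_2d",
    "shell_radius_grid",
]


@dataclass
class ImageGrid:
    """A 2D real-space image with physical pixel size (Å/px)."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ImageGrid expects 2D data, got shape {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class VolumeGrid:
    """A 3D real-space voxel grid with physical pixel size (Å/px).

    Also used for particle stacks (n_images along axis 0); volumes proper
    are cubic.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid expects 3D data, got shape {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        nz, ny, nx = self.data.shape
        return nz == ny == nx


@dataclass
class FourierGrid:
    """A centred complex frequency-domain grid.

    ``values[m]`` holds the Fourier coefficient at frequency
    ``(m - n//2) / (n * pixel_size)`` Å⁻¹ per axis, where ``pixel_size``
    is the Å/px sampling of the originating real grid.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim


def fft_centered(real: np.ndarray) -> np.ndarray:
    """Forward FFT with both spaces centred (origin at ``n//2``)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(real)))


def ifft_centered(ft: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_centered`; returns a complex array."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(ft)))


def freq_axis(n: int, pixel_size: float) -> np.ndarray:
    """Centred frequency coordinates (Å⁻¹) of one axis of length ``n``."""
    return (np.arange(n) - n // 2) / (n * pixel_size)


def freq_grids_2d(shape: tuple, pixel_size: float):
    """Per-pixel (ky, kx) frequency grids in Å⁻¹ for a centred 2D FT.

    Axis 0 is y, axis 1 is x (numpy row-major).
    """
    ny, nx = shape
    ky = freq_axis(ny, pixel_size)[:, None] * np.ones((1, nx))
    kx = freq_axis(nx, pixel_size)[None, :] * np.ones((ny, 1))
    return ky, kx


def shell_radius_grid(shape: tuple) -> np.ndarray:
    """Per-element radius (in grid units) from the centred Fourier origin."""
    axes = [np.arange(n) - n // 2 for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(m.astype(float) ** 2 for m in mesh))
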