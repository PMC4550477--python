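"""Sensor-grid geometry, spatial-frequency lattices and layered tissue media.

The recording hardware is a regular planar grid of extracellular electrodes
(a Utah-style array) lying on the cut surface of a neocortical slice.  The
coordinate convention used throughout the package is:

* ``x`` — cortical-depth direction within the recording plane; grid column 0
  sits at the pial surface.  Tissue layers are bands in ``x``.
* ``y`` — the along-layer direction within the recording plane.
* ``z`` — the normal, pointing from the recording plane into the slice
  toward the reconstruction plane (``z >= 0``).

Arrays are stored with shape ``(ny, nx)``: rows index ``y``, columns index
``x``.  Lengths are millimetres, spatial frequencies rad/mm, temporal
frequencies rad/s, conductivities S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ArrayGeometry",
    "TissueLayer",
    "MediumModel",
    "ScalarFieldFrame",
    "VectorFieldFrame",
    "KSpaceField",
    "build_frequency_lattice",
    "medium_at_plane",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Regular 2D electrode grid plus its (virtual) upsampling state.

    Parameters
    ----------
    n_x, n_y
        Number of electrode columns / rows of the *raw* grid.
    pitch_mm
        Inter-electrode distance (IED) of the raw grid, in mm.
    upsample_factor
        Integer factor by which virtual electrodes have been inserted
        between real ones (1 = raw grid).  The effective node spacing is
        ``pitch_mm / upsample_factor``.
    """

    n_x: int
    n_y: int
    pitch_mm: float
    upsample_factor: int = 1

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid needs at least 2 electrodes per axis")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        if int(self.upsample_factor) != self.upsample_factor or self.upsample_factor < 1:
            raise ValueError("upsample_factor must be a positive integer")

    @property
    def pitch_eff(self) -> float:
        """Node spacing of the (possibly upsampled) grid in mm."""
        return self.pitch_mm / self.upsample_factor

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of frames on this geometry."""
        return (self.n_y * self.upsample_factor, self.n_x * self.upsample_factor)

    @property
    def nyquist(self) -> float:
        """Nyquist spatial frequency pi / pitch_eff in rad/mm."""
        return np.pi / self.pitch_eff

    @property
    def raw_nyquist(self) -> float:
        """Nyquist frequency of the raw (unupsampled) grid in rad/mm."""
        return np.pi / self.pitch_mm

    def node_x(self) -> np.ndarray:
        """x coordinate (mm) of every node column, length ``shape[1]``."""
        return np.arange(self.shape[1]) * self.pitch_eff

    def node_y(self) -> np.ndarray:
        """y coordinate (mm) of every node row, length ``shape[0]``."""
        return np.arange(self.shape[0]) * self.pitch_eff

    @property
    def extent_x(self) -> float:
        """x extent of the raw grid (distance between outermost columns)."""
        return (self.n_x - 1) * self.pitch_mm

    @property
    def extent_y(self) -> float:
        return (self.n_y - 1) * self.pitch_mm

    def upsampled(self, factor: int) -> "ArrayGeometry":
        """Return the geometry after inserting ``factor - 1`` virtual nodes."""
        if int(factor) != factor or factor < 1:
            raise ValueError("factor must be a positive integer")
        return replace(self, upsample_factor=self.upsample_factor * factor)


def build_frequency_lattice(
    geometry: ArrayGeometry, pad_factor: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Angular spatial-frequency lattice matching the FFT coefficient layout.

    Returns 1D arrays ``(kx, ky)`` in rad/mm, ordered exactly as the
    coefficients of ``numpy.fft.fft2`` over a frame zero-padded by
    ``pad_factor`` per axis.  The lattice spacing is ``2*pi / padded_extent``
    and the largest magnitude equals the grid Nyquist ``pi / pitch_eff``.
    """
    if int(pad_factor) != pad_factor or pad_factor < 1:
        raise ValueError("pad_factor must be a positive integer >= 1")
    ny, nx = geometry.shape
    d = geometry.pitch_eff
    kx = 2.0 * np.pi * np.fft.fftfreq(nx * pad_factor, d=d)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny * pad_factor, d=d)
    return kx, ky


@dataclass(frozen=True)
class TissueLayer:
    """One cortical-depth band with homogeneous electromagnetic properties."""

    x_from_mm: float
    x_to_mm: float
    sigma: float  # conductivity, S/m
    eps_rel: float  # relative permittivity
    mu_rel: float = 1.0  # relative permeability

    def __post_init__(self) -> None:
        if self.x_to_mm <= self.x_from_mm:
            raise ValueError(f"empty layer band [{self.x_from_mm}, {self.x_to_mm})")
        if self.sigma < 0:
            raise ValueError("conductivity must be >= 0")
        if self.eps_rel <= 0 or self.mu_rel <= 0:
            raise ValueError("eps_rel and mu_rel must be > 0")


class MediumConfigurationError(ValueError):
    """Layer bands fail to tile the grid extent."""


@dataclass(frozen=True)
class MediumModel:
    """Layered tissue model: properties are piecewise constant in ``x``.

    The defaults used by the forward simulator and example configs are
    placeholders of physiologically plausible magnitude, not measured
    ground truth.
    """

    layers: tuple[TissueLayer, ...]
    anisotropy_ratio: float = 1.0  # across-/along-layer conductivity ratio

    def __init__(
        self,
        layers: Sequence[TissueLayer],
        anisotropy_ratio: float = 1.0,
    ) -> None:
        object.__setattr__(self, "layers", tuple(sorted(layers, key=lambda l: l.x_from_mm)))
        object.__setattr__(self, "anisotropy_ratio", float(anisotropy_ratio))
        if not self.layers:
            raise MediumConfigurationError("at least one layer is required")
        if self.anisotropy_ratio <= 0:
            raise ValueError("anisotropy_ratio must be > 0")
        prev = self.layers[0]
        for layer in self.layers[1:]:
            if not np.isclose(layer.x_from_mm, prev.x_to_mm, atol=1e-9):
                kind = "gap" if layer.x_from_mm > prev.x_to_mm else "overlap"
                raise MediumConfigurationError(
                    f"{kind} between layer band ending at {prev.x_to_mm} mm and "
                    f"band starting at {layer.x_from_mm} mm"
                )
            prev = layer

    @classmethod
    def uniform(
        cls,
        sigma: float = 0.3,
        eps_rel: float = 1.0e5,
        mu_rel: float = 1.0,
        x_extent_mm: float = 1.0e6,
        anisotropy_ratio: float = 1.0,
    ) -> "MediumModel":
        """Single homogeneous layer covering any grid up to ``x_extent_mm``."""
        layer = TissueLayer(0.0, x_extent_mm, sigma, eps_rel, mu_rel)
        return cls([layer], anisotropy_ratio=anisotropy_ratio)

    def lookup(self, x: float, y: float = 0.0) -> tuple[float, float, float]:
        """Properties ``(sigma, eps_rel, mu_rel)`` at point ``(x, y)``.

        A point on a shared band edge belongs to the deeper band; points
        beyond the last edge use the last band (so the outermost node is
        always covered).
        """
        for layer in self.layers:
            if layer.x_from_mm <= x < layer.x_to_mm:
                return (layer.sigma, layer.eps_rel, layer.mu_rel)
        last = self.layers[-1]
        if x >= last.x_to_mm - 1e-9 or np.isclose(x, last.x_to_mm):
            return (last.sigma, last.eps_rel, last.mu_rel)
        raise MediumConfigurationError(
            f"point x={x} mm lies before the first layer band "
            f"(starts at {self.layers[0].x_from_mm} mm)"
        )

    def check_covers(self, geometry: ArrayGeometry) -> None:
        """Raise if the layer bands do not cover the grid's x extent."""
        if self.layers[0].x_from_mm > 0 + 1e-9:
            raise MediumConfigurationError(
                f"first band starts at {self.layers[0].x_from_mm} mm > 0 (grid origin)"
            )
        if self.layers[-1].x_to_mm < geometry.extent_x - 1e-9:
            raise MediumConfigurationError(
                f"last band ends at {self.layers[-1].x_to_mm} mm, before the grid "
                f"extent {geometry.extent_x} mm"
            )


def medium_at_plane(
    medium: MediumModel, geometry: ArrayGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node ``(sigma, eps_rel, mu_rel)`` maps aligned with the grid.

    Each node is assigned the band containing its centre coordinate;
    maps are piecewise constant across layer boundaries.
    """
    medium.check_covers(geometry)
    ny, nx = geometry.shape
    xs = geometry.node_x()
    sigma_row = np.empty(nx)
    eps_row = np.empty(nx)
    mu_row = np.empty(nx)
    for i, x in enumerate(xs):
        sigma_row[i], eps_row[i], mu_row[i] = medium.lookup(x)
    tile = lambda row: np.tile(row, (ny, 1))
    return tile(sigma_row), tile(eps_row), tile(mu_row)


def _check_shape(values: np.ndarray, geometry: ArrayGeometry) -> np.ndarray:
    values = np.asarray(values)
    if values.shape[-2:] != geometry.shape:
        raise ValueError(
            f"value array shape {values.shape} does not match geometry {geometry.shape}"
        )
    return values


@dataclass
class ScalarFieldFrame:
    """Complex scalar field sampled on the grid at one time or frequency."""

    values: np.ndarray
    geometry: ArrayGeometry
    plane_z: float = 0.0  # mm; 0 = recording plane
    label: str = "potential"

    def __post_init__(self) -> None:
        self.values = _check_shape(self.values, self.geometry)

    def copy(self) -> "ScalarFieldFrame":
        return ScalarFieldFrame(self.values.copy(), self.geometry, self.plane_z, self.label)


@dataclass
class VectorFieldFrame:
    """Three-component complex field (x, y, z/normal) on the grid."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    geometry: ArrayGeometry
    plane_z: float = 0.0
    label: str = "E"

    def __post_init__(self) -> None:
        self.x = _check_shape(self.x, self.geometry)
        self.y = _check_shape(self.y, self.geometry)
        self.z = _check_shape(self.z, self.geometry)

    @property
    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.x, self.y, self.z)

    def magnitude(self) -> np.ndarray:
        """Euclidean magnitude of the complex 3-vector per node."""
        return np.sqrt(sum(np.abs(c) ** 2 for c in self.components))


@dataclass
class KSpaceField:
    """Spatial-Fourier representation of a frame with its (kx, ky) lattice."""

    coeffs: np.ndarray  # complex, FFT layout, possibly padded
    kx: np.ndarray  # 1D, rad/mm, FFT order
    ky: np.ndarray
    prepad_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coeffs.shape != (len(self.ky), len(self.kx)):
            raise ValueError("coefficient shape does not match the (ky, kx) lattice")
        if self.prepad_shape is None:
            self.prepad_shape = self.coeffs.shape
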