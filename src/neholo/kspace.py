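"""Complex wavenumbers, the plane-to-plane k-space propagator and filter.

The holographic step works in the spatial-frequency (k-) domain: a field
frame is Fourier transformed over the grid, multiplied nodewise by a
propagator ``Gz = exp(-i kz z)`` and a smooth band-limiting filter, and
transformed back.  In conductive tissue the characteristic wavenumber is
complex, ``k = omega * sqrt(mu * eps_hat)`` with
``eps_hat = eps + i sigma / omega``; at the temporal frequencies of slow
cortical rhythms ``|k|`` is tiny compared with the array's spatial
frequencies, so nearly every lattice mode is evanescent (near-field) and
``Gz`` is essentially a pure exponential decay ``exp(-kr z)``.

Branch convention for ``kz``: the principal square root of ``k^2 - kr^2``
is reflected into the closed lower half-plane (``Im kz <= 0``).  In the
lossless limit this reproduces the real far-field branch and the
``-i sqrt(kr^2 - k^2)`` near-field branch exactly, and it guarantees
``|Gz| <= 1`` for every mode and every ``z >= 0`` — propagation never
amplifies.  Back-projection to the reconstruction plane uses the same
decaying propagator; the resolution/noise trade-off is controlled entirely
by the filter parameters ``(kc, alpha)``, not by exponential amplification
of evanescent content.

The FFT pair is numpy's; relative to the analysis convention with forward
kernel ``exp(+i k.x)`` this maps ``k -> -k`` on the lattice.  All even
spectral multipliers (``Gz``, the filter) are unaffected; the odd
cross-product operator in the magnetic-field estimate changes sign, which
only flips the (arbitrary-units) sign of H and S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ArrayGeometry, KSpaceField, ScalarFieldFrame, VectorFieldFrame, build_frequency_lattice

__all__ = [
    "EPS0",
    "MU0",
    "WavenumberSet",
    "KSpaceFilter",
    "Propagator",
    "complex_permittivity",
    "characteristic_wavenumber",
    "normal_wavenumber",
    "kspace_filter",
    "all_pass_filter",
    "propagate",
    "propagate_values",
    "propagate_vector",
    "forward_transform",
    "inverse_transform",
]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
MU0 = 1.25663706212e-6  # vacuum permeability, H/m


def complex_permittivity(sigma: float, eps: float, omega: float) -> complex:
    """Lossy permittivity ``eps_hat = eps * (1 + i sigma/(omega eps))``.

    Scale-agnostic: pass absolute permittivity to obtain the absolute
    lossy permittivity.  ``omega`` must be positive (DC has no finite
    loss tangent).
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return eps + 1j * sigma / omega


def characteristic_wavenumber(eps_hat: complex, mu: float, omega: float) -> complex:
    """``k = omega * sqrt(mu * eps_hat)``, principal branch (``Re k >= 0``)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return omega * np.sqrt(mu * eps_hat + 0j)


def normal_wavenumber(
    k: complex, kx: np.ndarray, ky: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node normal wavenumber ``kz`` and far-field branch flags.

    ``kz = sqrt(k^2 - kx^2 - ky^2)`` reflected to ``Im kz <= 0`` so the
    propagator decays; nodes with ``kx^2 + ky^2 <= |k|^2`` are flagged
    far-field (propagating), the rest near-field (evanescent).
    """
    kx = np.asarray(kx)
    ky = np.asarray(ky)
    kr2 = kx[None, :] ** 2 + ky[:, None] ** 2
    kz = np.sqrt(k**2 - kr2 + 0j)
    kz = np.where(kz.imag > 0, np.conj(kz), kz)
    far_field = kr2 <= np.abs(k) ** 2
    return kz, far_field


@dataclass(frozen=True)
class WavenumberSet:
    """Wavenumbers of one homogeneous plane at one temporal frequency."""

    omega: float  # rad/s
    k: complex  # characteristic wavenumber, rad/mm
    kz: np.ndarray  # complex, per (ky, kx) node, rad/mm
    far_field: np.ndarray  # bool per node
    kx: np.ndarray  # 1D lattice, rad/mm
    ky: np.ndarray

    @classmethod
    def from_medium(
        cls,
        sigma: float,
        eps_rel: float,
        mu_rel: float,
        omega: float,
        kx: np.ndarray,
        ky: np.ndarray,
        anisotropy_ratio: float = 1.0,
    ) -> "WavenumberSet":
        """Build wavenumbers from tissue properties (SI) on a rad/mm lattice.

        Relative permittivity/permeability are scaled by the vacuum
        constants here; the across-layer anisotropy ratio enters as a
        scalar rescaling of the conductivity.
        """
        eps_hat = complex_permittivity(sigma * anisotropy_ratio, eps_rel * EPS0, omega)
        k_si = characteristic_wavenumber(eps_hat, mu_rel * MU0, omega)  # rad/m
        k = k_si * 1e-3  # rad/mm
        kz, far = normal_wavenumber(k, kx, ky)
        return cls(omega=omega, k=k, kz=kz, far_field=far, kx=np.asarray(kx), ky=np.asarray(ky))

    @classmethod
    def for_geometry(
        cls,
        geometry: ArrayGeometry,
        sigma: float,
        eps_rel: float,
        mu_rel: float,
        omega: float,
        pad_factor: int = 1,
        anisotropy_ratio: float = 1.0,
    ) -> "WavenumberSet":
        kx, ky = build_frequency_lattice(geometry, pad_factor)
        return cls.from_medium(sigma, eps_rel, mu_rel, omega, kx, ky, anisotropy_ratio)

    def propagator(self, z: float) -> "Propagator":
        if z < 0:
            raise ValueError("propagation distance z must be >= 0")
        return Propagator(z=z, gain=np.exp(-1j * self.kz * z))


@dataclass(frozen=True)
class Propagator:
    """Diagonal k-space operator ``Gz = exp(-i kz z)`` for one distance."""

    z: float  # mm
    gain: np.ndarray  # complex per node, |gain| <= 1


@dataclass(frozen=True)
class KSpaceFilter:
    """Smooth low-pass gain over radial spatial frequency.

    ``gain = 1 - 0.5 exp((kr/kc - 1)/alpha)`` for ``kr <= kc`` and
    ``0.5 exp((1 - kr/kc)/alpha)`` beyond; continuous (value 0.5) at the
    cutoff, bounded in [0, 1], monotone decaying past ``kc``.
    """

    kc: float  # cutoff, rad/mm
    alpha: float  # dimensionless roll-off steepness
    gain: np.ndarray  # per (ky, kx) node, in [0, 1]


def kspace_filter(kx: np.ndarray, ky: np.ndarray, kc: float, alpha: float) -> KSpaceFilter:
    """Evaluate the band-limiting filter on an FFT-ordered lattice."""
    if kc <= 0:
        raise ValueError("kc must be > 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    kx = np.asarray(kx)
    ky = np.asarray(ky)
    kr = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
    r = kr / kc
    with np.errstate(over="ignore"):
        gain = np.where(
            r <= 1.0,
            1.0 - 0.5 * np.exp(np.minimum((r - 1.0) / alpha, 0.0)),
            0.5 * np.exp(np.minimum((1.0 - r) / alpha, 0.0)),
        )
    return KSpaceFilter(kc=kc, alpha=alpha, gain=gain)


def all_pass_filter(kx: np.ndarray, ky: np.ndarray) -> KSpaceFilter:
    """Unit-gain filter (used by the forward simulator)."""
    gain = np.ones((len(np.asarray(ky)), len(np.asarray(kx))))
    return KSpaceFilter(kc=np.inf, alpha=np.inf, gain=gain)


# ---------------------------------------------------------------------------
# spatial transforms


def forward_transform(frame: ScalarFieldFrame, pad_factor: int = 1) -> KSpaceField:
    """Zero-padded 2D FFT of a frame, with its frequency lattice."""
    kx, ky = build_frequency_lattice(frame.geometry, pad_factor)
    ny, nx = frame.geometry.shape
    padded = np.zeros((ny * pad_factor, nx * pad_factor), dtype=complex)
    padded[:ny, :nx] = frame.values
    return KSpaceField(coeffs=np.fft.fft2(padded), kx=kx, ky=ky, prepad_shape=(ny, nx))


def inverse_transform(ks: KSpaceField) -> np.ndarray:
    """Inverse 2D FFT, cropped back to the pre-padding shape."""
    ny, nx = ks.prepad_shape
    return np.fft.ifft2(ks.coeffs)[..., :ny, :nx]


def propagate_values(
    values: np.ndarray,
    z: float,
    wavenumbers: WavenumberSet,
    filt: KSpaceFilter | None = None,
    pad_factor: int = 1,
) -> np.ndarray:
    """Propagate a frame (or a leading-dimension stack of frames) by ``z`` mm.

    Per frame: remove the spatial mean, zero-pad by ``pad_factor`` per
    axis, FFT, multiply nodewise by ``Gz`` and the filter gain, inverse
    FFT, crop, and restore the mean.  Mean removal keeps the padding
    unbiased; the DC term therefore bypasses the propagator.
    """
    values = np.asarray(values)
    if z < 0:
        raise ValueError("z must be >= 0 (propagation direction is fixed)")
    if int(pad_factor) != pad_factor or pad_factor < 1:
        raise ValueError("pad_factor must be a positive integer")
    ny, nx = values.shape[-2:]
    padded_shape = (ny * pad_factor, nx * pad_factor)
    if wavenumbers.kz.shape != padded_shape:
        raise ValueError(
            f"wavenumber lattice {wavenumbers.kz.shape} does not match the "
            f"padded frame shape {padded_shape}"
        )
    mult = wavenumbers.propagator(z).gain
    if filt is not None:
        if filt.gain.shape != padded_shape:
            raise ValueError("filter lattice does not match the padded frame shape")
        mult = mult * filt.gain

    mean = values.mean(axis=(-2, -1), keepdims=True)
    v = values - mean
    padded = np.zeros(values.shape[:-2] + padded_shape, dtype=complex)
    padded[..., :ny, :nx] = v
    spec = np.fft.fft2(padded, axes=(-2, -1))
    out = np.fft.ifft2(spec * mult, axes=(-2, -1))[..., :ny, :nx]
    return out + mean


def propagate(
    frame: ScalarFieldFrame,
    z: float,
    wavenumbers: WavenumberSet,
    filt: KSpaceFilter | None = None,
    pad_factor: int = 1,
) -> ScalarFieldFrame:
    """Propagate a scalar frame to the plane ``plane_z + z``."""
    out = propagate_values(frame.values, z, wavenumbers, filt, pad_factor)
    return ScalarFieldFrame(out, frame.geometry, frame.plane_z + z, frame.label)


def propagate_vector(
    frame: VectorFieldFrame,
    z: float,
    wavenumbers: WavenumberSet,
    filt: KSpaceFilter | None = None,
    pad_factor: int = 1,
) -> VectorFieldFrame:
    """Component-wise propagation of a vector frame."""
    comps = [propagate_values(c, z, wavenumbers, filt, pad_factor) for c in frame.components]
    return VectorFieldFrame(*comps, geometry=frame.geometry, plane_z=frame.plane_z + z, label=frame.label)
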