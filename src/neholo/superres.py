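"""Papoulis-Gerchberg band-limited interpolation of array frames.

Virtual electrodes are inserted between the real ones by alternating two
projections: (a) onto the set of fine-grid frames that agree with the
measured samples, and (b) onto the set of frames whose spectrum is
confined to the chosen band.  For a signal that is genuinely band-limited
below the raw-grid Nyquist frequency the iteration converges to the unique
consistent fine-grid signal; real recordings additionally contain noise
and above-band content, for which the iteration settles to a band-limited
least-change compromise while the measured nodes are re-imposed exactly
after the final pass.

The transforms are periodic (FFT) — the fine grid spans the raw grid's
periodic extent, so the last ``factor - 1`` columns/rows extrapolate
beyond the outermost electrodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .geometry import ArrayGeometry, ScalarFieldFrame, build_frequency_lattice

__all__ = ["SamplingMask", "PGResult", "pg_interpolate", "pg_interpolate_values", "downsample"]


@dataclass(frozen=True)
class SamplingMask:
    """Fine-grid boolean mask marking real-measurement nodes."""

    mask: np.ndarray  # bool (ny_fine, nx_fine)
    upsample_factor: int

    @classmethod
    def regular(cls, raw_shape: tuple[int, int], factor: int) -> "SamplingMask":
        ny, nx = raw_shape
        mask = np.zeros((ny * factor, nx * factor), dtype=bool)
        mask[::factor, ::factor] = True
        return cls(mask=mask, upsample_factor=factor)


@dataclass
class PGResult:
    """Interpolated values plus convergence diagnostics."""

    values: np.ndarray
    converged: bool
    n_iter: int
    residuals: np.ndarray  # L2 mismatch to known samples, one entry per iteration


def _band_mask(
    geometry_fine: ArrayGeometry, band_limit: float
) -> np.ndarray:
    kx, ky = build_frequency_lattice(geometry_fine, pad_factor=1)
    tol = 1.0 + 1e-9
    return (np.abs(kx)[None, :] <= band_limit * tol) & (np.abs(ky)[:, None] <= band_limit * tol)


def pg_interpolate_values(
    raw: np.ndarray,
    pitch_mm: float,
    upsample_factor: int,
    band_limit: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> PGResult:
    """Papoulis-Gerchberg interpolation of ``(..., ny, nx)`` raw frames.

    ``band_limit`` is the separable half-band in rad/mm retained along
    each axis (default: the raw-grid Nyquist ``pi / pitch_mm``, the
    information-theoretic ceiling of the measurement).  Leading dimensions
    (e.g. time) are interpolated jointly frame-by-frame with a pooled
    convergence criterion.
    """
    raw = np.asarray(raw)
    if int(upsample_factor) != upsample_factor or upsample_factor < 1:
        raise ValueError("upsample_factor must be a positive integer")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    raw_nyquist = np.pi / pitch_mm
    if band_limit is None:
        band_limit = raw_nyquist
    if band_limit > raw_nyquist * (1 + 1e-9):
        raise ValueError(
            f"band_limit {band_limit:g} rad/mm exceeds the raw-grid Nyquist "
            f"{raw_nyquist:g} rad/mm"
        )
    if upsample_factor == 1:
        return PGResult(values=raw.astype(complex).copy(), converged=True, n_iter=0,
                        residuals=np.zeros(0))

    ny, nx = raw.shape[-2:]
    f = upsample_factor
    fine_geom = ArrayGeometry(nx, ny, pitch_mm).upsampled(f)
    band = _band_mask(fine_geom, band_limit)
    mask = SamplingMask.regular((ny, nx), f).mask

    # initial estimate: band-limited projection of the gain-compensated
    # zero-filled frame — exact for strictly in-band signals, so the
    # iterations only have to correct out-of-band/noise content
    x = np.zeros(raw.shape[:-2] + mask.shape, dtype=complex)
    x[..., ::f, ::f] = raw
    x *= f**2
    spec0 = np.fft.fft2(x, axes=(-2, -1))
    spec0 *= band
    x = np.fft.ifft2(spec0, axes=(-2, -1))
    raw_norm = np.linalg.norm(raw)
    residuals = []
    converged = False
    prev = None
    it = 0
    for it in range(1, max_iter + 1):
        # projection onto the measurement-consistent set
        x[..., ::f, ::f] = raw
        # projection onto the band-limited set
        spec = np.fft.fft2(x, axes=(-2, -1))
        spec *= band
        x = np.fft.ifft2(spec, axes=(-2, -1))
        residuals.append(float(np.linalg.norm(x[..., ::f, ::f] - raw)))
        if prev is not None:
            change = float(np.linalg.norm(x - prev))
            if change <= tol * max(np.linalg.norm(prev), raw_norm, 1e-300):
                converged = True
                break
        prev = x.copy()
    if not converged and max_iter > 1:
        warnings.warn(
            f"Papoulis-Gerchberg iteration did not converge in {max_iter} iterations "
            f"(last sample residual {residuals[-1]:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    # final enforcement: measured nodes are exact in the output
    x[..., ::f, ::f] = raw
    return PGResult(values=x, converged=converged, n_iter=it, residuals=np.asarray(residuals))


def pg_interpolate(
    raw_frame: ScalarFieldFrame,
    upsample_factor: int,
    band_limit: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ScalarFieldFrame:
    """Interpolate a raw frame onto a grid ``upsample_factor`` times finer.

    The returned frame keeps the raw pitch with an increased geometry
    ``upsample_factor``; its ``pg_converged`` attribute carries the
    convergence flag.
    """
    res = pg_interpolate_values(
        raw_frame.values,
        raw_frame.geometry.pitch_eff,
        upsample_factor,
        band_limit=band_limit,
        max_iter=max_iter,
        tol=tol,
    )
    out = ScalarFieldFrame(
        res.values,
        raw_frame.geometry.upsampled(upsample_factor),
        raw_frame.plane_z,
        raw_frame.label,
    )
    out.pg_converged = res.converged  # type: ignore[attr-defined]
    return out


def downsample(frame: ScalarFieldFrame, step: int) -> ScalarFieldFrame:
    """Keep every ``step``-th node along both axes (node (0, 0) retained)."""
    if int(step) != step or step < 1:
        raise ValueError("step must be a positive integer")
    if step == 1:
        return frame.copy()
    g = frame.geometry
    if g.upsample_factor != 1:
        raise ValueError("downsample expects a raw (unupsampled) frame")
    values = frame.values[::step, ::step]
    ny, nx = values.shape
    coarse = ArrayGeometry(nx, ny, g.pitch_mm * step)
    return ScalarFieldFrame(values, coarse, frame.plane_z, frame.label)
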