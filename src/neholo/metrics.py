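"""Map-level diagnostics: peak finding, focus contrast, blob width, SNR.

These quantify the focusing behaviour of the reconstruction: where the
energy-source-density map peaks, how sharp a source blob is (full width
at half maximum of its radial profile), how clearly two sources separate
(peak-to-valley contrast), and how far the map stands above its noise
background.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "find_peaks_2d",
    "two_peak_contrast",
    "radial_fwhm",
    "peak_background_snr",
]


def find_peaks_2d(
    values: np.ndarray, rel_threshold: float = 0.5, min_distance: int = 1
) -> list[tuple[int, int, float]]:
    """Local maxima of a real 2D map above ``rel_threshold * max``.

    Returns ``(iy, ix, value)`` triples sorted by decreasing value.  A
    node is a peak when it equals the maximum of its
    ``(2 min_distance + 1)``-square neighbourhood.
    """
    values = np.asarray(values, dtype=float)
    size = 2 * min_distance + 1
    local_max = values == ndimage.maximum_filter(values, size=size, mode="nearest")
    # plateau tie-break: keep one representative per connected plateau
    labelled, n = ndimage.label(local_max & (values >= rel_threshold * values.max()))
    peaks = []
    for idx in ndimage.center_of_mass(values, labelled, range(1, n + 1)):
        iy, ix = int(round(idx[0])), int(round(idx[1]))
        peaks.append((iy, ix, float(values[iy, ix])))
    peaks.sort(key=lambda p: -p[2])
    return peaks


def two_peak_contrast(
    values: np.ndarray,
    peak_a: tuple[int, int],
    peak_b: tuple[int, int],
    exclude_radius: int = 4,
) -> float:
    """Joint dominance of two known peaks over the rest of the map.

    ``min(value at the two peak nodes) / max(value elsewhere)``, where
    "elsewhere" excludes a disc of ``exclude_radius`` pixels around each
    peak.  The ratio drops when either blob fades (defocus toward depth),
    when the blobs blur into the space between them, or when a too-sharp
    reconstruction fractures into structure away from the sources.
    """
    values = np.asarray(values, dtype=float)
    yy, xx = np.mgrid[: values.shape[0], : values.shape[1]]
    bg = np.ones(values.shape, dtype=bool)
    for iy, ix in (peak_a, peak_b):
        bg &= (yy - iy) ** 2 + (xx - ix) ** 2 > exclude_radius**2
    background = values[bg].max()
    if background == 0:
        return np.inf
    return float(min(values[peak_a], values[peak_b]) / background)


def radial_fwhm(
    values: np.ndarray, peak: tuple[int, int] | None = None, n_theta: int = 48
) -> float:
    """Full width at half maximum of the radial profile around a peak, in pixels.

    The profile is averaged over ``n_theta`` directions with bilinear
    interpolation; the half-max crossing radius is located by linear
    interpolation, so the width varies continuously with the map.
    """
    values = np.asarray(values, dtype=float)
    if peak is None:
        peak = tuple(np.unravel_index(np.argmax(values), values.shape))  # type: ignore[assignment]
    iy, ix = peak
    peak_val = values[iy, ix]
    r_max = int(min(iy, ix, values.shape[0] - 1 - iy, values.shape[1] - 1 - ix))
    if r_max < 1:
        raise ValueError("peak too close to the map edge for a radial profile")
    radii = np.arange(0, r_max + 1, 0.25)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    ys = iy + np.outer(radii, np.sin(theta))
    xs = ix + np.outer(radii, np.cos(theta))
    samples = ndimage.map_coordinates(values, np.vstack([ys.ravel(), xs.ravel()]), order=1)
    profile = samples.reshape(len(radii), n_theta).mean(axis=1)
    half = 0.5 * peak_val
    below = np.nonzero(profile < half)[0]
    if len(below) == 0:
        return float(2 * radii[-1])  # never drops below half max within range
    j = below[0]
    if j == 0:
        return 0.0
    r_lo, r_hi = radii[j - 1], radii[j]
    p_lo, p_hi = profile[j - 1], profile[j]
    r_half = r_lo + (p_lo - half) / (p_lo - p_hi) * (r_hi - r_lo)
    return float(2 * r_half)


def peak_background_snr(
    values: np.ndarray,
    peaks: list[tuple[int, int]] | None = None,
    exclude_radius: int = 3,
) -> float:
    """Peak value over background RMS, excluding peak neighbourhoods.

    Background nodes are those farther than ``exclude_radius`` pixels
    from every listed peak (default: the global maximum).
    """
    values = np.asarray(values, dtype=float)
    if peaks is None:
        peaks = [tuple(np.unravel_index(np.argmax(values), values.shape))]  # type: ignore[list-item]
    yy, xx = np.mgrid[: values.shape[0], : values.shape[1]]
    bg = np.ones(values.shape, dtype=bool)
    peak_val = -np.inf
    for iy, ix in peaks:
        bg &= (yy - iy) ** 2 + (xx - ix) ** 2 > exclude_radius**2
        peak_val = max(peak_val, values[iy, ix])
    rms = float(np.sqrt(np.mean(values[bg] ** 2))) if bg.any() else np.nan
    if rms == 0:
        return np.inf
    return float(peak_val / rms)
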