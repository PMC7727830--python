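"""The SERDS arithmetic: difference, reconstruction, baseline, axes, metrics.

The difference spectrum D = S(lambda1) - S(lambda2) is formed channel-wise on
the detector grid (both spectra live on the same pixels, so no resampling is
needed).  Because the lambda2 rendering of a band sits ``delta`` channels to
the red of the lambda1 rendering, D(x) = S(x) - S(x - delta), and the running
(cumulative) sum of D telescopes into a delta-channel moving-window sum of S:
a broadened but background-free reconstruction of the Raman spectrum.  The
reconstruction step itself introduces a slowly varying pedestal, which is
removed afterwards with the SNIP clipping algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import SpectralAxis, wavelength_to_raman_shift
from .reduction import DataCube

__all__ = [
    "DifferenceCube",
    "ReconstructedCube",
    "subtract_pairs",
    "reconstruct_cumulative",
    "reconstruct_cube",
    "snip_baseline",
    "snip_cube",
    "to_relative_wavenumber",
    "residual_background_metric",
]


@dataclass
class DifferenceCube:
    """Per-spaxel SERDS difference spectra (lambda1 minus lambda2)."""

    axis: SpectralAxis
    data: np.ndarray
    mask: np.ndarray
    provenance: dict

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def spectra(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class ReconstructedCube:
    """Cumulative-sum reconstructed (and optionally baseline-corrected) cube."""

    axis: SpectralAxis
    data: np.ndarray
    mask: np.ndarray
    provenance: dict
    baseline_corrected: bool = False

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def spectra(self) -> np.ndarray:
        return self.data[self.mask]


def subtract_pairs(cube_l1: DataCube, cube_l2: DataCube, provenance: dict | None = None) -> DifferenceCube:
    """Pairwise subtraction: always lambda1 (lower excitation) minus lambda2.

    Requires matching grids, axes and masks; the subtraction happens on the
    shared detector-channel grid without any interpolation.
    """
    if cube_l1.grid_shape != cube_l2.grid_shape:
        raise ValueError("cubes differ in grid shape")
    if len(cube_l1.axis) != len(cube_l2.axis):
        raise ValueError("cubes differ in channel count")
    if not np.array_equal(cube_l1.mask, cube_l2.mask):
        raise ValueError("cubes differ in spaxel mask")
    return DifferenceCube(
        axis=cube_l1.axis,
        data=cube_l1.data - cube_l2.data,
        mask=cube_l1.mask.copy(),
        provenance=dict(provenance or {}),
    )


def reconstruct_cumulative(difference_spectrum: np.ndarray) -> np.ndarray:
    """Reconstruct a Raman spectrum by running summation over the channels.

    For a noiseless difference D(x) = S(x) - S(x - delta) the output equals
    the moving-window sum of S over delta channels — the telescoping
    identity.  Direction: ascending channel index (low to high wavenumber).
    """
    return np.cumsum(np.asarray(difference_spectrum, dtype=float))


def reconstruct_cube(diff: DifferenceCube) -> ReconstructedCube:
    return ReconstructedCube(
        axis=diff.axis,
        data=np.cumsum(diff.data, axis=-1),
        mask=diff.mask.copy(),
        provenance=dict(diff.provenance),
        baseline_corrected=False,
    )


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(
    spectrum: np.ndarray, half_width: int, lls: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """SNIP baseline estimate with a decreasing clipping window.

    Iterates m = half_width .. 1, replacing each point by the minimum of
    itself and the mean of its two neighbours at distance m; the optional
    log-log-square-root (LLS) compression makes the clipping robust to large
    dynamic range.  Returns (baseline, corrected = spectrum - baseline).
    """
    y = np.asarray(spectrum, dtype=float)
    if half_width < 1:
        raise ValueError("half_width must be at least 1")
    if y.size <= 2 * half_width:
        raise ValueError("spectrum too short for the requested SNIP window")
    offset = 0.0
    v = y
    if lls:
        offset = min(0.0, float(y.min()))
        v = _lls(y - offset)
    else:
        v = y.copy()
    for m in range(half_width, 0, -1):
        avg = 0.5 * (v[: -2 * m] + v[2 * m :])
        v[m:-m] = np.minimum(v[m:-m], avg)
    baseline = _lls_inv(v) + offset if lls else v
    return baseline, y - baseline


def snip_cube(cube: ReconstructedCube, half_width: int, lls: bool = True) -> ReconstructedCube:
    """Baseline-correct every spaxel of a reconstructed cube with SNIP."""
    out = np.zeros_like(cube.data)
    rows, cols = cube.grid_shape
    for i in range(rows):
        for j in range(cols):
            if cube.mask[i, j]:
                _, out[i, j] = snip_baseline(cube.data[i, j], half_width, lls=lls)
    prov = dict(cube.provenance)
    prov["snip_half_width"] = half_width
    return ReconstructedCube(
        axis=cube.axis,
        data=out,
        mask=cube.mask.copy(),
        provenance=prov,
        baseline_corrected=True,
    )


def to_relative_wavenumber(axis: SpectralAxis, lambda_exc: float) -> SpectralAxis:
    """Attach the Raman-shift axis of the given excitation to a wavelength axis."""
    if axis.kind != "wavelength-nm":
        raise ValueError("input axis must be in wavelength (nm)")
    if lambda_exc <= 0:
        raise ValueError("excitation wavelength must be positive")
    nu = wavelength_to_raman_shift(lambda_exc, axis.values)
    return SpectralAxis("relative-wavenumber-cm-1", nu, channel_shift=axis.channel_shift)


def residual_background_metric(
    diff: DifferenceCube, band_free: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Robust per-spaxel magnitude of the uncancelled background.

    Median of |difference| over the band-free channels (default: the outer
    10% of the axis at each end, where no Raman band is expected).  Returns
    (per-spaxel map with NaN at masked spaxels, mean over unmasked spaxels).
    """
    n = diff.data.shape[-1]
    if band_free is None:
        edge = max(1, n // 10)
        band_free = np.zeros(n, dtype=bool)
        band_free[:edge] = True
        band_free[-edge:] = True
    band_free = np.asarray(band_free, dtype=bool)
    if not band_free.any():
        raise ValueError("no band-free channels configured")
    per_spaxel = np.median(np.abs(diff.data[..., band_free]), axis=-1)
    out = np.where(diff.mask, per_spaxel, np.nan)
    summary = float(per_spaxel[diff.mask].mean()) if diff.mask.any() else float("nan")
    return out, summary
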