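"""Closed-form forward model for wide-field SERDS acquisitions.

Shifted-excitation Raman difference spectroscopy (SERDS) exploits the fact
that Raman bands are fixed in *relative wavenumber* — so they move in
wavelength when the excitation laser is shifted — while autofluorescence,
room light and instrument background are fixed in *wavelength*.  This module
provides the spectral physics needed to simulate such acquisitions:

* conversions between excitation wavelength, absolute wavelength and Raman
  shift (relative wavenumber),
* analyte models built from pseudo-Voigt Raman bands,
* smooth fluorescence backgrounds with photobleaching kinetics
  (constant / linear / exponential decay under continued illumination),
* room-light emission lines with an on/off time window, and
* acquisition schedules: interleaved (nod-and-shuffle) or sequential
  exposure slots alternating between the two excitation wavelengths.

All spectral quantities are photon rates (photons/s per channel); slot
integration multiplies by exposure time and integrates the bleaching decay
in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import erf

__all__ = [
    "ExcitationPair",
    "SpectralAxis",
    "RamanBand",
    "AnalyteModel",
    "BackgroundModel",
    "RoomLight",
    "Scene",
    "Slot",
    "AcquisitionSchedule",
    "wavenumber_shift",
    "raman_band_to_wavelength",
    "wavelength_to_raman_shift",
    "make_schedule",
    "readout_time_budget",
    "synth_emission_spectrum",
    "integrate_slot",
    "instrument_kernel",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# axis conversions
# ---------------------------------------------------------------------------

def wavenumber_shift(lambda1: float, lambda2: float) -> float:
    """Wavenumber separation (cm^-1) between two excitation wavelengths (nm).

    Positive when ``lambda1 < lambda2``; the sign follows the argument order.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("excitation wavelengths must be positive")
    return 1e7 * (1.0 / lambda1 - 1.0 / lambda2)


def raman_band_to_wavelength(lambda_exc: float, nu: float | np.ndarray) -> float | np.ndarray:
    """Absolute (Stokes) wavelength in nm of a band at Raman shift ``nu`` cm^-1."""
    if lambda_exc <= 0:
        raise ValueError("excitation wavelength must be positive")
    nu_exc = 1e7 / lambda_exc
    nu = np.asarray(nu, dtype=float)
    if np.any(nu >= nu_exc):
        raise ValueError("Raman shift exceeds the excitation photon energy")
    out = 1e7 / (nu_exc - nu)
    return float(out) if out.ndim == 0 else out


def wavelength_to_raman_shift(lambda_exc: float, lam: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`raman_band_to_wavelength`: wavelength nm -> shift cm^-1."""
    if lambda_exc <= 0:
        raise ValueError("excitation wavelength must be positive")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = 1e7 * (1.0 / lambda_exc - 1.0 / lam)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExcitationPair:
    """The two SERDS excitation wavelengths, lambda1 < lambda2 (nm)."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("wavelengths must be positive")
        if not self.lambda1 < self.lambda2:
            raise ValueError("lambda1 must be smaller than lambda2")

    @property
    def delta_nu(self) -> float:
        """Wavenumber separation in cm^-1 (always positive)."""
        return wavenumber_shift(self.lambda1, self.lambda2)

    def wavelength(self, index: int) -> float:
        if index == 1:
            return self.lambda1
        if index == 2:
            return self.lambda2
        raise ValueError("wavelength index must be 1 or 2")


@dataclass
class SpectralAxis:
    """A monotonically increasing sample grid with a declared unit kind."""

    kind: Literal["wavelength-nm", "relative-wavenumber-cm-1", "detector-channel"]
    values: np.ndarray
    channel_shift: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("axis needs at least two samples")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("axis values must be strictly increasing")
        if self.channel_shift is not None and self.channel_shift < 1:
            raise ValueError("channel_shift must be >= 1 for a SERDS pair")

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Mean sample spacing (exact for uniform grids)."""
        return float((self.values[-1] - self.values[0]) / (self.values.size - 1))

    def bin_edges(self) -> np.ndarray:
        mid = 0.5 * (self.values[1:] + self.values[:-1])
        first = self.values[0] - (mid[0] - self.values[0])
        last = self.values[-1] + (self.values[-1] - mid[-1])
        return np.concatenate([[first], mid, [last]])


def pair_channel_shift(axis: SpectralAxis, pair: ExcitationPair) -> int:
    """Integer channel separation of the SERDS pair on a wavelength axis.

    The wavelength offset between the two renderings of the same Raman band
    equals the excitation offset to first order, so the channel shift is
    ``(lambda2 - lambda1) / step`` rounded to the nearest channel (>= 1).
    """
    if axis.kind != "wavelength-nm":
        raise ValueError("channel shift is defined on a wavelength axis")
    delta = (pair.lambda2 - pair.lambda1) / axis.step
    return max(1, int(round(delta)))


# ---------------------------------------------------------------------------
# band and background models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RamanBand:
    """One Raman band: center (cm^-1), FWHM (cm^-1), amplitude (photons/s)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


@dataclass(frozen=True)
class AnalyteModel:
    name: str
    bands: tuple[RamanBand, ...]
    scatter_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("analyte needs at least one band")
        if self.scatter_scale <= 0:
            raise ValueError("scatter_scale must be positive")


def _lorentz_cdf(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.arctan(2.0 * (x - center) / fwhm) / np.pi + 0.5


def _gauss_cdf(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return 0.5 * (1.0 + erf((x - center) / (sigma * np.sqrt(2.0))))


def band_profile(edges: np.ndarray, center: float, fwhm: float, eta: float = 1.0) -> np.ndarray:
    """Bin-integrated unit-area pseudo-Voigt profile.

    ``eta`` is the Lorentzian fraction (1 = pure Lorentzian, the default).
    Using the analytic CDF per bin conserves flux exactly for bands narrower
    than the sampling step.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("Lorentzian fraction must be in [0, 1]")
    cdf = eta * _lorentz_cdf(edges, center, fwhm)
    if eta < 1.0:
        cdf = cdf + (1.0 - eta) * _gauss_cdf(edges, center, fwhm)
    return np.diff(cdf)


def instrument_kernel(fwhm_nm: float, step_nm: float) -> np.ndarray:
    """Discrete unit-sum Gaussian kernel for instrument broadening."""
    if fwhm_nm <= 0:
        return np.ones(1)
    sigma = fwhm_nm * _FWHM_TO_SIGMA / step_nm
    half = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


@dataclass
class BackgroundModel:
    """Smooth wavelength-fixed background with photobleaching kinetics.

    The spectral shape is either flat or a broad Gaussian hump in wavelength;
    the temporal factor models bleaching of autofluorescence under continued
    laser illumination:

    * ``constant``     — time-invariant,
    * ``linear``       — ``max(0, 1 - rate * t)`` with rate in 1/s,
    * ``exponential``  — ``exp(-t / tau)`` with ``tau`` in s.

    ``amplitude`` is the peak photon rate (photons/s per channel-equivalent)
    at t = 0 before any per-spaxel scaling.
    """

    amplitude: float = 0.0
    shape_kind: Literal["flat", "gaussian"] = "flat"
    shape_center: float = 0.0
    shape_fwhm: float = 1.0
    decay_kind: Literal["constant", "linear", "exponential"] = "constant"
    decay_rate: float = 0.0  # 1/s for linear
    decay_tau: float = 1.0  # s for exponential

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("background amplitude must be non-negative")
        if self.decay_kind == "linear" and self.decay_rate < 0:
            raise ValueError("linear decay rate must be non-negative")
        if self.decay_kind == "exponential" and self.decay_tau <= 0:
            raise ValueError("exponential time constant must be positive")

    def shape(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if self.shape_kind == "flat":
            return np.ones_like(lam)
        sigma = self.shape_fwhm * _FWHM_TO_SIGMA
        return np.exp(-0.5 * ((lam - self.shape_center) / sigma) ** 2)

    def decay_factor(self, t: float) -> float:
        if self.decay_kind == "constant":
            return 1.0
        if self.decay_kind == "linear":
            return max(0.0, 1.0 - self.decay_rate * t)
        return float(np.exp(-t / self.decay_tau))

    def decay_integral(self, t0: float, t1: float) -> float:
        """Closed-form integral of the decay factor over [t0, t1]."""
        if t1 < t0:
            raise ValueError("slot end precedes start")
        if self.decay_kind == "constant":
            return t1 - t0
        if self.decay_kind == "linear":
            m = self.decay_rate
            if m == 0:
                return t1 - t0
            t_zero = 1.0 / m
            a, b = min(t0, t_zero), min(t1, t_zero)
            return (b - a) - 0.5 * m * (b**2 - a**2)
        tau = self.decay_tau
        return tau * (np.exp(-t0 / tau) - np.exp(-t1 / tau))

    def rate(self, lam: np.ndarray, t: float) -> np.ndarray:
        return self.amplitude * self.decay_factor(t) * self.shape(lam)


@dataclass
class RoomLight:
    """Narrow emission lines fixed in wavelength, on only inside a window."""

    lines: tuple[tuple[float, float], ...] = ()
    on_window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        t0, t1 = self.on_window
        if t1 < t0:
            raise ValueError("on_window end precedes start")
        for lam, amp in self.lines:
            if lam <= 0 or amp < 0:
                raise ValueError("room-light lines need positive wavelength, non-negative amplitude")

    def overlap(self, t0: float, t1: float) -> float:
        """Seconds of room-light illumination inside the slot [t0, t1]."""
        lo, hi = self.on_window
        return max(0.0, min(t1, hi) - max(t0, lo))

    def rate(self, axis: SpectralAxis, t: float) -> np.ndarray:
        out = np.zeros(len(axis))
        lo, hi = self.on_window
        if not (lo <= t < hi) or not self.lines:
            return out
        return self._line_vector(axis)

    def _line_vector(self, axis: SpectralAxis) -> np.ndarray:
        """Photon rate per channel with all lines on.

        Each (delta-like) line's flux is shared linearly between the two
        neighbouring channels, which conserves both the flux and the line's
        sub-channel centroid on a uniform grid.
        """
        out = np.zeros(len(axis))
        n = out.size
        for lam, amp in self.lines:
            if lam < axis.values[0] or lam > axis.values[-1]:
                continue
            pos = (lam - axis.values[0]) / axis.step
            lo = int(np.floor(pos))
            frac = pos - lo
            out[lo] += amp * (1.0 - frac)
            if lo + 1 < n:
                out[lo + 1] += amp * frac
        return out


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """Spaxel grid mapping positions to composition and background.

    ``weights`` has shape (rows, cols, n_analytes) with non-negative entries;
    ``fluor_amplitude`` scales the shared background model per spaxel; masked
    spaxels (mask == False) are excluded from downstream statistics.
    """

    analytes: tuple[AnalyteModel, ...]
    weights: np.ndarray
    fluor_amplitude: np.ndarray
    mask: np.ndarray
    background: BackgroundModel = field(default_factory=BackgroundModel)
    room_light: RoomLight | None = None
    labels: np.ndarray | None = None  # ground-truth region labels

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.fluor_amplitude = np.asarray(self.fluor_amplitude, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights.ndim != 3 or self.weights.shape[2] != len(self.analytes):
            raise ValueError("weights must be (rows, cols, n_analytes)")
        if np.any(self.weights < 0):
            raise ValueError("composition weights must be non-negative")
        if self.fluor_amplitude.shape != self.grid_shape or self.mask.shape != self.grid_shape:
            raise ValueError("per-spaxel arrays must match the grid shape")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.weights.shape[:2]

    @property
    def n_spaxels(self) -> int:
        return self.weights.shape[0] * self.weights.shape[1]


def _band_rate(
    scene: Scene,
    spaxel: tuple[int, int],
    excitation: float,
    axis: SpectralAxis,
    eta: float = 1.0,
) -> np.ndarray:
    """Raman photon rate per channel for one spaxel at one excitation."""
    if axis.kind != "wavelength-nm":
        raise ValueError("emission spectra are rendered on a wavelength axis")
    i, j = spaxel
    edges = axis.bin_edges()
    lo, hi = axis.values[0], axis.values[-1]
    out = np.zeros(len(axis))
    for a, analyte in enumerate(scene.analytes):
        w = scene.weights[i, j, a]
        if w == 0:
            continue
        for band in analyte.bands:
            lam_c = raman_band_to_wavelength(excitation, band.center)
            fwhm_nm = lam_c**2 * band.width / 1e7
            if lam_c < lo or lam_c > hi:
                warnings.warn(
                    f"band at {band.center:.0f} cm^-1 ({lam_c:.1f} nm) falls outside "
                    "the spectral axis and is truncated",
                    stacklevel=2,
                )
            out += (
                w
                * analyte.scatter_scale
                * band.amplitude
                * band_profile(edges, lam_c, fwhm_nm, eta=eta)
            )
    return out


def synth_emission_spectrum(
    scene: Scene,
    spaxel: tuple[int, int],
    excitation: float,
    axis: SpectralAxis,
    t: float,
    eta: float = 1.0,
    instrument_fwhm_nm: float = 0.22,
) -> np.ndarray:
    """Instantaneous photon rate per channel at time ``t``.

    Sum of excitation-dependent Raman bands, wavelength-fixed background at
    its bleached level, and room-light lines if ``t`` lies in the on-window.
    The whole spectrum is convolved with the instrument response (Gaussian,
    default FWHM 0.22 nm).
    """
    i, j = spaxel
    rate = _band_rate(scene, spaxel, excitation, axis, eta=eta)
    rate = rate + scene.fluor_amplitude[i, j] * scene.background.rate(axis.values, t)
    if scene.room_light is not None:
        rate = rate + scene.room_light.rate(axis, t)
    kernel = instrument_kernel(instrument_fwhm_nm, axis.step)
    if kernel.size > 1:
        rate = np.convolve(rate, kernel, mode="same")
    return rate


def integrate_slot(
    scene: Scene,
    spaxel: tuple[int, int],
    excitation: float,
    axis: SpectralAxis,
    t_start: float,
    t_exp: float,
    eta: float = 1.0,
    instrument_fwhm_nm: float = 0.22,
) -> np.ndarray:
    """Expected photon counts per channel for one exposure slot.

    Bands are time-invariant (rate x t_exp); the background decay and the
    room-light window are integrated in closed form over the slot.
    """
    i, j = spaxel
    counts = _band_rate(scene, spaxel, excitation, axis, eta=eta) * t_exp
    bg_int = scene.background.decay_integral(t_start, t_start + t_exp)
    counts = counts + (
        scene.fluor_amplitude[i, j]
        * scene.background.amplitude
        * bg_int
        * scene.background.shape(axis.values)
    )
    if scene.room_light is not None:
        dt = scene.room_light.overlap(t_start, t_start + t_exp)
        if dt > 0:
            counts = counts + dt * scene.room_light._line_vector(axis)
    kernel = instrument_kernel(instrument_fwhm_nm, axis.step)
    if kernel.size > 1:
        counts = np.convolve(counts, kernel, mode="same")
    return counts


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slot:
    wavelength_index: int  # 1 or 2
    t_start: float
    t_exp: float


@dataclass
class AcquisitionSchedule:
    """Ordered, non-overlapping exposure slots for the two excitations."""

    slots: tuple[Slot, ...]
    mode: Literal["interleaved", "sequential"]
    n_cycles: int
    t_exp: float

    def __post_init__(self) -> None:
        t = -np.inf
        for s in self.slots:
            if s.wavelength_index not in (1, 2):
                raise ValueError("wavelength index must be 1 or 2")
            if s.t_exp <= 0:
                raise ValueError("exposure must be positive")
            if s.t_start < t - 1e-12:
                raise ValueError("slots must be time-ordered and non-overlapping")
            t = s.t_start + s.t_exp
        e1 = self.total_exposure(1)
        e2 = self.total_exposure(2)
        if abs(e1 - e2) > 1e-9 * max(e1, e2, 1.0):
            raise ValueError("total exposure must be equal across the two wavelengths")

    def total_exposure(self, wavelength_index: int) -> float:
        return sum(s.t_exp for s in self.slots if s.wavelength_index == wavelength_index)

    @property
    def duration(self) -> float:
        last = self.slots[-1]
        return last.t_start + last.t_exp


def make_schedule(
    mode: Literal["interleaved", "sequential"], n_cycles: int, t_exp: float
) -> AcquisitionSchedule:
    """Build the acquisition schedule for N cycles of t_exp per wavelength.

    Interleaved (nod-and-shuffle) mode alternates lambda1/lambda2 in 2N short
    slots; sequential mode exposes each wavelength once for N * t_exp.  Both
    give the same total exposure per wavelength (N * t_exp).
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if t_exp <= 0:
        raise ValueError("exposure time must be positive")
    if mode == "interleaved":
        slots = []
        t = 0.0
        for _ in range(n_cycles):
            slots.append(Slot(1, t, t_exp))
            t += t_exp
            slots.append(Slot(2, t, t_exp))
            t += t_exp
    elif mode == "sequential":
        block = n_cycles * t_exp
        slots = [Slot(1, 0.0, block), Slot(2, block, block)]
    else:
        raise ValueError(f"unknown schedule mode {mode!r}")
    return AcquisitionSchedule(tuple(slots), mode, n_cycles, t_exp)


def readout_time_budget(n_cycles: int, readout_s: float = 60.0) -> dict[str, float]:
    """Cumulative CCD readout time for N cycles per wavelength.

    Reading out after every acquisition costs ``2 N`` readouts; the
    nod-and-shuffle scheme accumulates charge on-chip and reads out once.
    Returns both totals in seconds.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    return {
        "per_acquisition_readout_s": 2 * n_cycles * readout_s,
        "nod_and_shuffle_readout_s": readout_s,
    }
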