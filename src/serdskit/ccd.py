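"""Interlaced nod-and-shuffle CCD frame simulation.

The detector records each spaxel's spectrum as a horizontal trace.  During a
nod-and-shuffle acquisition the accumulated charge is shuffled up by a fixed
number of pixel rows (default 5) whenever the excitation switches to the
second wavelength, so the two Raman images interlace on the chip: every
lambda2 trace sits ``shuffle_offset`` rows above its lambda1 partner, and
both share the same detector columns (hence the same wavelength axis and the
same pixel response).  Charge accumulates across all exposure slots and is
read out once, so readout noise is applied a single time per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .forward import (
    AcquisitionSchedule,
    ExcitationPair,
    Scene,
    SpectralAxis,
    _band_rate,
    instrument_kernel,
)

__all__ = [
    "TraceLayout",
    "DetectorFrame",
    "render_frame",
    "render_split_frames",
    "add_readout_noise",
    "check_crosstalk",
    "gaussian_leak_fraction",
    "default_layout",
    "small_layout",
]


@dataclass
class TraceLayout:
    """Geometry of the interlaced traces on the detector.

    ``trace_pitch`` is the row spacing between consecutive lambda1 traces;
    the paired lambda2 trace sits ``shuffle_offset`` rows above (larger row
    index).  ``block_size`` traces of each wavelength form one block per
    spaxel-image row.  ``dispersion`` maps detector column -> wavelength nm
    (polynomial coefficients, ascending order).  ``response`` is an optional
    per-column relative sensitivity divided out by flat-field calibration.
    """

    frame_shape: tuple[int, int] = (4096, 4096)
    trace_pitch: int = 10
    shuffle_offset: int = 5
    block_size: int = 20
    n_blocks: int = 20
    cross_profile_sigma: float = 0.7
    dispersion: tuple[float, ...] = (456.0, 0.164)
    row_origin: int = 2
    response: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shuffle_offset >= self.trace_pitch:
            raise ValueError("shuffle offset must be smaller than the trace pitch")
        if self.shuffle_offset < 1:
            raise ValueError("shuffle offset must be at least one row")
        last = self.trace_row(self.n_blocks - 1, self.block_size - 1, 2)
        margin = int(np.floor(3.0 * self.cross_profile_sigma))  # discrete profile half width
        if self.row_origin < margin:
            raise ValueError(
                f"row_origin {self.row_origin} too small for the +/-{margin}-row cross profile"
            )
        if last + margin >= self.frame_shape[0]:
            raise ValueError(
                f"layout needs {last + margin + 1} rows for "
                f"{2 * self.n_spaxels} traces, frame has {self.frame_shape[0]}"
            )
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if self.response.shape != (self.frame_shape[1],):
                raise ValueError("response must have one entry per column")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.n_blocks, self.block_size)

    @property
    def n_spaxels(self) -> int:
        return self.n_blocks * self.block_size

    def trace_row(self, i: int, j: int, wavelength_index: int) -> int:
        """Center row of the trace of spaxel (i, j) for the given excitation."""
        k = i * self.block_size + j
        row = self.row_origin + k * self.trace_pitch
        if wavelength_index == 2:
            row += self.shuffle_offset
        elif wavelength_index != 1:
            raise ValueError("wavelength index must be 1 or 2")
        return row

    def wavelength_axis(self) -> SpectralAxis:
        cols = np.arange(self.frame_shape[1], dtype=float)
        lam = np.polynomial.polynomial.polyval(cols, np.asarray(self.dispersion))
        return SpectralAxis("wavelength-nm", lam)

    def profile_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete cross-dispersion profile: (row offsets, unit-sum weights).

        Gaussian in rows, truncated at +/- 3 sigma and renormalized, so all
        charge lands inside the truncation window.
        """
        sigma = self.cross_profile_sigma
        if sigma <= 0:
            return np.array([0]), np.array([1.0])
        half = int(np.floor(3.0 * sigma))
        offsets = np.arange(-half, half + 1)
        w = np.exp(-0.5 * (offsets / sigma) ** 2)
        return offsets, w / w.sum()


def default_layout(**overrides) -> TraceLayout:
    """Full-size layout: 4096 x 4096 chip, 20 x 20 spaxels, 800 traces."""
    params = dict(
        frame_shape=(4096, 4096),
        trace_pitch=10,
        shuffle_offset=5,
        block_size=20,
        n_blocks=20,
        dispersion=(456.0, (540.0 - 456.0) / 4096),
    )
    params.update(overrides)
    return TraceLayout(**params)


def small_layout(**overrides) -> TraceLayout:
    """Compact test layout: 512 x 512 frame, 7 x 7 spaxels, 98 traces.

    Keeps the physical trace pitch (10 rows) and shuffle offset (5 rows); the
    spaxel grid is the largest square that fits 512 rows at that pitch.
    """
    params = dict(
        frame_shape=(512, 512),
        trace_pitch=10,
        shuffle_offset=5,
        block_size=7,
        n_blocks=7,
        dispersion=(456.0, (540.0 - 456.0) / 512),
    )
    params.update(overrides)
    return TraceLayout(**params)


@dataclass
class DetectorFrame:
    """A (possibly accumulated) detector image plus acquisition metadata."""

    counts: np.ndarray
    layout: TraceLayout
    schedule: AcquisitionSchedule
    pair: ExcitationPair
    rng_seed: int | None = None
    readout_noise_sigma: float = 3.0
    saturation: float = 6.5e4
    read_out: bool = False
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.layout.frame_shape:
            raise ValueError("counts shape does not match the layout frame shape")
        if self.saturated is None:
            self.saturated = self.counts >= self.saturation


def _expected_spectra(
    scene: Scene,
    pair: ExcitationPair,
    layout: TraceLayout,
    eta: float,
    instrument_fwhm_nm: float,
):
    """Precompute per-spaxel band rates and shared background vectors."""
    axis = layout.wavelength_axis()
    kernel = instrument_kernel(instrument_fwhm_nm, axis.step)

    def smooth(v: np.ndarray) -> np.ndarray:
        return np.convolve(v, kernel, mode="same") if kernel.size > 1 else v

    rows, cols = scene.grid_shape
    band = {1: {}, 2: {}}
    for wl, exc in ((1, pair.lambda1), (2, pair.lambda2)):
        for i in range(rows):
            for j in range(cols):
                if not scene.mask[i, j]:
                    continue
                band[wl][(i, j)] = smooth(_band_rate(scene, (i, j), exc, axis, eta=eta))
    bg_shape = smooth(scene.background.shape(axis.values)) * scene.background.amplitude
    lines = (
        smooth(scene.room_light._line_vector(axis))
        if scene.room_light is not None
        else np.zeros(len(axis))
    )
    return axis, band, bg_shape, lines


def render_frame(
    scene: Scene,
    pair: ExcitationPair,
    schedule: AcquisitionSchedule,
    layout: TraceLayout,
    seed: int | None = None,
    noise: bool = True,
    eta: float = 1.0,
    instrument_fwhm_nm: float = 0.22,
    readout_noise_sigma: float = 3.0,
    saturation: float = 6.5e4,
) -> DetectorFrame:
    """Render an acquisition schedule into one interlaced detector frame.

    For every exposure slot each unmasked spaxel's spectrum (at the slot's
    excitation and epoch) is deposited as a trace with a Gaussian cross
    profile; lambda2 slots land ``shuffle_offset`` rows up.  Shot noise is
    drawn per slot (Poisson); charge accumulates without intermediate
    readout.  With ``noise=False`` the frame holds expected counts.
    """
    if scene.grid_shape != layout.grid_shape:
        raise ValueError(
            f"scene grid {scene.grid_shape} does not match layout grid {layout.grid_shape}"
        )
    rng = np.random.default_rng(seed)
    axis, band, bg_shape, lines = _expected_spectra(scene, pair, layout, eta, instrument_fwhm_nm)
    offsets, weights = layout.profile_weights()
    frame = np.zeros(layout.frame_shape)
    resp = layout.response if layout.response is not None else 1.0

    for slot in schedule.slots:
        bg_int = scene.background.decay_integral(slot.t_start, slot.t_start + slot.t_exp)
        line_dt = (
            scene.room_light.overlap(slot.t_start, slot.t_start + slot.t_exp)
            if scene.room_light is not None
            else 0.0
        )
        for (i, j), rate in band[slot.wavelength_index].items():
            expected = rate * slot.t_exp + scene.fluor_amplitude[i, j] * bg_shape * bg_int
            if line_dt > 0:
                expected = expected + line_dt * lines
            expected = expected * resp
            patch = weights[:, None] * expected[None, :]
            if noise:
                patch = rng.poisson(patch).astype(float)
            row = layout.trace_row(i, j, slot.wavelength_index)
            frame[row + offsets[0] : row + offsets[-1] + 1, :] += patch

    return DetectorFrame(
        counts=frame,
        layout=layout,
        schedule=schedule,
        pair=pair,
        rng_seed=seed,
        readout_noise_sigma=readout_noise_sigma,
        saturation=saturation,
    )


def render_split_frames(
    scene: Scene,
    pair: ExcitationPair,
    schedule: AcquisitionSchedule,
    layout: TraceLayout,
    seed: int | None = None,
    **kwargs,
) -> list[DetectorFrame]:
    """Traditional protocol: one frame (and one readout) per wavelength.

    Renders the same schedule but splits the slots by excitation into two
    frames, each of which must be read out separately — the comparison case
    for the single-readout nod-and-shuffle frame.
    """
    frames = []
    for wl in (1, 2):
        slots = tuple(s for s in schedule.slots if s.wavelength_index == wl)
        sub = AcquisitionSchedule.__new__(AcquisitionSchedule)
        sub.slots, sub.mode, sub.n_cycles, sub.t_exp = (
            slots,
            schedule.mode,
            schedule.n_cycles,
            schedule.t_exp,
        )
        sub_seed = None if seed is None else seed + wl
        frames.append(render_frame(scene, pair, sub, layout, seed=sub_seed, **kwargs))
    return frames


def add_readout_noise(
    frame: DetectorFrame, sigma: float | None = None, seed: int | None = None
) -> DetectorFrame:
    """Apply the one-time readout: one Gaussian draw per pixel.

    Raises if the frame was already read out — readout noise enters exactly
    once per frame, which is the point of accumulating on-chip.
    """
    if frame.read_out:
        raise RuntimeError("frame was already read out; readout noise applies once")
    sigma = frame.readout_noise_sigma if sigma is None else sigma
    if sigma < 0:
        raise ValueError("readout noise sigma must be non-negative")
    frame.saturated = frame.counts >= frame.saturation
    if sigma > 0:
        rng = np.random.default_rng(seed if seed is not None else frame.rng_seed)
        frame.counts = frame.counts + rng.normal(0.0, sigma, size=frame.counts.shape)
    frame.read_out = True
    return frame


def gaussian_leak_fraction(sigma: float, offset: int, aperture: int) -> float:
    """Fraction of a Gaussian trace's charge inside the paired neighbour's
    extraction aperture (rows offset-aperture .. offset+aperture)."""
    if sigma <= 0:
        return 0.0
    a = (offset - aperture - 0.5) / (sigma * np.sqrt(2.0))
    b = (offset + aperture + 0.5) / (sigma * np.sqrt(2.0))
    return float(0.5 * (erf(b) - erf(a)))


def check_crosstalk(
    frame: DetectorFrame,
    layout: TraceLayout | None = None,
    aperture: int = 2,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Estimate charge leaking from each trace into its pair's aperture.

    The leak fraction follows from the Gaussian cross profile at the shuffle
    offset; a trace is flagged when its estimated leak exceeds ``threshold``
    times the partner trace's own counts (a bright trace contaminating a
    faint neighbour).  Returns one row per trace.
    """
    layout = layout or frame.layout
    frac = gaussian_leak_fraction(layout.cross_profile_sigma, layout.shuffle_offset, aperture)
    records = []
    rows, cols = layout.grid_shape
    for i in range(rows):
        for j in range(cols):
            totals = {}
            for wl in (1, 2):
                r = layout.trace_row(i, j, wl)
                totals[wl] = float(
                    frame.counts[max(0, r - aperture) : r + aperture + 1, :].sum()
                )
            for wl in (1, 2):
                other = totals[2 if wl == 1 else 1]
                leak = totals[wl] * frac
                records.append(
                    {
                        "spaxel_row": i,
                        "spaxel_col": j,
                        "wavelength_index": wl,
                        "total_counts": totals[wl],
                        "partner_counts": other,
                        "leak_fraction": frac,
                        "leak_counts": leak,
                        "flagged": bool(leak > threshold * max(other, 1e-12)),
                    }
                )
    return pd.DataFrame.from_records(records)
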