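"""SERDS arithmetic: subtraction, telescoping reconstruction, SNIP, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from serdskit import pipeline, scenes, serds
from serdskit.forward import BackgroundModel, ExcitationPair, SpectralAxis, make_schedule
from serdskit.reduction import DataCube
from serdskit.serds import (
    DifferenceCube,
    reconstruct_cumulative,
    residual_background_metric,
    snip_baseline,
    subtract_pairs,
    to_relative_wavenumber,
)


def _cube(data, mask=None, lo=456.0, hi=540.0):
    data = np.asarray(data, dtype=float)
    axis = SpectralAxis("wavelength-nm", np.linspace(lo, hi, data.shape[-1]))
    mask = np.ones(data.shape[:2], dtype=bool) if mask is None else mask
    return DataCube(axis, data, mask)


def moving_window_sum(s: np.ndarray, delta: int) -> np.ndarray:
    """Independent brute-force oracle: out[x] = sum of s[x-delta+1 .. x]."""
    out = np.zeros_like(s, dtype=float)
    for x in range(s.size):
        out[x] = s[max(0, x - delta + 1) : x + 1].sum()
    return out


def test_identical_cubes_give_zero_difference(rng):
    data = rng.random((3, 3, 50))
    d = subtract_pairs(_cube(data), _cube(data.copy()))
    assert np.all(d.data == 0)


def test_subtraction_grid_mismatch_rejected(rng):
    a = _cube(rng.random((3, 3, 50)))
    b = _cube(rng.random((3, 4, 50)))
    with pytest.raises(ValueError, match="grid"):
        subtract_pairs(a, b)


def test_shifted_band_difference_sums_to_zero(rng):
    """Channel sum of S - shift(S, d) telescopes to zero when the band lies
    fully inside the window."""
    n, delta = 200, 12
    x = np.arange(n, dtype=float)
    band = 40.0 * np.exp(-0.5 * ((x - 90) / 5.0) ** 2)
    shifted = np.roll(band, delta)
    assert abs((band - shifted).sum()) < 1e-9


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    s=hnp.arrays(
        float,
        st.integers(min_value=80, max_value=300),
        elements=st.floats(min_value=0.0, max_value=1e6),
    ),
    delta=st.integers(min_value=1, max_value=64),
)
def test_telescoping_identity(s, delta):
    """cumsum(S - shift(S, delta)) equals the moving-window sum of S exactly."""
    shifted = np.zeros_like(s)
    shifted[delta:] = s[:-delta]
    diff = s - shifted
    recon = reconstruct_cumulative(diff)
    assert np.allclose(recon, moving_window_sum(s, delta), atol=1e-9 * max(1.0, s.max()))


def test_reconstruction_of_band_pair_matches_oracle(rng):
    n, delta = 300, 10
    x = np.arange(n, dtype=float)
    s = 25.0 / (1.0 + (2.0 * (x - 140) / 9.0) ** 2)
    shifted = np.zeros_like(s)
    shifted[delta:] = s[:-delta]
    recon = reconstruct_cumulative(s - shifted)
    assert np.allclose(recon, moving_window_sum(s, delta), atol=1e-9)


def test_reconstructed_peak_lands_near_band_position():
    """An isolated 999 cm^-1 ring-breathing band reconstructed through the
    full chain peaks where the oracle moving-window sum peaks, within
    delta/2 channels of the true band position."""
    from serdskit.forward import AnalyteModel, RamanBand

    preset = scenes.beads_scene(grid_shape=(3, 3), n_cycles=2, t_exp=0.1)
    single = AnalyteModel("ps_ring", (RamanBand(999.0, 10.0, 1000.0),))
    preset.scene = scenes.Scene(
        analytes=(single,),
        weights=np.ones((3, 3, 1)),
        fluor_amplitude=np.zeros((3, 3)),
        mask=np.ones((3, 3), dtype=bool),
        background=scenes.BackgroundModel(amplitude=0.0),
    )
    layout = pipeline.layout_for_preset(preset, n_cols=512)
    result = pipeline.run_pipeline(preset, noise=False, layout=layout)
    recon = result.reconstructed
    delta = recon.provenance["delta_channels"]
    # oracle: moving-window sum of the extracted lambda1 spectrum
    oracle = moving_window_sum(result.cube_l1.data[1, 1], delta)
    rec = np.cumsum(result.difference.data[1, 1])
    # the physical shift is delta to the nearest channel, so the argmax may
    # differ from the integer-shift oracle by at most one channel
    assert abs(np.argmax(rec) - np.argmax(oracle)) <= 1
    nu = recon.axis.values
    step_nu = np.median(np.diff(nu))
    assert abs(nu[np.argmax(rec)] - 999.0) <= (delta / 2 + 1) * step_nu


# ---------------------------------------------------------------------------
# SNIP
# ---------------------------------------------------------------------------

def test_snip_zero_spectrum_zero_baseline():
    baseline, corrected = snip_baseline(np.zeros(100), half_width=10)
    assert np.allclose(baseline, 0.0, atol=1e-12)
    assert np.allclose(corrected, 0.0, atol=1e-12)


def test_snip_tracks_smooth_continuum():
    """Peak-free smooth continuum is absorbed into the baseline to <= 2%."""
    x = np.linspace(0, 1, 400)
    continuum = 1000.0 * np.exp(-0.5 * ((x - 0.4) / 0.35) ** 2)
    # clipping window well below the continuum curvature scale (~140 channels)
    baseline, corrected = snip_baseline(continuum, half_width=10)
    assert np.max(np.abs(corrected)) <= 0.02 * continuum.max()


def test_snip_preserves_narrow_band_height():
    x = np.arange(400, dtype=float)
    offset = 200.0
    band = 500.0 / (1.0 + (2.0 * (x - 180) / 6.0) ** 2)
    baseline, corrected = snip_baseline(band + offset, half_width=40)
    assert corrected.max() == pytest.approx(500.0, rel=0.05)


def test_snip_idempotent():
    x = np.arange(300, dtype=float)
    spec = 100.0 + 0.3 * x + 200.0 / (1.0 + ((x - 150) / 4.0) ** 2)
    _, corrected = snip_baseline(spec, half_width=30)
    _, twice = snip_baseline(corrected, half_width=30)
    scale = max(1.0, np.abs(corrected).max())
    assert np.max(np.abs(twice - corrected)) <= 0.02 * scale


def test_snip_window_too_large():
    with pytest.raises(ValueError, match="short"):
        snip_baseline(np.zeros(20), half_width=10)


# ---------------------------------------------------------------------------
# relative wavenumber axis
# ---------------------------------------------------------------------------

def test_relative_wavenumber_examples():
    axis = SpectralAxis("wavelength-nm", np.array([457.74, 479.67, 500.0]))
    nu = to_relative_wavenumber(axis, 457.74)
    assert nu.kind == "relative-wavenumber-cm-1"
    assert nu.values[0] == pytest.approx(0.0, abs=1e-9)
    assert nu.values[1] == pytest.approx(999.0, abs=1.0)  # 479.67 nm rounded to 0.01 nm

    axis_nir = SpectralAxis("wavelength-nm", np.array([784.43, 785.48, 790.0]))
    nu_nir = to_relative_wavenumber(axis_nir, 784.43)
    assert nu_nir.values[1] == pytest.approx(17.0, abs=0.1)


def test_relative_wavenumber_rejects_bad_excitation():
    axis = SpectralAxis("wavelength-nm", np.array([457.74, 500.0]))
    with pytest.raises(ValueError):
        to_relative_wavenumber(axis, -1.0)


# ---------------------------------------------------------------------------
# residual background metric
# ---------------------------------------------------------------------------

def _diff_cube(data):
    data = np.asarray(data, dtype=float)
    axis = SpectralAxis("detector-channel", np.arange(data.shape[-1], dtype=float))
    return DifferenceCube(axis, data, np.ones(data.shape[:2], dtype=bool), {})


def test_zero_difference_zero_metric():
    _, summary = residual_background_metric(_diff_cube(np.zeros((2, 2, 100))))
    assert summary == 0.0


def test_metric_requires_band_free_channels():
    with pytest.raises(ValueError, match="band-free"):
        residual_background_metric(_diff_cube(np.zeros((1, 1, 50))), band_free=np.zeros(50, bool))


def _bleach_metric(mode, decay_kwargs, n_cycles=8, t_exp=0.05):
    preset = scenes.tissue_scene(grid_shape=(3, 3), n_cycles=n_cycles, t_exp=t_exp, mode=mode)
    preset.scene.weights[:] = 0.0  # fluorescence only: the closed-form case
    preset.scene.background = BackgroundModel(
        amplitude=2000.0, shape_kind="gaussian", shape_center=500.0, shape_fwhm=70.0, **decay_kwargs
    )
    layout = pipeline.layout_for_preset(preset, n_cols=128)
    frame = pipeline.simulate_preset(preset, layout=layout, noise=False, readout=False)
    c1, c2 = pipeline.reduce_frame(frame, despike_spectra=False)
    diff = subtract_pairs(c1, c2)
    _, metric = residual_background_metric(diff)
    return metric


def test_constant_background_cancels_for_both_schedules():
    for mode in ("interleaved", "sequential"):
        metric = _bleach_metric(mode, dict(decay_kind="constant"))
        assert metric == pytest.approx(0.0, abs=1e-9)


def test_linear_bleaching_residual_scales_as_one_over_n():
    """Closed form: sequential residual ~ m T^2, interleaved ~ m T^2 / N."""
    n = 8
    seq = _bleach_metric("sequential", dict(decay_kind="linear", decay_rate=0.05), n_cycles=n)
    inter = _bleach_metric("interleaved", dict(decay_kind="linear", decay_rate=0.05), n_cycles=n)
    assert seq / inter == pytest.approx(n, rel=1e-6)


def test_room_light_cancellation_balance():
    """Equal room-light exposure per wavelength cancels the lines exactly;
    a known imbalance leaves a residual equal to imbalance x line flux."""
    preset = scenes.tablets_scene(grid_shape=(3, 3), n_cycles=4, t_exp=0.2)
    line_amp = 3000.0
    layout = pipeline.layout_for_preset(preset, n_cols=256)
    sched = preset.schedule

    def run(window):
        preset.scene.room_light.on_window = window
        frame = pipeline.simulate_preset(preset, layout=layout, noise=False, readout=False)
        c1, c2 = pipeline.reduce_frame(frame, despike_spectra=False, scene_mask=preset.scene.mask)
        return subtract_pairs(c1, c2)

    # window covering the whole schedule: equal exposure, lines vanish
    diff_eq = run((0.0, sched.duration))
    # window covering one extra lambda2 slot: imbalance of one slot
    diff_im = run((0.2, 0.4))  # exactly the first lambda2 slot

    empty = np.argwhere(preset.scene.labels == 2)[0]
    line_channels = np.abs(diff_im.data[empty[0], empty[1]]).max()
    eq_resid = np.abs(diff_eq.data[empty[0], empty[1]]).max()
    assert eq_resid <= 1e-9 * line_amp
    # residual equals (imbalance time) x (line flux): one 0.2 s slot of lambda2
    expected_line_counts = 0.2 * line_amp
    total_imbalanced = np.abs(diff_im.data[empty[0], empty[1]]).sum()
    assert total_imbalanced == pytest.approx(expected_line_counts * len(preset.scene.room_light.lines), rel=1e-6)
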