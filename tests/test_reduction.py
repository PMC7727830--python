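"""Extraction, despiking, calibration and cube assembly."""

import numpy as np
import pytest

from serdskit import forward, pipeline, reduction, scenes
from serdskit.ccd import default_layout, render_frame
from serdskit.forward import ExcitationPair, make_schedule
from serdskit.reduction import (
    apply_flat,
    assemble_cubes,
    despike,
    extract_traces,
    find_line_centroids,
    fit_wavelength_solution,
)

BLUE = ExcitationPair(457.74, 458.90)


def test_extraction_roundtrips_injected_spectra(beads_preset, beads_layout, beads_frame_noise_free):
    """Noise-free extraction recovers the forward-model slot sums to 1e-6."""
    axis = beads_layout.wavelength_axis()
    pairs = extract_traces(beads_frame_noise_free)
    by_id = {p.spaxel_id: p for p in pairs}
    schedule, pair, scene = beads_preset.schedule, beads_preset.pair, beads_preset.scene
    for spaxel in [(0, 0), (2, 3), (4, 4)]:
        expected = {1: np.zeros(len(axis)), 2: np.zeros(len(axis))}
        for slot in schedule.slots:
            exc = pair.wavelength(slot.wavelength_index)
            expected[slot.wavelength_index] += forward.integrate_slot(
                scene, spaxel, exc, axis, slot.t_start, slot.t_exp
            )
        got = by_id[spaxel]
        scale = max(expected[1].max(), 1.0)
        assert np.allclose(got.spectrum_l1, expected[1], atol=1e-6 * scale)
        assert np.allclose(got.spectrum_l2, expected[2], atol=1e-6 * scale)


def test_weighted_extraction_matches_boxcar_noise_free(beads_frame_noise_free):
    boxcar = extract_traces(beads_frame_noise_free)
    weighted = extract_traces(beads_frame_noise_free, weighted=True)
    for b, w in zip(boxcar, weighted):
        scale = max(b.spectrum_l1.max(), 1.0)
        assert np.allclose(b.spectrum_l1, w.spectrum_l1, atol=1e-6 * scale)


def test_default_layout_yields_400_pairs():
    """The full 20x20 fiber-array layout carries 800 traces = 400 pairs."""
    preset = scenes.beads_scene(grid_shape=(20, 20), n_cycles=1, t_exp=0.1)
    layout = default_layout(frame_shape=(4096, 64), dispersion=(456.0, (540.0 - 456.0) / 64))
    frame = render_frame(preset.scene, preset.pair, preset.schedule, layout, noise=False)
    pairs = extract_traces(frame)
    assert len(pairs) == 400
    assert {p.spaxel_id for p in pairs} == {(i, j) for i in range(20) for j in range(20)}


def test_empty_frame_extracts_zero_spectra(beads_layout):
    preset = scenes.beads_scene(grid_shape=(5, 5), n_cycles=1, t_exp=0.1)
    scene = preset.scene
    scene.weights[:] = 0
    scene.fluor_amplitude[:] = 0
    scene.background = forward.BackgroundModel(amplitude=0.0)
    frame = render_frame(scene, preset.pair, preset.schedule, beads_layout, noise=False)
    pairs = extract_traces(frame)
    assert len(pairs) == 25
    assert all(p.spectrum_l1.sum() == 0 and p.spectrum_l2.sum() == 0 for p in pairs)


def test_extraction_is_linear(beads_preset, beads_layout, beads_frame_noise_free):
    """extract(aF + bG) = a extract(F) + b extract(G) for noise-free frames."""
    import copy

    f = beads_frame_noise_free
    g = copy.deepcopy(f)
    g.counts = np.roll(f.counts, 3, axis=1)
    combo = copy.deepcopy(f)
    combo.counts = 2.0 * f.counts + 0.5 * g.counts
    pf = extract_traces(f)[7]
    pg = extract_traces(g)[7]
    pc = extract_traces(combo)[7]
    assert np.allclose(pc.spectrum_l1, 2.0 * pf.spectrum_l1 + 0.5 * pg.spectrum_l1, rtol=1e-12)


def test_overlapping_boxcar_aperture_rejected(beads_frame_noise_free):
    with pytest.raises(ValueError, match="overlap"):
        extract_traces(beads_frame_noise_free, aperture=3)
    # weighted extraction tolerates it
    extract_traces(beads_frame_noise_free, aperture=3, weighted=True)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def _lorentzian(n=200, center=100.0, fwhm=8.0, amp=50.0):
    x = np.arange(n, dtype=float)
    return amp / (1.0 + (2.0 * (x - center) / fwhm) ** 2)


def test_despike_leaves_clean_band_untouched(rng):
    spec = _lorentzian() + rng.normal(0, 0.5, 200)
    assert np.array_equal(despike(spec), spec)  # band is wider than max_width


def test_despike_removes_single_channel_spike(rng):
    spec = _lorentzian() + rng.normal(0, 0.5, 200)
    spiked = spec.copy()
    spiked[40] += 500.0
    out = despike(spiked)
    # interpolated value equals the mean of the two neighbours
    assert out[40] == pytest.approx(0.5 * (spiked[39] + spiked[41]))
    assert np.array_equal(out[:39], spiked[:39])


def test_despike_flat_spectrum_unchanged():
    spec = np.full(50, 7.0)
    assert np.array_equal(despike(spec), spec)


def test_despike_preserves_wide_artifacts(rng):
    spec = rng.normal(0, 0.5, 200)
    spec[60:70] += 100.0  # 10-channel block, wider than max_width
    assert np.array_equal(despike(spec, max_width=3), spec)


# ---------------------------------------------------------------------------
# wavelength calibration
# ---------------------------------------------------------------------------

def test_wavelength_fit_recovers_known_quadratic():
    truth = np.array([455.8, 0.165, 1.5e-6])
    pos = np.linspace(10, 500, 12)
    lam = np.polynomial.polynomial.polyval(pos, truth)
    coeffs, rms = fit_wavelength_solution(pos, lam, degree=2)
    assert np.allclose(coeffs, truth, rtol=1e-8)
    assert rms < 1e-10


def test_wavelength_fit_identity_dispersion():
    pos = np.arange(5, dtype=float)
    coeffs, _ = fit_wavelength_solution(pos, pos, degree=1)
    assert np.allclose(coeffs, [0.0, 1.0], atol=1e-12)


def test_wavelength_fit_underdetermined():
    with pytest.raises(ValueError, match="at least 3 lines"):
        fit_wavelength_solution([1.0, 2.0], [450.0, 451.0], degree=2)


def test_arc_frame_calibration_recovery(beads_layout):
    """Dispersion fitted from a simulated arc frame agrees with the
    simulator's polynomial to <= 0.01 channel RMS."""
    lines_nm = (460.0, 475.5, 492.3, 510.8, 524.4, 535.1)
    scene = scenes.arc_scene((5, 5), lines_nm)
    schedule = make_schedule("sequential", 1, 1.0)
    frame = render_frame(scene, BLUE, schedule, beads_layout, noise=False)
    spec = extract_traces(frame)[12].spectrum_l1
    centroids = find_line_centroids(spec)
    assert centroids.size == len(lines_nm)
    coeffs, _ = fit_wavelength_solution(centroids, np.asarray(lines_nm), degree=2)
    axis = beads_layout.wavelength_axis()
    cols = np.arange(len(axis), dtype=float)
    fitted = np.polynomial.polynomial.polyval(cols, coeffs)
    rms_channels = np.sqrt(np.mean(((fitted - axis.values) / axis.step) ** 2))
    assert rms_channels <= 0.01


# ---------------------------------------------------------------------------
# flat fielding
# ---------------------------------------------------------------------------

def test_flat_identity_response():
    spec = np.arange(10, dtype=float)
    assert np.allclose(apply_flat(spec, np.ones(10)), spec)


def test_flat_zero_channel_masked():
    spec = np.ones(5)
    resp = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
    out = apply_flat(spec, resp)
    assert np.isnan(out[2]) and np.isfinite(out[[0, 1, 3, 4]]).all()


def test_flat_divides_out_simulated_response(beads_preset):
    """A smooth response imposed at render time is recovered by apply_flat."""
    n_cols = 256
    ramp = 1.0 + 0.4 * np.sin(np.linspace(0, np.pi, n_cols))
    ramp /= ramp.mean()  # unit-mean response: flat correction recovers the input exactly
    layout = pipeline.layout_for_preset(beads_preset, n_cols=n_cols, response=ramp)
    frame = pipeline.simulate_preset(beads_preset, layout=layout, noise=False, readout=False)
    plain_layout = pipeline.layout_for_preset(beads_preset, n_cols=n_cols)
    reference = pipeline.simulate_preset(beads_preset, layout=plain_layout, noise=False, readout=False)
    got = apply_flat(extract_traces(frame)[6].spectrum_l1, ramp)
    want = extract_traces(reference)[6].spectrum_l1
    # apply_flat divides by the unit-mean response, so the flat continuum is
    # recovered exactly (noise-free), up to nothing at all: ramp cancels
    assert np.allclose(got, want, rtol=1e-9)


# ---------------------------------------------------------------------------
# cube assembly
# ---------------------------------------------------------------------------

def test_assemble_cubes_mask_arithmetic(beads_frame_noise_free, beads_layout):
    pairs = extract_traces(beads_frame_noise_free)
    mask = np.ones((5, 5), dtype=bool)
    mask[0, :] = False  # discard the shaded top spaxel row
    c1, c2 = assemble_cubes(pairs, beads_layout.wavelength_axis(), scene_mask=mask)
    assert c1.grid_shape == (5, 5)
    assert c1.mask.sum() == 20
    assert c1.spectra().shape[0] == 20
    assert len(c1.axis) == len(c2.axis) == beads_frame_noise_free.counts.shape[1]


def test_assemble_cubes_empty_input():
    with pytest.raises(ValueError, match="no trace pairs"):
        assemble_cubes([], np.array([0.0, 1.0]))


def test_pairing_roundtrip_is_bijective(beads_frame_noise_free):
    """Each extracted pair maps back to the scene position used at render time."""
    pairs = extract_traces(beads_frame_noise_free)
    ids = [p.spaxel_id for p in pairs]
    assert len(ids) == len(set(ids)) == 25
    assert set(ids) == {(i, j) for i in range(5) for j in range(5)}
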