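"""End-to-end glue: simulate -> reduce -> SERDS -> cluster.

These functions chain the per-module operations in the canonical order
(extract, despike, calibrate, assemble cubes, subtract, reconstruct, SNIP,
optionally normalize, cluster) and are shared by the command-line interface,
the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chemometrics, reduction, serds
from .ccd import DetectorFrame, TraceLayout, add_readout_noise, render_frame
from .forward import ExcitationPair, pair_channel_shift
from .reduction import DataCube
from .scenes import ScenePreset
from .serds import DifferenceCube, ReconstructedCube

__all__ = [
    "layout_for_preset",
    "simulate_preset",
    "reduce_frame",
    "serds_chain",
    "run_pipeline",
    "best_match_agreement",
    "PipelineResult",
]


def layout_for_preset(
    preset: ScenePreset,
    n_cols: int = 512,
    trace_pitch: int = 10,
    shuffle_offset: int = 5,
    **overrides,
) -> TraceLayout:
    """Build a trace layout sized to a preset's grid and spectral window."""
    rows_grid, cols_grid = preset.scene.grid_shape
    n_traces = rows_grid * cols_grid
    row_origin = overrides.pop("row_origin", 2)
    need = row_origin + (n_traces - 1) * trace_pitch + shuffle_offset + 4
    frame_rows = overrides.pop("frame_rows", int(np.ceil(need / 256.0)) * 256)
    lo, hi = preset.dispersion_window_nm
    return TraceLayout(
        frame_shape=(frame_rows, n_cols),
        trace_pitch=trace_pitch,
        shuffle_offset=shuffle_offset,
        block_size=cols_grid,
        n_blocks=rows_grid,
        dispersion=(lo, (hi - lo) / n_cols),
        row_origin=row_origin,
        **overrides,
    )


def simulate_preset(
    preset: ScenePreset,
    layout: TraceLayout | None = None,
    seed: int | None = None,
    noise: bool = True,
    readout: bool = True,
    readout_noise_sigma: float = 3.0,
) -> DetectorFrame:
    """Render a preset into a single nod-and-shuffle frame and read it out."""
    layout = layout or layout_for_preset(preset)
    frame = render_frame(
        preset.scene,
        preset.pair,
        preset.schedule,
        layout,
        seed=seed,
        noise=noise,
        readout_noise_sigma=readout_noise_sigma if noise else 0.0,
    )
    if readout:
        add_readout_noise(frame, seed=None if seed is None else seed + 7919)
    return frame


def reduce_frame(
    frame: DetectorFrame,
    aperture: int = 2,
    weighted: bool = False,
    despike_spectra: bool = True,
    scene_mask: np.ndarray | None = None,
) -> tuple[DataCube, DataCube]:
    """Raw frame -> two wavelength-calibrated cubes (one per excitation)."""
    pairs = reduction.extract_traces(frame, aperture=aperture, weighted=weighted)
    if despike_spectra:
        for p in pairs:
            p.spectrum_l1 = reduction.despike(p.spectrum_l1)
            p.spectrum_l2 = reduction.despike(p.spectrum_l2)
    if frame.layout.response is not None:
        for p in pairs:
            p.spectrum_l1 = reduction.apply_flat(p.spectrum_l1, frame.layout.response)
            p.spectrum_l2 = reduction.apply_flat(p.spectrum_l2, frame.layout.response)
    axis = frame.layout.wavelength_axis()
    return reduction.assemble_cubes(pairs, axis, scene_mask=scene_mask)


def serds_chain(
    cube_l1: DataCube,
    cube_l2: DataCube,
    pair: ExcitationPair,
    snip_half_width: int = 40,
) -> tuple[DifferenceCube, ReconstructedCube]:
    """Subtract, reconstruct, SNIP-correct, and attach the Raman-shift axis.

    The difference is formed on the shared detector grid; the relative
    wavenumber axis of the lower excitation wavelength is attached to the
    reconstructed cube afterwards.
    """
    delta = pair_channel_shift(cube_l1.axis, pair)
    prov = {"delta_channels": delta, "lambda1": pair.lambda1, "lambda2": pair.lambda2}
    diff = serds.subtract_pairs(cube_l1, cube_l2, provenance=prov)
    recon = serds.reconstruct_cube(diff)
    corrected = serds.snip_cube(recon, snip_half_width)
    # wavenumber calibration of the reconstruction: the moving-sum value at
    # channel x summarises the window [x-delta+1, x], whose center sits
    # (delta-1)/2 channels lower, so the axis is shifted accordingly
    from .forward import SpectralAxis

    lam = cube_l1.axis.values - cube_l1.axis.step * (delta - 1) / 2.0
    recon_lambda_axis = SpectralAxis("wavelength-nm", lam)
    nu_axis = serds.to_relative_wavenumber(recon_lambda_axis, pair.lambda1)
    nu_axis.channel_shift = delta
    recon.axis = nu_axis
    corrected.axis = nu_axis
    return diff, corrected


@dataclass
class PipelineResult:
    frame: DetectorFrame
    cube_l1: DataCube
    cube_l2: DataCube
    difference: DifferenceCube
    reconstructed: ReconstructedCube
    label_grid: np.ndarray | None = None
    cluster_model: chemometrics.ClusterModel | None = None


def run_pipeline(
    preset: ScenePreset,
    seed: int | None = None,
    k: int | None = None,
    normalize: bool = False,
    cluster_on: str = "difference",
    layout: TraceLayout | None = None,
    noise: bool = True,
) -> PipelineResult:
    """Full chain on a preset: simulate, reduce, SERDS, optional clustering.

    ``cluster_on`` selects the clustering input: raw SERDS difference
    spectra (default) or the baseline-corrected reconstruction
    (``"reconstructed"``).
    """
    frame = simulate_preset(preset, layout=layout, seed=seed, noise=noise)
    cube1, cube2 = reduce_frame(frame, scene_mask=preset.scene.mask)
    diff, recon = serds_chain(cube1, cube2, preset.pair, preset.snip_half_width)
    result = PipelineResult(frame, cube1, cube2, diff, recon)
    if k is not None:
        cube = diff if cluster_on == "difference" else recon
        result.label_grid, result.cluster_model = chemometrics.cluster_cube(
            cube, k, normalize=normalize
        )
    return result


def best_match_agreement(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    """Fraction of spaxels agreeing after optimal cluster-to-region relabelling."""
    from scipy.optimize import linear_sum_assignment

    t = np.asarray(labels_true).ravel()
    p = np.asarray(labels_pred).ravel()
    if t.size != p.size:
        raise ValueError("label arrays differ in size")
    t_vals, t_inv = np.unique(t, return_inverse=True)
    p_vals, p_inv = np.unique(p, return_inverse=True)
    confusion = np.zeros((t_vals.size, p_vals.size))
    np.add.at(confusion, (t_inv, p_inv), 1)
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum() / t.size)
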