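"""Synthetic scene presets mirroring the demonstration samples.

Three study scenes are provided:

* ``tablets`` — two pharmaceutical pills (paracetamol-like, aspirin-like) on
  an otherwise empty probe head, NIR excitation pair 784.43/785.48 nm, with
  a fluorescent room lamp switched on for 3 s during the acquisition;
* ``beads``   — polystyrene (PS) and poly(methyl methacrylate) (PMMA)
  microbeads on a CaF2 window, blue pair 457.74/458.90 nm;
* ``tissue``  — a lipid/protein tissue section (pork-like), blue pair, with
  strong photobleaching autofluorescence.

Band inventories for PS, PMMA, lipid and protein use the standard marker
positions of those materials; the paracetamol/aspirin band lists are
synthetic fixtures with plausible pharmaceutical-band positions (the exact
inventories are configuration choices, not ground truth).  Scatter scales
encode that lipids have a higher Raman scattering cross-section than
proteins.  Each preset carries a ground-truth label grid so downstream
clustering can be scored without re-deriving regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import (
    AcquisitionSchedule,
    AnalyteModel,
    BackgroundModel,
    ExcitationPair,
    RamanBand,
    RoomLight,
    Scene,
    make_schedule,
)

__all__ = [
    "ScenePreset",
    "PS",
    "PMMA",
    "LIPID",
    "PROTEIN",
    "PARACETAMOL",
    "ASPIRIN",
    "PS_MARKERS",
    "PMMA_MARKERS",
    "tablets_scene",
    "beads_scene",
    "tissue_scene",
    "arc_scene",
    "get_preset",
    "KR_LAMP_LINES_NM",
]


def _bands(spec) -> tuple[RamanBand, ...]:
    return tuple(RamanBand(c, w, a) for c, w, a in spec)


PS = AnalyteModel(
    "polystyrene",
    _bands(
        [
            (621, 12, 150),
            (999, 10, 1000),
            (1031, 10, 300),
            (1155, 14, 120),
            (1450, 14, 150),
            (1590, 12, 350),
            (3047, 22, 450),
        ]
    ),
)

PMMA = AnalyteModel(
    "pmma",
    _bands(
        [
            (812, 14, 400),
            (968, 14, 200),
            (1444, 16, 600),
            (1718, 16, 350),
            (2935, 26, 700),
        ]
    ),
)

# marker bands used for the intensity maps (cm^-1)
PS_MARKERS = (999.0, 1590.0, 3047.0)
PMMA_MARKERS = (1444.0, 1718.0, 2935.0)

LIPID = AnalyteModel(
    "lipid",
    _bands(
        [
            (1060, 16, 300),
            (1300, 18, 400),
            (1446, 18, 600),
            (1650, 18, 300),
            (1740, 16, 250),
            (2850, 30, 800),
            (2900, 30, 700),
        ]
    ),
    scatter_scale=2.5,
)

PROTEIN = AnalyteModel(
    "protein",
    _bands(
        [
            (754, 16, 150),
            (858, 14, 180),
            (894, 14, 100),
            (1004, 10, 250),
            (1075, 14, 100),
            (1099, 14, 100),
            (1128, 14, 100),
            (1282, 18, 200),
            (1363, 14, 120),
            (1587, 16, 150),
            (1638, 20, 250),
            (2935, 34, 400),
        ]
    ),
    scatter_scale=1.0,
)

# synthetic pharmaceutical fixtures (band lists are placeholders, see module docstring)
PARACETAMOL = AnalyteModel(
    "paracetamol",
    _bands(
        [
            (797, 10, 400),
            (857, 10, 600),
            (1168, 10, 300),
            (1236, 10, 350),
            (1323, 10, 450),
            (1561, 12, 400),
            (1648, 12, 500),
        ]
    ),
)

ASPIRIN = AnalyteModel(
    "aspirin",
    _bands(
        [
            (749, 10, 450),
            (1044, 10, 500),
            (1190, 10, 250),
            (1292, 10, 300),
            (1606, 12, 600),
        ]
    ),
)

# krypton-like fluorescent-lamp emission lines (nm) inside the NIR window
KR_LAMP_LINES_NM = (805.95, 811.29, 819.01, 826.32, 829.81, 877.67)

NIR_PAIR = ExcitationPair(784.43, 785.48)
BLUE_PAIR = ExcitationPair(457.74, 458.90)


@dataclass
class ScenePreset:
    """A scene plus the excitation pair and schedule it is meant to run with."""

    name: str
    scene: Scene
    pair: ExcitationPair
    schedule: AcquisitionSchedule
    dispersion_window_nm: tuple[float, float]
    snip_half_width: int = 40
    marker_bands: dict | None = None


def _empty_arrays(grid_shape, n_analytes):
    r, c = grid_shape
    return (
        np.zeros((r, c, n_analytes)),
        np.zeros((r, c)),
        np.ones((r, c), dtype=bool),
        np.zeros((r, c), dtype=int),
    )


def tablets_scene(
    grid_shape: tuple[int, int] = (7, 7),
    n_cycles: int = 200,
    t_exp: float = 0.2,
    room_light_amplitude: float = 3000.0,
) -> ScenePreset:
    """Two pills and empty probe-head space, NIR pair, room lamp on for 3 s.

    The default schedule is the full tablet protocol (200 accumulations of
    200 ms per wavelength); the fluorescent lamp switches on 1 s into the
    acquisition for 3 s, so its lines are a small perturbation on the pill
    spectra but the dominant signature of the empty spaxels.

    Labels: 1 = paracetamol (left), 2 = empty/room light (center strip),
    3 = aspirin (right).  The lamp window in general exposes the two
    wavelengths unequally and leaves the residual room-light lines the
    empty-space cluster is identified by.
    """
    r, c = grid_shape
    weights, fluor, mask, labels = _empty_arrays(grid_shape, 2)
    third = max(1, c // 3)
    labels[:, :third] = 1
    labels[:, third : c - third] = 2
    labels[:, c - third :] = 3
    weights[:, :, 0] = (labels == 1) * 1.0
    weights[:, :, 1] = (labels == 3) * 1.0
    fluor[labels != 2] = 0.3
    schedule = make_schedule("interleaved", n_cycles, t_exp)
    lamp_on = min(1.0, 0.25 * schedule.duration)
    scene = Scene(
        analytes=(PARACETAMOL, ASPIRIN),
        weights=weights,
        fluor_amplitude=fluor,
        mask=mask,
        background=BackgroundModel(
            amplitude=200.0,
            shape_kind="gaussian",
            shape_center=830.0,
            shape_fwhm=120.0,
            decay_kind="exponential",
            decay_tau=8.0,
        ),
        room_light=RoomLight(
            lines=tuple((lam, room_light_amplitude) for lam in KR_LAMP_LINES_NM),
            on_window=(lamp_on, min(lamp_on + 3.0, schedule.duration)),
        ),
        labels=labels,
    )
    return ScenePreset(
        name="tablets",
        scene=scene,
        pair=NIR_PAIR,
        schedule=schedule,
        dispersion_window_nm=(786.0, 906.0),
        snip_half_width=40,
    )


def beads_scene(
    grid_shape: tuple[int, int] = (7, 7),
    n_cycles: int = 10,
    t_exp: float = 0.1,
    seed: int = 0,
) -> ScenePreset:
    """Scattered PS spaxels and a PMMA block on a clean window, blue pair.

    Labels: 0 = bare window, 1 = PS, 2 = PMMA.
    """
    r, c = grid_shape
    weights, fluor, mask, labels = _empty_arrays(grid_shape, 2)
    rng = np.random.default_rng(seed)
    # PMMA: a contiguous block in the lower-right quadrant
    labels[r // 2 :, c // 2 :] = 2
    # PS: scattered spaxels outside the PMMA block
    candidates = np.argwhere(labels == 0)
    n_ps = max(3, candidates.shape[0] // 4)
    for i, j in candidates[rng.choice(candidates.shape[0], size=n_ps, replace=False)]:
        labels[i, j] = 1
    weights[:, :, 0] = (labels == 1) * 1.0
    weights[:, :, 1] = (labels == 2) * 1.0
    # bare window keeps a faint substrate glow so every spaxel has signal
    fluor[:] = np.where(labels > 0, 0.2, 0.05)
    scene = Scene(
        analytes=(PS, PMMA),
        weights=weights,
        fluor_amplitude=fluor,
        mask=mask,
        background=BackgroundModel(
            amplitude=100.0,
            shape_kind="gaussian",
            shape_center=490.0,
            shape_fwhm=60.0,
            decay_kind="exponential",
            decay_tau=10.0,
        ),
        labels=labels,
    )
    return ScenePreset(
        name="beads",
        scene=scene,
        pair=BLUE_PAIR,
        schedule=make_schedule("interleaved", n_cycles, t_exp),
        dispersion_window_nm=(456.0, 540.0),
        snip_half_width=30,
        marker_bands={"PS": PS_MARKERS, "PMMA": PMMA_MARKERS},
    )


def tissue_scene(
    grid_shape: tuple[int, int] = (7, 7),
    n_cycles: int = 40,
    t_exp: float = 0.05,
    mode: str = "interleaved",
) -> ScenePreset:
    """Lipid/protein tissue section with photobleaching autofluorescence.

    Labels: 1 = protein-rich (right), 2 = lipid-rich (left).  The protein
    region carries the higher fluorescence background; lipid has the higher
    scattering cross-section, so the lipid cluster mean comes out more
    intense.
    """
    r, c = grid_shape
    weights, fluor, mask, labels = _empty_arrays(grid_shape, 2)
    split = c // 2 + (c % 2)
    labels[:, :split] = 2
    labels[:, split:] = 1
    lipid_region = labels == 2
    # dominant analyte with slight admixture of the other
    weights[:, :, 0] = np.where(lipid_region, 0.85, 0.15)
    weights[:, :, 1] = np.where(lipid_region, 0.15, 0.85)
    fluor[:] = np.where(lipid_region, 0.6, 1.0)
    scene = Scene(
        analytes=(LIPID, PROTEIN),
        weights=weights,
        fluor_amplitude=fluor,
        mask=mask,
        background=BackgroundModel(
            amplitude=2000.0,
            shape_kind="gaussian",
            shape_center=500.0,
            shape_fwhm=70.0,
            decay_kind="exponential",
            decay_tau=3.0,
        ),
        labels=labels,
    )
    return ScenePreset(
        name="tissue",
        scene=scene,
        pair=BLUE_PAIR,
        schedule=make_schedule(mode, n_cycles, t_exp),
        dispersion_window_nm=(456.0, 540.0),
        snip_half_width=30,
        marker_bands={"lipid_ch": (2900.0,)},
    )


def arc_scene(grid_shape: tuple[int, int], lines_nm, amplitude: float = 5000.0) -> Scene:
    """Arc-lamp calibration scene: emission lines only, always on."""
    weights, fluor, mask, _ = _empty_arrays(grid_shape, 0)
    return Scene(
        analytes=(),
        weights=weights,
        fluor_amplitude=fluor,
        mask=mask,
        background=BackgroundModel(amplitude=0.0),
        room_light=RoomLight(
            lines=tuple((float(lam), amplitude) for lam in lines_nm),
            on_window=(0.0, 1e9),
        ),
    )


_PRESETS = {"tablets": tablets_scene, "beads": beads_scene, "tissue": tissue_scene}


def get_preset(name: str, grid_shape: tuple[int, int] = (7, 7), **kwargs) -> ScenePreset:
    """Look up a scene preset by name."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown scene preset {name!r}; choose from {sorted(_PRESETS)}")
    return factory(grid_shape=grid_shape, **kwargs)
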