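# Methods

## Physical model

**Axes.** All conversions use vacuum-style wavenumbers: a band at Raman
shift ν̃ (cm⁻¹) under excitation λ_exc (nm) sits at λ = 10⁷ / (10⁷/λ_exc − ν̃)
nm; the separation of an excitation pair is Δν̃ = 10⁷(1/λ₁ − 1/λ₂). The
detector column → wavelength mapping is a polynomial (default linear);
cubes carry either the wavelength axis or the Raman-shift axis of λ₁.

**Bands.** Raman bands are pseudo-Voigt profiles with configurable
Gaussian fraction, default pure Lorentzian (no lineshape is mandated by the
underlying measurement technique). Profiles are *bin-integrated* through
their analytic CDFs, so band flux is conserved exactly per channel;
amplitudes are photon rates (photons/s) and per-slot counts are amplitude ×
exposure. Analytes are band lists with a relative scattering cross-section
(`scatter_scale`); the lipid fixture uses 2.5 vs 1.0 for protein, encoding
the higher Raman cross-section of lipids.

**Instrument broadening.** Every emission component (bands, background,
lines) is convolved with a unit-sum Gaussian kernel of FWHM 0.22 nm — the
spectrograph resolution — before deposition. Delta-like emission lines
(room light, arc lamps) are first shared linearly between the two channels
adjacent to their wavelength, which conserves both flux and the
sub-channel centroid; this is what lets arc-lamp dispersion fits recover
the true polynomial to ≲ 0.01 channel.

**Background and photobleaching.** The autofluorescence background is a
smooth non-negative shape in wavelength (flat or broad Gaussian) scaled per
spaxel, with one of three temporal laws under continued illumination:
constant, linear `max(0, 1 − m t)`, or exponential `exp(−t/τ)`. Decay is
integrated in closed form over each exposure slot (the linear law is
clipped at zero piecewise). Bleaching is spectrally uniform — the shape
does not change, only its level — which is the stated observation the
technique exploits; nothing else about real fluorophore kinetics is
modelled. Room light is a set of wavelength-fixed lines that are nonzero
only inside an on/off time window.

**Schedules.** An acquisition schedule is an ordered list of
non-overlapping slots (wavelength index, start, exposure). `interleaved`
mode (nod and shuffle) alternates λ₁/λ₂ in 2N short slots; `sequential`
mode exposes each wavelength once for N·t_exp. Both give equal total
exposure per wavelength — an invariant of the type. For a linear bleaching
slope m the λ₁/λ₂ background imbalance is m·T² sequential vs m·T²/N
interleaved (T = N·t_exp per wavelength), so the residual-background
metric ratio is exactly N; for exponential decay with τ ≫ t_exp the same
holds to first order (measured 39.97 at N = 40, τ = 20 s, t_exp = 50 ms).

## Detector model

Each spaxel's spectrum is a horizontal trace with a Gaussian cross-profile
in rows (σ = 0.7 rows, truncated at ±3σ on integer offsets and
renormalized, so all charge stays within ±2 rows). λ₁ traces repeat every
10 rows (`trace_pitch`); the paired λ₂ trace sits 5 rows up
(`shuffle_offset`), both on the same columns. Twenty traces per wavelength
form one block per spaxel-image row in the full 4096 × 4096 / 20 × 20
layout; the pitch of 10 follows from 800 traces centred on 4096 rows with
the shuffle landing midway between recording positions. The compact test
layout keeps pitch 10 and shuffle 5 on a 512 × 512 frame, which fits 7 × 7
spaxels (98 traces in 490 rows) — an 8 × 8 grid would need 640 rows at this
pitch, so the smaller grid is used for fast tests.

Shot noise is Poisson, drawn per exposure slot on the expected 2-D patch;
charge accumulates across slots without intermediate readout. Readout noise
is a single Gaussian draw per pixel applied exactly once per frame —
`add_readout_noise` refuses a second application. Saturated pixels are
flagged in a mask plane, never clipped silently. Crosstalk between the
interlaced neighbours is quantified analytically: the fraction of a
Gaussian trace's charge inside the partner's extraction aperture at offset
s is ½[erf((s+a+½)/σ√2) − erf((s−a−½)/σ√2)]; traces whose estimated leak
exceeds a configurable fraction of the partner's own counts are flagged.

## Reduction chain

Extraction is boxcar over ±2 rows by default (the 5-row pair separation
leaves the apertures disjoint); profile-weighted ("optimal") extraction is
available and required if apertures would overlap. Despiking replaces runs
of at most 2 channels that exceed the rolling median by 8 MAD with linear
interpolation: cosmic hits deposit in 1–2 channels, while the narrowest
real features — emission lines at the instrument resolution — span 3 or
more after binning and convolution, so they survive. (A wider `max_width`
was observed to clip room-light lines inconsistently between the two
wavelength images and was rejected.) Wavelength solutions are least-squares
polynomials (default degree 2) through arc-line centroids; intensity
calibration divides by a unit-mean white-light response, masking
non-positive channels. Cubes are assembled per excitation on the shared
detector axis; masked spaxels (e.g. shaded border rows) carry no spectra.

## SERDS arithmetic

Subtraction is always λ₁ − λ₂, channel-wise on the detector grid with no
resampling — the nod-and-shuffle geometry records both spectra on the same
pixels, which is the point. Reconstruction is the plain cumulative sum in
ascending channel order, so the telescoping identity
`cumsum(S − shift(S, δ)) = moving_sum(S, δ)` holds exactly for any
spectrum and any integer δ ≥ 1 (property-tested over δ ∈ [1, 64]).
Because the moving-sum value at channel x summarises the window
[x−δ+1, x], the Raman-shift axis attached to reconstructed cubes is
shifted by (δ−1)/2 channels — the analogue of re-calibrating wavenumber on
reconstructed spectra; without it every reconstructed band would read
≈ Δν̃/2 too high. SNIP baseline correction then removes the pedestal the
quasi-integration leaves: a decreasing-window clip (m = M…1, point ←
min(itself, mean of neighbours at ±m)) in log-log-sqrt space by default.
M defaults to roughly twice the broadest expected band width in channels;
the presets use 30–40. The residual-background metric is the median of
|difference| over band-free channels (default: the outer 10% of the axis
at each end), averaged over unmasked spaxels.

## Chemometrics

Clustering follows the standard spectroscopy recipe: Pearson correlation
distance d = 1 − r between spaxel spectra, agglomerated with Ward's
minimum-variance criterion in the Ward.D2 convention (Lance–Williams on
squared distances, via scipy's ward linkage on the precomputed condensed
matrix), cut at a user-chosen k — k is a required parameter, not
estimated. Difference spectra are clustered raw by default; vector
normalization (unit Euclidean norm) is switchable for scenes where
intensity differences would otherwise dominate, at the cost of amplifying
any room-light residual. Marker-band intensity maps average the
reconstructed, baseline-corrected spectra over ± window/2 around each
listed band and then over bands; cluster identity is assigned by comparing
cluster means against ground truth or marker bands, never by label index.

## Synthetic scenes: what they do and do not show

The three presets mirror the demonstration samples: `tablets` (two pills +
empty space, NIR pair 784.43/785.48 nm, fluorescent lamp on for 3 s from
t = 1 s, full 200 × 200 ms protocol — cheap at 7 × 7 spaxels), `beads`
(scattered PS + a PMMA block on a faintly glowing window, blue pair
457.74/458.90 nm, 40-cycle class schedule scaled to 10 × 100 ms), and
`tissue` (lipid/protein halves with 15% cross-mixing, strong exponential
bleaching, 40 × 50 ms). Band inventories for PS, PMMA, lipid and protein
use the standard marker positions of those materials; the
paracetamol/aspirin lists are synthetic placeholder fixtures. Ground-truth
labels ride along in a JSON sidecar so tests never re-derive regions.

The simulator reproduces the *mechanisms* the technique addresses —
shift-invariant backgrounds, bleaching kinetics, room-light windows,
interlaced geometry, one-shot readout noise — under idealized conditions:
perfectly known dispersion, no trace curvature or PSF variation, no
charge-transfer inefficiency, no cosmic rays unless injected, simplified
band inventories. Passing tests therefore validate the reduction
arithmetic and the schedule-dependent cancellation properties, not
radiometric realism or classification performance on real tissue.

## Numerical choices and limitations

Problem sizes in tests and the acceptance script are chosen so the full
chain runs in seconds: 7 × 7 spaxels on 512-column frames for the study
scenes, a 4096-row × 64-column frame for the 400-pair geometry check.
Determinism: one `numpy` Generator seeded per frame render plus a derived
seed for readout noise; identical seeds give byte-identical frames. Ties
in Ward merges follow scipy's deterministic nearest-neighbour chain.
Degenerate inputs raise rather than warn: non-positive wavelengths,
overlapping apertures, constant spectra in Pearson distance, zero vectors
in normalization, a second readout-noise application. Known limitations:
no anti-Stokes region, no alternative reconstruction schemes
(deconvolution, least-squares inversion), saturation flagged but not
modelled non-linearly, and the FITS layer covers simple image HDUs only.
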