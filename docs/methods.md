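# Methods

## Forward model

The object is a 2D complex transmittance `s(r) = A(r)·e^{jφ(r)}` on a
high-resolution (HR) grid of pixel size `p_hr = p_cam/(M·q)` µm, where
`p_cam` is the camera pitch (4.54 µm), `M` the effective magnification
(4.29) and `q` the upsampling factor (default 5, so 1.058/5 ≈ 0.212 µm).
The model is strictly coherent and monochromatic: partial coherence, the
~20 nm LED bandwidth, vignetting and sensor non-uniformity are not
modelled. Illumination is a plane wave per LED; the LED grid is assumed
centred on the optical axis (the axis coincides with a LED, which is what
makes a 177-LED — 1+4k — circular subset achievable; a configurable axis
offset is supported). All spectra are stored centred (DC at `n//2`,
fftshift layout), everywhere.

Per LED, the low-resolution (LR) intensity is formed in the Fourier
domain: the centred HR spectrum block of LR size located at the LED's
illumination frequency (rounded to the nearest spectral pixel — no
sub-pixel interpolation, so forward and inverse use the same discrete
offsets) is masked by the binary pupil (radius `NA_MO/λ`), inverse
transformed at the LR sampling and squared. Downsampling is therefore
ideal band-limited (spectral cropping), consistent with a coherent
band-limited image; intensities are normalised so a flat unit-amplitude
object under the on-axis LED gives exactly 1. Optional Poisson shot noise
(mean photon count per unit intensity, default 10⁴ when enabled) and
12-bit quantization (integer digital numbers scaled to the stack maximum)
follow; exposure is assumed equal across LEDs — users importing measured
stacks with per-LED exposure variation must normalise first.

## Reconstruction

Sequential alternate projections with hard replacement: for each LED (in
centre-outward radial order, the standard choice for stable convergence;
the acquisition order is also available), the pupil-supported sub-spectrum
is inverse-transformed, the modulus of the LR field estimate is replaced
by `√I_i` keeping its phase, and the transform is written back only within
the pupil support. No relaxation and no pupil refinement (the pupil is an
ideal binary circle; aberration recovery is out of scope). The initial
guess is the upsampled square root of the on-axis frame with zero phase
(`flat` initialisation — all energy at DC — is available and coincides
with it for a flat object). The iteration count is fixed at 60 by default;
an optional early stop triggers when the relative spectrum change drops
below `convergence_tol`.

Convergence behaviour worth knowing: the noise-free consistent solution is
an exact fixed point (verified to machine precision in the tests), and the
data-fidelity trace is monotone, but the error against ground truth decays
roughly like 1/iterations — at 60 iterations a reduced-scale in-band
round trip reaches ~0.04 rad full-map phase RMSE, while the residual
localized on structure edges (~0.08 rad) keeps shrinking to <0.02 rad by
~200–250 iterations. Tests that assert structure-level recovery therefore
run the solver to convergence; the 60-iteration budget is asserted on the
full-map error and on data fidelity.

If adjacent LEDs' shifted pupils overlap by less than 40% of their area
the reconstruction emits a warning: alternate projections need shared
spectral support to transfer phase between sub-apertures. The default
geometry sits at 47%.

All comparisons to ground truth first remove the global phase (and a
global amplitude scale where intensities were rescaled), to which phase
retrieval is blind. Output phase is wrapped in (−π, π]; unwrapping is a
deliberate, separate step.

## Phantoms

`phantom` renders kidney-like structures — glomerular tufts (smooth
Gaussian blobs in a capsule disk), tubule/vessel cross-sections (annuli),
red blood cells (small high-phase disks) — plus two-point and Siemens-star
resolution targets. Phase sums over structures and is normalised to
`max_phase`; amplitude is 1 until a stain is applied. Structures get a
1-pixel Gaussian edge blur so the ground truth is not dominated by
single-pixel spectra (keeping the weak-scattering picture meaningful). One
seeded generator drives every random draw; phantoms are bitwise
reproducible.

Stains attenuate amplitude multiplicatively, `A·(1 − strength·mask)`, on
the structure classes they target (H&E/Giemsa/BlueTol → nuclei, CKpool →
tubules and capsules, PAS → tubules/membranes, AML → muscle, FVIIIra →
vessels); phase is untouched. Thickness scenarios scale structure phase by
`2π·Δn·t/λ`, so 3 µm at Δn = 0.05 peaks at ~1.49 rad (in range) while
10/20/30 µm exceed π and wrap. No refractive-index data exists for renal
tissue in this context, so Δn is a free parameter (default 0.05) and all
thickness results are stated relative to it.

What the phantoms do *not* emulate: real histology texture and speckle,
RGB stain rendering, sub-resolution scatterers, 3D structure (a phantom is
a single thin layer — the 20/30 µm "scattering zones" are emulated by
injected phase vortices, clearly synthetic). Passing the round-trip tests
therefore shows the solver inverts its own forward model under realistic
geometry, not that it handles multiple scattering in thick tissue — the
20–30 µm slide regime needs multi-slice propagation models, which are out
of scope.

An acquisition determines the object only inside the synthetic aperture,
so round-trip experiments band-limit the phantom (`phantom.bandlimit`) to
0.9 × NA_syn/λ. The margin is uncritical — measured recovery error is
identical for margins 0.7–0.95 — 0.9 is simply "comfortably in-band".

## Resolution

The headline 0.5 µm figure is the half-pitch `λ/(2·NA_syn)`: the finest
grating period the synthetic aperture transfers is `λ/NA_syn` ≈ 1.0 µm.
Note the coherent *two-point* Sparrow distance of a circular aperture is
larger: a central dip between two in-phase point scatterers first appears
near 1.5–1.6× the half-pitch (closed-form jinc PSF analysis, reproduced by
the simulations), and reaches a 0.8 peak-to-dip ratio only around
1.7–1.8×. The resolution-gain test therefore demonstrates a pair at 1.8×
half-pitch (0.90 µm) — resolved in the reconstruction, far below the
3.16 µm objective-only half-pitch and unresolvable in the bright-field
frame, whose 1.058 µm pixels cannot even sample the pair apart.

## Mosaics

Full frames (1460×1940) are processed as 100×100 patches: 266 without
overlap, or with a 40-px LR overlap (stride 60, last tile clamped to the
frame edge) which becomes a 200-px HR overlap at q=5. Stitching places
patches at q-scaled offsets and blends with separable linear feathering
weights normalised to a partition of unity — constant inputs reconstruct
exactly, seams are suppressed. Complex patches are first aligned by a
constant phase to the mosaic built so far on the overlap (each patch's
retrieval carries its own global phase). Stage-scan planning divides a
target slide extent by the camera's object-space FoV
(1.545×2.053 mm) with ceilings per axis — 17.1×9.8 mm needs 9×7 = 63 FoVs.

Known limitation: cutting a patch out of a frame windows the coherent
field, which breaks the periodicity the FFT model assumes; structures
straddling a patch border keep a localized artifact that feathering
reduces but does not remove. The pipeline test asserts the median pixel
error for this reason.

## Phase post-processing

Wrapping uses the half-open convention (−π, π] (unique representative;
the boundary value is +π). Unwrapping is delegated to scikit-image's
deterministic reliability-sorting algorithm and returns a surface defined
up to one global 2π multiple; quantitative use anchors the background
(e.g. median of known-empty pixels). Residues — ±2π circulations of
wrapped gradients around 2×2 loops — are counted in-package;
`thin_sample_ok` flags maps whose residue density stays below 10 per mm²
(a documented heuristic operationalising the qualitative thick-slide
distinction; configurable). Optical thickness is `φ·λ/(2π·Δn)` per pixel;
dry mass integrates phase with the specific refraction increment
α = 0.2 µm³/pg (standard protein value). The pseudo-3D export writes a
heightfield `z = k·φ` with axes in physical µm; `k` (default 10) is purely
for display and never enters quantitative results.

## Problem sizes in the test suite

Unit and property tests run on 64–256 px grids with 5–49 LEDs; the
round-trip experiments use a 64×64 LR patch, 49 LEDs, q=4 (60 iterations
for the budgeted checks, 250 for convergence-level recovery); the
resolution experiment uses 177 LEDs at q=8 on a 64×64 patch; the mosaic
shape check stitches the full 266 patches. These sizes were chosen so the
whole suite exercises every code path at interactive speed while keeping
the instrument geometry (pitch, distance, NA, wavelength) exactly at its
defaults.
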