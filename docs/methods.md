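# Methods

## Scope and model assumptions

`planedose` computes relative planar dose at a single QA plane (fixed
SSD/depth) in homogeneous water. Inverse-square and depth effects, photon
spectra, beam hardening, kernel tilting, electron contamination and 3D dose
are outside the model; they are absorbed into the relative normalisation or
deliberately not modelled. Source occlusion makes the extra-focal model
invalid below 3×3 cm², so such fields are rejected by the source fit.

The machine abstraction is an Elekta-like head: target (z = 0), extra-focal
source plane, MLC (x edges), a single y jaw pair below the MLC, isocenter at
SAD. The paperwork-independent geometry values shipped with the package are
declared assumptions, not measurements:

| quantity | default | note |
|---|---|---|
| SAD | 100 cm | convention |
| z_mlc | 33 cm | Elekta-like upper collimator level |
| z_jaw | 43 cm | lower level |
| source plane (FF / FFF) | 12.5 / 6 cm | filter base / primary-collimator base |
| leaf width at iso | 0.5 cm | Agility-like |
| bulk = interleaf = T&G transmission | 0.01 | published fit values; bulk is a separate knob |
| T&G strip width | 0.026 cm | projected gap |
| interleaf strip width | 0.03 cm | assumption |
| CC13-like detector sigma | 0.20 cm | assumption, config-overridable |

All lateral coordinates are cm projected to the isocenter plane; x is
cross-plane (leaf travel), y in-plane (jaw-defined).

## Numerical choices

* **Leaf-tip transmission.** The rounded-end curve is L(d) = exp(−d^α/β)
  with α = 0.70, β = 0.24 over the first centimetre. This exponent
  arrangement is adopted deliberately: it gives L(1 cm) ≈ 0.016, decaying
  toward the ~1% bulk transmission, whereas the plausible alternatives
  (exp(−dαβ) ≈ 0.85, exp(−(d/β)^α) ≈ 0.066 at 1 cm) do not. Beyond the
  1 cm soft range the aperture machinery switches to bulk transmission
  (0.01); the small downward step there (0.016 → 0.01) is accepted rather
  than forcing continuity.
* **Sub-pixel MLC structure.** Tongue-and-groove (0.26 mm) and interleaf
  (0.3 mm) strips are narrower than the 1 mm dose grid. The transmission
  map integrates the exact piecewise-constant y-profile over each pixel
  (area averaging) instead of requiring a finer lattice. The T&G factor
  (0.01) multiplies the open-side fluence within the strip; interleaf
  transmission replaces bulk where both neighbouring leaves are shielded.
* **Scatter integrals.** Back-projected edges are affine in the
  calculation-point coordinate and separable per axis, so every open leaf
  row contributes an outer product of 1D error-function factors; this is
  exact, and matches 2D adaptive quadrature at 1e-8 relative in the tests.
  Scatter through closed leaves is neglected (≤10% scatter amplitude ×
  ≤1% transmission).
* **Convolution.** The kernel is sampled at pixel centres to a radius of
  3 σ_max and renormalised so its discrete plane integral equals Σ Aᵢ,
  removing discretisation bias at 1 mm spacing; FFT convolution with zero
  padding implements linear convolution (verified against direct summation
  at 1e-10). A separable per-component Gaussian-filter path is used inside
  optimisation loops for speed.
* **Off-axis ratio.** The OAR multiplies the *total* (primary + scatter)
  fluence, with the radius taken at the iso-depth plane. Its absolute scale
  (a₀ ≈ 0.55 in the shipped sets) is irrelevant because planes are
  relatively normalised; evaluation offers a normalised form R(r)/R(0).
* **Gamma.** Exhaustive interpolated search (bilinear, 0.1 mm step over a
  disk of radius 3·DTA) rather than the analytic-ellipse method: simple and
  directly verifiable against a brute-force oracle. Reference = measurement
  by convention; the low-dose threshold applies to the reference maximum;
  local-mode points with non-positive reference dose are excluded and
  counted.
* **Optimisation.** All fits are bounded trust-region least squares with
  seeded multi-starts (5 for the source, fewer for the cheaper stages) and
  tolerances 1e-12; every fit is deterministic given (data, seed,
  tolerances). Source bounds: A ∈ (0, 0.5], σ ∈ [0.05, 20] cm; kernel σ
  ordering is enforced by optimising positive increments; the leaf-end
  parameters are bounded in (0, 5].

## Commissioning design

The stages run in a fixed order with fixed data routing: S꜀ → source;
large-field (30/40 cm) in-field profiles (≥1 cm inside the edges) → OAR;
in-plane profiles of 5/10/20/30 cm fields → kernel (in-plane scans cross
only jaw edges, excluding leaf-tip influence); cross-plane profiles →
leaf end, with the kernel frozen. Computed profiles are convolved with the
Gaussian detector response before comparison, so the fitted model describes
the volume-averaging-free beam — the mechanism that lets a sharp calculated
penumbra coexist with a broadened chamber-scanned measurement.

Two identifiability facts shape the interface. The kernel's absolute
amplitude scale cancels in CAX-normalised profiles, so the fitted kernel is
rescaled to the provisional kernel's plane integral (relative dosimetry is
unaffected). And under measurement noise the *total* extra-focal amplitude
is weakly identified — the broad component's tail lies mostly outside every
visible rectangle — while the predicted S꜀ curve itself is stable; tests
therefore assert the curve, not the tail mass, under noise. The OAR stage
refines its polynomial through three fixed-point iterations because the
OAR factor and the convolution do not commute exactly.

The provisional kernel for the OAR stage is the template model's own
kernel; recovery is insensitive to this choice because only low-gradient
in-field samples enter the fit.

## Synthetic data: what it does and does not show

The generator reproduces the commissioning *design* (field menus with the
4-cm rectangle family held out, 10 cm depth / 90 cm SSD scan conditions, a
staggered 1 cm diode lattice, step-and-shoot plans with ≤70 segments of
≥4 cm² area) with multiplicative Gaussian noise: 0.1% on S꜀, 0.5% on
profiles and planes — repeatability-scale magnitudes chosen as defaults.
Everything is bit-reproducible per seed.

Passing recovery tests on these fixtures shows the estimation machinery is
self-consistent — the staged fits recover the generating parameters and
reconstruct every commissioning profile within 1%/1 mm, and a closed-loop
pseudo-measured IMRT beam passes 2%/2 mm local gamma at ≥95%. It does
*not* show agreement with a physical linac: real measurements carry
detector dose-rate dependence, setup error, beam asymmetries and spectrum
effects the generator deliberately omits, and the shipped FF parameter
sets reuse the same-energy FFF kernel because no FF kernel table ships
with the package.

## Problem sizes

Default grids are 1 mm over the aperture plus margins (typically 200–500
pixels per side). The staged recovery check runs the full field menus with
the kernel stage on four fields at 1 mm; the end-to-end QA loop uses
10-segment beams on a ±10 cm plane over five seeds. These sizes were chosen
so the whole validation runs comfortably on a single CPU while exercising
every code path at the production grid resolution.

## Known limitations

* Relative dosimetry only; the cGy calibration hook is a single scalar.
* One jaw pair (Versa HD layout); a second pair is a config generalisation,
  ignored by default.
* Closed leaf pairs whose touching tips sit inside the field of view show a
  physical leakage ridge; the fixture generator parks closed pairs at the
  row centre, mimicking but not reproducing any specific vendor parking
  strategy.
* No DICOM-RT parsing; the beam JSON dialect documents the mapping instead.
* Gamma search cost grows with (DTA · search factor / step)², fine for
  sparse diode references and small planes; dense 0.1 mm reference grids
  would want the coarse-to-fine refinement this package does not implement.
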