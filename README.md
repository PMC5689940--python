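# planedose

Independent planar dose calculation and gamma QA for flattened (FF) and
flattening-filter-free (FFF) IMRT photon beams.

Patient-specific IMRT QA compares a measured planar dose against the
treatment planning system. An *independent* calculation — a second,
physics-based dose engine fed only by machine parameters and the delivered
segment list — adds a check that does not share the TPS's beam model.
`planedose` implements such an engine for a Versa-HD-like linac with a
single (y) jaw pair below the MLC, for 6/10 MV FF and FFF modes, together
with the staged commissioning procedure that estimates every model
parameter from standard measurements, and the 2D gamma analysis used to
score agreement.

## The model

**Source.** Primary photons are a point source at the target (weight 1).
Head scatter, monitor-chamber backscatter and the collimator exchange
effect are carried by an extra-focal source on a plane below the target
(flattening-filter base for FF, primary-collimator base for FFF), modelled
as a sum of N bivariate Gaussians,

    f(x, y) = Σᵢ Aᵢ / (2π σₓᵢ σᵧᵢ) · exp(−x²/2σₓᵢ² − y²/2σᵧᵢ²),

with x the cross-plane (leaf travel) and y the in-plane (jaw) direction.
N = 2 suffices for the shipped parameter sets.

**Fluence.** The scatter fluence at a point is the integral of f over the
source-plane region visible through the collimators, obtained by
back-projecting the MLC x-edges and jaw y-edges; for rectangles the
integral reduces to error functions. The primary term is the aperture
transmission map, including rounded-leaf-tip transmission
L(d) = exp(−d^α/β), bulk/interleaf leakage and the 0.26 mm
tongue-and-groove strip. FFF planes are multiplied by a rotationally
symmetric off-axis ratio R(r) = Σ aᵢ rⁱ (degree 4).

**Dose.** Planar dose in water is the 2D convolution of the fluence with a
poly-energetic analytical kernel k(r) = Σᵢ Aᵢ/(2π σᵢ²) exp(−r²/2σᵢ²)
(three components), on a 1 mm grid.

**Commissioning.** Four bounded least-squares stages: source from in-air
output factors S꜀ (squares 3–35 cm plus two rectangle families), OAR from
the in-field part of 30/40 cm profiles, kernel from in-plane profiles
(5/10/20/30 cm), leaf end from cross-plane profiles. Computed profiles are
convolved with a Gaussian detector response so chamber volume averaging
does not bias the fitted model.

**QA scoring.** 2D gamma with local or global dose criterion, DTA, and a
low-dose threshold; the evaluated plane is bilinearly interpolated on a
0.1 mm sub-grid.

## Worked example

```python
import planedose as pl

model = pl.load_builtin_model("6FFF")
print(pl.total_extrafocal_intensity(model.source))   # 0.0685
print(pl.central_intensity(model.source))            # 0.019
print(pl.half_max_radius(model.source))              # 0.75 cm
print(pl.compute_sc(model, pl.RectField(3, 3)))      # 0.9783
print(pl.compute_sc(model, pl.RectField(35, 35)))    # 1.0129

beam = pl.make_imrt_plan(pl.FixtureSpec(n_segments=10, seed=1))
meas, calc = pl.make_measurement(model, beam, noise=0.005, seed=1,
                                 half_extent=10.0)
res = pl.gamma_map(meas, calc, pl.GammaCriteria(dose_pct=2, dta=0.2,
                                                threshold_pct=10, mode="local"))
print(res.passing_rate, res.n_evaluated)             # 100.0 % of 162 points
```

The first block evaluates the shipped 6 MV FFF source: the extra-focal
source carries 6.85% of the primary intensity, peaks at 0.019 cm⁻² on
axis, and falls to half maximum at 0.75 cm; S꜀ spans ≈3.5% between 3×3 and
35×35 cm². The second block builds a random 10-segment step-and-shoot
beam, "measures" it on a staggered MapCHECK-like diode lattice with 0.5%
noise, and gamma-compares measurement against calculation at 2%/2 mm
(local) with a 10% threshold — all 162 evaluated diodes pass.

The same operations are available from a shell:

```
planedose sc --energy 6FFF --field 10x10 --field 35x35
planedose simulate --energy 6FFF --out-dir fixtures --seed 1
planedose calc-plane --beam fixtures/beam.json --out plane.txt
planedose gamma --ref fixtures/measured.txt --eval plane.txt --dd 2 --dta 2
planedose commission --sc fixtures/sc.csv --oar-profiles fixtures/profiles_oar.csv \
    --kernel-profiles fixtures/profiles_inplane.csv \
    --leafend-profiles fixtures/profiles_crossplane.csv --model-out fit.json
```

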