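# Methods

## Field model

The solver computes the fractional resonance-frequency offset (ppm) of
each voxel of a volume-susceptibility map χ(r), with the static field
B₀ along z. Susceptibilities are ppm-scale, so (1 + χ) products are
linearized throughout; the neglected χ² terms are ~10⁻¹¹.

**Output convention.** The returned quantity is the *nuclear*
(Lorentz-sphere-corrected) offset — what an NMR resonance reports — not
the macroscopic flux density. Flux-density statements such as the
interface average B = μ₀[1 + (χ₁ + χ₂)/2]H₀ and the bulk cylinder limit
B = μ₀(1 + χ)H₀ are recovered as differences between two points in the
*same* material, because the Lorentz term −χ/3 is constant within one
material. Offsets are defined only up to a global constant; every
reported quantity is a difference. Positive offset = higher frequency =
downfield; a more diamagnetic (more negative χ) environment shifts
resonances upfield.

**Kernel.** The default kernel is built in image space: the point-dipole
field V(3z² − r²)/(4πr⁵) sampled at voxel-center offsets, with zero
self-term, convolved exactly with the χ contrast (χ − χ_background)
using 2× zero padding per axis (no circular wraparound). The zero
self-term is not an approximation: for a cubic voxel the Lorentz-sphere
correction cancels the voxel's own contribution exactly, since a cube's
demagnetizing factor is 1/3. A consequence worth knowing is that the
field of a sphere of voxels vanishes at its center to rounding error
(cubic-lattice symmetry), and that the FFT route and the brute-force
direct summation (`forward_field_direct`) share one discretization, so
the direct sum is an independent oracle of the FFT machinery at
machine precision. The analytic spectral kernel
D(k) = 1/3 − k_z²/|k|² (k = 0 term zeroed) is available as
`kernel="continuous"`; the two agree on resolved geometry and differ
only near the Nyquist scale. Non-cubic voxels are rejected unless
`anisotropic_ok=True`, because the cubic Lorentz cancellation no longer
holds exactly.

**Accuracy (measured by the test suite).** Infinite-cylinder interior
Δχ/3 to 0.02% at 4 voxels/radius; sphere interior offset ≲10⁻¹⁶;
on-axis interface profile (Δχ/2)(1 − h/√(h² + R²)) matched within 0.4%
for 0.15R ≤ h ≤ 5R at 10 voxels/radius. Readings closer than ~1.5
voxels to a contrast boundary carry percent-level lattice deviations,
so measurement grids place material interfaces on voxel *edges*
(`VoxelGrid.for_interface`) and nothing is read inside
partial-contrast voxels.

**Shim emulation.** The bottom of a real tube is an air/condensed-matter
break of ~9.4 ppm whose on-axis gradient (~0.15 ppm across the coil)
dwarfs the 0.03 ppm interface signals of interest; experimentally it is
removed, to first order, by shimming on a plain solvent tube at the same
fill height. The computational analog is exact to first order by
linearity: the field of the sample minus the field of the shim-reference
sample, computed here as one forward pass of the χ-difference map
(`differential_field`). The interface presets (`shigemi`,
`plug_in_tube`) therefore carry their shim-reference scene.

## Closed forms

Demagnetizing factors of a general ellipsoid use the Carlson symmetric
integral R_D (`scipy.special.elliprd`): N_i = (abc/3)·R_D(·), with
N_a + N_b + N_c = 1 identically; a closed-form prolate-spheroid
expression ((1 − e²)/e³)(atanh e − e) serves as a cross-check. The
interior offset of an ellipsoid with c ∥ B₀ is (1/3 − N_c)Δχ — zero for
a sphere, 0.2985·Δχ for the default 1.65/1.65/11.5 mm cavity
(N_c = 0.0348). The on-axis interface formula treats the lower medium as
an equivalent semi-infinite solenoid; only the upper-medium branch
(h ≥ 0) is implemented, and finite solid segments are handled as the
difference of two open ends.

## Line shapes

A spectrum is the weighted histogram of solvent-voxel offsets convolved
with a Lorentzian. Solvent voxels are identified by χ equality within
tolerance, which deliberately excludes partial-volume boundary voxels.
Defaults: Lorentzian FWHM 1 Hz (the non-spinning linewidth the cell
achieves); bin width FWHM/4; spectrometer frequency 600.13 MHz for
Hz↔ppm. The discrete kernel is normalized to unit sum, and the small
Lorentzian mass convolved past the axis ends (≲1% at the default 10-FWHM
padding) is folded back by renormalization, so total intensity equals
total voxel weight exactly — the spectral analog of finite sweep width.

Coil sensitivity is a flat window (default 16 mm) with raised-cosine
roll-off (2 mm), centered 5 mm above the interface in the interface
presets; real cryoprobe profiles are not published, so the profile is
configurable and only its finite extent carries meaning. Slice selection
is an ideal rectangular window of 0.6 mm by default (the
excitation-sculpting selection; RF pulse internals are out of scope),
with a Gaussian option. Slice bandwidth is the closed form
(γ/2π)·G·Δz; 11.5 G/cm and 0.6 mm give 2938 Hz.

`base_width` measures the support of the *stick* histogram above a
threshold fraction of its maximum, so the reading is not inflated by
Lorentzian tails. The default threshold is 1% of the maximum; the 0.55%
option matches the convention of quoting solvent-line humps at 0.55% of
the peak and is the threshold used for the mismatched-tube base-width
diagnostic, whose tail amplitude near the interface is inherently at the
percent level of the bulk peak. Peak position ties break downfield
(documented, deterministic). `projection_profile` returns 1-D density
projections (the one-pulse gradient-encoded image), not center cuts.

## Susceptometry

δ = interface peak − bulk peak (upfield shoulder ⇒ negative δ ⇒ solid
more diamagnetic than solvent); χ_solid = χ_solvent + 2δ. Solvent
references are fraction-weighted mixtures anchored at χ(H₂O) = −9.05 ppm
and χ(D₂O) = −9.01 ppm; the isotope rule Δχ = 2Δδ/span treats the span
as a protonation-fraction difference (0.94 for a 97%/3% pair measured
both ways; mole- vs volume-fraction distinction is numerically
irrelevant at these compositions). The NaCl model is linear with slope
0.2 ppm/M, validated 0–2 M; outside that range the evaluation warns.
Calibration fits are ordinary least squares over all supplied points;
the doping zero crossing is the root of the fitted line and is flagged
as an extrapolation when the points do not bracket a sign change.
Reported χ values are rounded to 2 decimals (the measurement's
meaningful precision); raw values are preserved alongside.

## Geometry and meshes

Scenes paint (shape, χ) regions last-wins over a uniform background,
default air (+0.36 ppm) — the choice is immaterial for same-medium
differences after shim emulation, and configurable otherwise.
Voxelization supersamples 3× per axis (anti-aliased partial-volume
boundaries) and warns when a shape spans fewer than 2 voxels. Lengths
are mm (1 mm³ = 1 µL); 0-based indexing, voxel-center sampling.

The microcell design defaults to interior semi-axes 1.65/1.65/11.5 mm
with a 0.3 mm wall — the printed drawing's interior dimensions are not
published, so the quoted 23 × 3.3 mm envelope is taken as the cavity —
and a 1.3 mm × 8.5 mm access channel (measured bore; designed 1.6 mm).
Analytic volumes: cavity 131.1 µL, channel 11.28 µL, overlap-corrected
total 141.8 µL; the gravimetric total of a printed cell (130 µL) is
smaller because polymerization growth (~0.15 mm sticky layer) shrinks
the realized cavity, which is modeled only as a documented constant
offset option, not predicted.

STL export produces watertight binary meshes. Channel-less shells are
meshed parametrically (subdivided icospheres scaled to the semi-axes;
outer surface plus inverted inner surface), which converges
monotonically in facet count. Designs with a pierced channel have no
parametric seam, and no mesh-boolean backend is assumed, so they are
meshed by marching cubes over a supersampled occupancy fraction of the
implicit solid; `facet_count` maps to the grid pitch as an approximate
resolution target (never coarser than half the wall thickness). Mesh
volume agrees with a brute-force voxel count of the default design to
0.1% at the default 10k-facet target.

## Synthetic data

`generate_synthetic_series` emulates the two calibration experiments:
the NaCl titration (five concentrations 0–2 M, slope 0.2 ppm/M,
intercept −9.01 ppm, Gaussian noise σ = 0.01 ppm — the scatter of
repeated slice readings) and the cobalt(II) doping series (0/2/5 mM
through the measured endpoints +117 Hz and −80 Hz). Series are seeded
and byte-reproducible with provenance headers. The generator produces
ideal linear responses plus i.i.d. noise; it does not emulate lateral
slice gradients, radiation damping, temperature drift of χ, or peak
picking from raw FIDs, so fit-recovery tests validate the calibration
calculus, not spectrometer data handling.

## Problem sizes and verification

The interface simulations run on 64×64×256 grids at 0.10 mm (tube ID
4.2 mm, glass segment 8 mm, interface on a voxel edge, bulk reference
slice at h = 13 mm); the microcell on 48×48×384 at 0.10 mm. At these
sizes the simulated interface reading (upfield edge of the 0.3 mm
interface layer minus the bulk slice) lands 1.2% from the closed form,
the cavity's interior offset matches (1/3 − N_c)Δχ with a relative
spread of 0.2% (channel off), and enabling the access channel strictly
increases that spread. The full suite and the acceptance script each
run in well under a minute.

## Known limitations

The field inside the solid near an interface is not asserted (lattice
deviations within ~1.5 voxels of boundaries); shim coils are emulated
only as reference-field subtraction (no residual-gradient model);
radiation damping, relaxation weighting, Bloch-level excitation
sculpting, and 3-D image reconstruction are out of scope; χ is treated
as temperature-independent; resin chemistry (cure, impurity leaching)
is not modeled beyond the printed dimensions.
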