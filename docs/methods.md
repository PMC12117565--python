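# Methods

This note documents the models, conventions, numerical choices and
limitations of `escatter`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Units and coordinate system

Internal lengths are nm and scattering vectors q are nm⁻¹.  Form-factor
coefficient widths `b` are stored in Å² exactly as published; the two
conventions meet in the evaluation argument `(q/40π)²`, since
q[nm⁻¹]/40π = sin θ/λ [Å⁻¹].  Form-factor amplitudes (and hence all
scattering amplitudes of atomic models) are in Å; intensities in Å².
The beam runs along +y; 2D detector axes are x (written q⊥) and z
(written q_z).  Energies are eV; k_B = 8.617333 × 10⁻⁵ eV/K.

## Coefficient tables

Three plain-text tables ship under `escatter/data/` (loaded read-only at
import, format documented in their headers):

- `electron_ff.tsv` — five-Gaussian electron rows for the neutral atoms
  H, He, C, N, O, S (Peng-style parameterization, valid to
  q ≈ 250 nm⁻¹) and for the eight protein atomic groups CH, CH₂, CH₃,
  NH, NH₂, NH₃, OH, SH.  Some group rows contain negative amplitudes and
  one a slightly negative width; they are kept verbatim and evaluate
  finitely over the validity range.
- `electron_ff_derived.tsv` — rows for Na, Mg, P, Cl, K, Ca, Fe, Zn, Au
  generated by fitting five Gaussians to the Mott–Bethe transform of
  the embedded X-ray table (fit over sin θ/λ ∈ [0, 2.5] Å⁻¹, rmse
  < 0.005 Å).  The file header flags them as derived, few-percent
  accuracy.  Ions are not tabulated; lookups for unlisted species raise.
- `xray_ff.tsv` — X-ray rows stored as five Gaussians where the fifth is
  a zero-width Gaussian carrying the Cromer–Mann constant term; f(0)
  matches Z to better than 0.2% on every row (better than 0.02% for H
  and O, which the water conversion depends on).

Consistency of the embedded data is enforced by tests: the electron and
X-ray tables agree through the Mott–Bethe relation to a few percent at
moderate q, and each group row's f(0) matches the sum over its
constituent atoms to < 0.02 Å.

Excluded-volume radii are standard displaced-solvent values (e.g. C
0.1577 nm, H 0.107 nm, O 0.130 nm); group volumes are sums of their
constituents with the radius back-computed from V = (4/3)πr³.  Masses
are standard atomic weights.

## Converters

q = (4π/λ) sin(kλ), k = arcsin(qλ/4π)/λ, s = q/2π.  Wavelengths derive
relativistically from the acceleration voltage (200 kV → 2.508 pm;
200 kV is the documented default).  The zero-potential converter
computes p as the ratio of composition-weighted X-ray to electron
coefficient sums and returns φ0 = ρ_bulk/p.  The printed unit
convention (input e⁻/nm³, output labeled e⁻/nm) is followed as is;
internally φ0 only ever multiplies volumes in nm³ to yield amplitudes
in Å, so usage is dimensionally consistent throughout the package.
Division (rather than multiplication) by p is the interpretation that
reproduces the established water value, and is fixed by a test.

## Solvent models

Mean atomic volume V_m is the mean of tabulated excluded volumes over
the sites actually present: no implicit-hydrogen inference is performed;
hydrogens enter either as explicit H atoms or through group symbols.
The dummy-atom route subtracts
C1(q) φ0 V_j exp(−V_m^{2/3} q²/4π) per site with
C1(q) = c1³ exp(−V_m^{2/3} q² (c1²−1)/4π); c1 defaults to 1 and warns
outside (0.95, 1.05).  The voxel route classifies a regular lattice of
cells (default edge v = 0.2 nm): a voxel is excluded iff its center
lies within the species radius of any atom — no partial-volume
weighting, so the excluded volume converges to the analytic union as
v → 0 (verified against a single-atom sphere).  Solvation-layer voxels
are the non-excluded voxels within the configured thickness of the
excluded set, found by a Euclidean distance transform on the lattice;
the layer term is always voxel-based, also when the excluded solvent
uses dummy atoms.  With `solvent_only` the molecular term is dropped
(the a = 0 switch).

## Geometric models

Uniform spheres and core–shell spheres with per-region zero-potential
contrast, by superposition of the closed-form sphere amplitude
Δφ·4π(sin qR − qR cos qR)/q³ (series-expanded below qR = 10⁻⁴ for
stability); q → 0 gives Δφ·V and the first zero sits at qR ≈ 4.4934.

## Reciprocal grids and the hierarchy

Grids sample a source on spherical shells uniform in |q| (spacing
qmax/n_shells) with an equiangular (θ, φ) layout shared across shells
(n_θ ≈ 1.6 n_shells polar angles, 2(n_θ−1) azimuths), interpolated
trilinearly in (|q|, θ, φ); a dense Cartesian layout exists as a
debugging fallback.  `suggest_parameters` returns
n_shells = 3·ceil(qmax·D_max/π) + 8 — three times the Nyquist density
of a structure of diameter D_max — at which the measured interpolation
error stays below the declared tolerance of 10% of the RMS amplitude
(max over random q; typically far less for planar structures).
Centering a structure before gridding reduces the phase rate and is
recommended; `center_structure` uses mass-weighted centering.

Assembly nodes group placements by orientation (matrices equal within
1e-9 entrywise) so each unique orientation shares one translation phase
sum.  Rotation convention: Tait–Bryan angles are intrinsic rotations
about x, then y, then z, degrees in files, applied as matrices
internally; dol files written by the package carry a header comment
stating the convention.  Interchange with other tools may require
re-mapping since axis orders differ across the field.  Per-node
evaluation policy: `direct` (exact re-evaluation at every rotated q,
the default), `grid`, or `hybrid` (grids atomic leaves above 400
atoms).  For all-atomic trees `flatten` provides the exact oracle;
equality of the direct hierarchy with the flattened structure is exact
to rounding, and of the gridded hierarchy within the declared grid
tolerance times the number of leaf placements.

## Intensity estimands

The solution average uses stratified Monte Carlo: directions come from
a spherical Fibonacci lattice rotated by a seeded random rotation.  The
reported per-q standard error is the i.i.d. estimate, which for a
stratified set is a conservative upper bound on the true quadrature
error — the Debye-oracle tests exploit exactly this property.  A
Gauss–Legendre × uniform-azimuth product rule is available as the
deterministic alternative.  2D patterns sample a flat Ewald plane by
default (q_beam = 0), appropriate for high-energy electrons where the
sphere curvature at q = 70 nm⁻¹ and 200 kV is ~1 nm⁻¹; the curved
mapping is available by passing a wavelength.  Pixel coordinates are
pixel centers on the uniform [−qmax, qmax] grid; odd point counts put a
pixel exactly at q = 0.  Fiber patterns average deterministically over
360 (configurable) uniform azimuths about the fiber axis.  Resolution
smearing convolves with a Gaussian truncated at ±4σ and renormalized;
polydispersity averages intensities at 15 equally spaced parameter
values spanning mean ± 3σ with normalized Gaussian weights (the ±3σ
span is this package's choice), dropping nonphysical samples with a
warning.  Azimuthal integration bins pixels by q = √(q⊥² + q_z²) into
half-open shells of width qmax/N_p and reports per-shell means; empty
shells are NaN-flagged, never zero-filled.

## Synthetic fixtures

The generators are deterministic given their parameters and define the
conditions under which the package is tested:

- `make_graphene` — honeycomb lattice in the xz-plane, C–C bond
  0.142 nm (a parameter; the standard value), two atoms per cell,
  stacked layers with per-layer spacing and twist about the beam axis.
  The bilayer/quadlayer constructions used in tests take spacing
  0.348 nm and twists of 5° (within a bilayer) and 30° (between
  bilayers).
- `make_helix` — continuous n-start helical lattice: subunit k of
  protofilament p at azimuth ±2πp/P and height k·pitch +
  p·(n_start·pitch/P).  Each protofilament is a vertical stack with
  axial period equal to the pitch; the lattice climbs n_start·pitch per
  turn, so subunits lie on n_start interleaved strands and fiber
  patterns show layer lines at multiples of 2π/pitch.  Real microtubule
  lattices are discontinuous at a seam; this generator deliberately
  omits the seam (the seam rule is not part of this package's scope),
  so tests against it validate the lattice convention, not seam
  physics.  The standard fixture (pitch 12.214 nm, radius 11.9 nm,
  3-start, 14 protofilaments × 16 subunits) mimics a microtubule-like
  geometry with 224 placements.
- `make_toy` — seeded pseudo-random clusters (minimum separation
  0.1 nm) for oracle tests.

These fixtures exercise every code path but are idealized: no thermal
disorder, no substrate, no partial occupancy, single-element or
few-element compositions.  Passing tests demonstrate correctness of the
scattering mathematics on such models, not agreement with any measured
pattern.

## Monte-Carlo ensembles

Single-atom Metropolis moves with uniform cube displacements;
acceptance min(1, e^{−ΔE/k_BT}).  During equilibration the maximum step
adapts by ×1.1 / ÷1.1 every 50 moves toward ~40% acceptance, then
freezes (so production sampling obeys detailed balance).  Per-move
energy differences touch only the moved atom's pairs; the running total
is refreshed from scratch at every retained sample to stop drift.
Configurations are retained at a fixed interval after equilibration; a
diagnostic error fires if 5000 consecutive moves are rejected.  No
periodic boundary and no cutoff (cluster-scale systems).  The two-atom
thermal bond length is validated against 1D numerical Boltzmann
integration; ensemble intensities are unweighted means over retained
configurations, each configuration's amplitude optionally augmented by
a static (rigid-ligand) amplitude before squaring.

## Known limitations

- Single elastic scattering only; no multiple-scattering, inelastic or
  absorptive effects — thick samples are out of scope.
- The electron table covers the listed species only; derived rows
  inherit X-ray-table accuracy through Mott–Bethe; no ions.
- Voxel classification is center-in/center-out (no partial volumes);
  accuracy is controlled by the voxel size.
- The flat-Ewald default ignores sphere curvature (small but nonzero at
  wide angles and lower voltages); enable the curved mapping where it
  matters.
- Solvent models attach to atomic leaves; solvating an assembly means
  solvating its leaves (or flattening first).
- No fitting to measured data, no absolute-intensity calibration, no
  detector corrections (solid angle, polarization).
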