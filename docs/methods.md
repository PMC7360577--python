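# Methods

`ctdose` estimates energy-resolved photon fluence and effective dose in
voxelized CT phantoms by solving the steady-state linear Boltzmann transport
equation with the discrete-ordinates (S_N) method, and cross-checks every
deterministic result against an in-package analog Monte Carlo transport code
that shares the same multigroup data.

## Transport model

The steady photon field in a non-multiplying medium satisfies

    [Ω·∇ + σ_t(r, E)] ψ(r, E, Ω) = ∫∫ σ_s(r, E'→E, Ω·Ω') ψ(r, E', Ω') dΩ' dE' + S(r, E, Ω)

with ψ the angular fluence, σ_t the total macroscopic cross section, σ_s the
differential scattering cross section and S the external source.  The solver
discretizes:

- **Energy** into G groups (default G = 7 with boundaries 10, 20, 30, 45,
  60, 70, 75, 100 keV, descending index order: group 0 is 75–100 keV).
  Photons in this range only lose energy (photoelectric absorption and
  incoherent scattering), so the group-to-group transfer matrices are
  downscatter-only: lower-triangular in the (from, to) convention with the
  within-group diagonal included.  Scatter that would land below 10 keV is
  removed (counted as absorption); this is the multigroup analog of an
  energy cutoff.
- **Angle** onto a level-symmetric S_N quadrature of N(N+2) unit directions
  closed under sign flips of each axis.  Weights are normalized to Σw = 1,
  so the scalar fluence is the bare weighted sum φ = Σ_n w_n ψ_n and the
  multigroup scattering source needs no 4π factors.  Level cosines for
  N = 2–16 use the classic equal-spacing-in-μ² layout; point weights for
  N ≤ 8 are the classic tabulated class weights, and for N ≥ 10 they are the
  minimum deviation from equal point weights that satisfies as many leading
  even-moment conditions (Σ w μ^{2m} = 1/(2m+1)) as positivity allows.  The
  μ⁰ and μ² conditions hold exactly for any class weights that sum to one
  per octant — a property of the level structure — so particle balance and
  the scalar-fluence sum are unaffected by the fallback depth.
- **Space** onto a regular voxel grid with diamond-difference closure
  (outgoing face fluence = 2·cell − incoming per axis) and vacuum boundaries.
  Sweeps visit the 8 octants with lexicographic downwind ordering.  Negative
  outgoing fluences are repaired by the standard set-to-zero fixup with a
  local cell rebalance, which keeps the scheme strictly conservative (the
  sweep closes particle balance to machine precision on fixtures).

## Uncollided/collided split and the first-collision source

The fluence is split as φ = φ_u + φ_c.  The uncollided part has a closed
form — inverse-square geometry times Beer–Lambert attenuation along the
sight line — and is evaluated analytically at voxel centers with a
Siddon-style voxel ray tracer (exact chord lengths, half-open 0-based voxel
boxes, membership by center point).  Its first scattering,

    q_l(g, v) = Σ_{g'} σ_{s,l}^{g'→g}(v) · φ_u^{g'}(v),

is the first-collision source that drives the collided solve; representing
the (smooth) collided field on the quadrature instead of the (beam-like)
total field suppresses ray effects.  With L = 1 the vector moment is
accumulated source-by-source along each source's own per-voxel sight-line
direction, which preserves anisotropy when several beams overlap.  Sources
must lie strictly outside the voxel-center set (1/d² singularity guard).

The collided equation is solved group-by-group in descending energy order
(exact for downscatter-only physics — verified against a full Gauss–Seidel
iteration over groups); within each group the scattering source is lagged
and iterated (source iteration, no acceleration) to a relative L∞ change
below 1e-6, at most 200 iterations, both configurable.  The spectral radius
is the within-group scattering ratio, which stays below ~0.7 for the
embedded materials, so unaccelerated iteration converges in tens of sweeps.
Non-convergence is flagged in the diagnostics, not raised.

At P_0 the scattering source at direction n is σ_s0·φ; at P_1 it is
σ_s0·φ + 3 σ_s1 (Ω_n·J) with J the quadrature current.  The quadrature
weight sits on the integrated (primed) direction — the convention that
conserves particles, enforced by the balance tests.

## Multigroup data

The embedded water physics is a pointwise (energy → photoelectric,
incoherent) mass-attenuation table on 10–100 keV with coherent (Rayleigh)
scattering excluded.  The photoelectric column follows an E^-3.15 power law
anchored at 20 keV and the incoherent column has the Klein–Nishina shape;
the anchors put the water mean free path at 13.9 mm at 20 keV rising to
≈60 mm at 100 keV, the attenuation behavior the multigroup transport in this
package targets.  Group constants are evaluated at group midpoints; voxel
values scale linearly with mass density relative to the material's reference
density (the CT-number workflow).

Group transfer matrices are built from Compton kinematics: the
Klein–Nishina angular density at the group-midpoint energy is integrated on
a fine cosine grid, each deflection's outgoing energy E' = E/(1 + k(1−μ))
is binned into groups, and the magnitude is normalized to the incoherent
column.  This yields σ_s0 and σ_s1 per group pair (Legendre order capped at
L = 1 by default; the data model permits higher orders).

The built-in library holds five dosimetrically equivalent media — air
(ρ = 0.0012 g/cm³, never true void), lung (0.30), soft tissue (1.00), water
(1.00), and a bone surrogate (1.50, photoelectric column ×4.5 for the higher
effective Z, incoherent ×0.98 for electrons per gram).  CT numbers map to
(material, density) through a four-interval threshold table (air / lung /
soft tissue / bone at −900, −100, +150 HU) with piecewise-linear density
ramps; 0 HU gives soft tissue at exactly 1.0 g/cm³.  This simplified map
stands in for a full stoichiometric calibration, which needs scanner-specific
data and is out of scope.

## Sources and spectra

Point sources are isotropic; cone beams emit uniformly over solid angle
within the polar half-angle of the axis; fan beams bound the azimuthal
(in-axial-plane) and polar angles separately.  Aperture boundaries are
inclusive.  A "30° cone" is a full apex angle (half-angle 15°); the config
takes the full angle, the internal representation the half-angle.  An axial
scan places n equally spaced cone beams on a ring in the central axial
plane, each aimed at the isocenter with an equal share of one source
particle.  The ring radius defaults to 50 cm; the distance is a config
default, not a physical constant.  The default spectrum is a Kramers
(bremsstrahlung) shape with 100 keV peak, integrated per group.

All fluences are per source particle of the *isotropic focal spot*: a
collimated source's histories and ray-traced contributions both carry the
1/(4π d²) normalization, so deterministic and Monte Carlo results are
directly comparable and independent of aperture size.

## Monte Carlo oracle

The analog multigroup Monte Carlo shares the phantom, cross sections,
sources and dose coefficients with the deterministic solver, so
discrepancies isolate the angular and spatial discretization rather than the
data — deliberately removing the cross-section variable from the comparison.
Per history: sample source, group, and aperture direction; free paths are
sampled from the local voxel's σ_t with memoryless resampling at voxel
boundaries; at a collision the photon survives with probability
σ_s,out/σ_t, the outgoing group is sampled from the transfer row, and the
deflection cosine from the P_1-truncated density (1 + aμ)/2 with
a = 3σ_s1/σ_s0 clipped to [−1, 1] (clipped pairs are counted and reported;
clipping affects mainly the forward-peaked top groups).  Track lengths
accumulate into F4-style volume-averaged fluence tallies per (group, voxel),
split by collision count into uncollided (0) and collided (≥1), plus a
direct effective-dose tally.  Batch statistics give per-voxel relative
standard errors; histories run in equal batches with per-batch seeded
streams derived from the user seed, making results bit-identical for a fixed
(seed, histories, batches) triple.  No variance reduction is applied.

Note the MC keeps its P_1 deflection sampling even when the deterministic
run is P_0 — mirroring the usual benchmark situation where the reference
carries fuller angular physics than the deterministic truncation.

## Dosimetry and comparison statistics

Effective dose per voxel is Σ_g k_g φ_g with k_g the fluence-to-effective-
dose coefficient (pSv·cm²) interpolated linearly at group midpoints from an
embedded ICRP-116-style anterior-posterior reference table (10–100 keV);
users may supply their own two-column table.  Dose in air is zeroed: air
kerma is irrelevant to patient dose and the zeroing also removes residual
ray-effect streaks in the air region outside the body.

Two runs are compared by the relative-difference volume
100·(test − ref)/ref and by percent RMSD — the RMS of voxelwise relative
differences over the central axial slice within a 35 cm circular field of
view, excluding voxels where the reference is zero or its relative standard
error exceeds 5% (the same discarding applied to high-uncertainty reference
tallies in practice; low-energy groups can lose all their reference voxels
and are reported as undefined).  Normalization is by the reference, so the
statistic is deliberately asymmetric.

## Verification conditions and problem sizes

The shipped scenarios run at desk scale on one CPU:

- `vacuum-point-source`, `absorber-slab`, `infinite-medium-c05` — analytic
  limits: inverse-square to 1e-9 relative, Beer–Lambert to 1e-9, and the
  one-group infinite-medium interior fluence S/σ_a within 3% at c = 0.5.
- `water-projection-coarse` — 35 cm water cylinder, 64×64×16 grid
  (7.81 mm voxels), one 30° cone beam at 50 cm, S6P0.  The projection uses
  a cone rather than a bare isotropic point source so that analog histories
  are spent inside the phantom.
- `water-ctscan-coarse` / `abdomen-ctscan-coarse` — 16 cone beams on the
  ring, S6P0.

Cross-method agreement is checked two ways.  (1) A fixed-seed 1e6-history MC
run: the S6P0 collided fluence must agree within 3 MC standard errors in at
least 95% of in-phantom voxels.  (2) The central-slice total-dose RMSD
against a 1.6e7-history reference must be below 6%.  The reference is larger
than the fixed-seed run because at 1e6 histories the per-voxel noise floor
of the RMSD statistic on this mesh is itself above 6% (two independent
1e6-history runs differ by ≈9% RMSD under the same uncertainty filter); a
meaningful RMSD needs a converged reference, and 1.6e7 histories run in
about a minute.

Measured behavior at these conditions: balance closure ~1e-6, within-3-SE
fractions ≈95%, scan total-dose RMSD ≈3.9%.  The residual is dominated by
the P_0 angular truncation: the collided field is ≈7% low at the cylinder
center for a single projection (underestimation at the center,
overestimation at the periphery), and switching the solver to P_1 moves the
center collided ratio from 0.93 to 1.03.  This is the expected signature of
isotropic-kernel transport against an anisotropic reference.

## What the synthetic data does and does not show

The phantoms, spectra and materials are synthetic.  The water cylinder is
an exact geometric fixture; the abdomen-like phantom is a seeded generator
(elliptical soft-tissue body, posterior bone ellipse, 1–3 air pockets) that
emulates the material mix of an abdominal slice but is not derived from any
CT data set.  The embedded attenuation table and the bone surrogate are
physically shaped but not an evaluated nuclear data library; coherent
scattering, bound-electron effects and electron transport are absent by
construction.  Passing tests therefore demonstrate the correctness of the
transport numerics (discretization, sweeps, ray tracing, tallies,
conservation) and the internal consistency of the deterministic and Monte
Carlo routes on shared data — not the absolute dosimetric accuracy of any
clinical scan, which would require evaluated cross sections, a measured
spectrum, and a calibrated CT-number conversion.

## Numerical choices and degenerate inputs

- Convergence: relative L∞ change of the group scalar fluence < 1e-6,
  ≤200 iterations (configurable); residual histories are recorded per group.
- Fixup: set-to-zero with local rebalance, at most one face fixed per pass
  and a final consistent center solve; disabled via config for scheme
  studies (negative fluences then propagate to the output validation).
- Zero cross section (vacuum/air limit): mean free path reports infinity
  rather than raising; MC treats σ ≤ 1e-12 voxels as collision-free.
- Boundary energies: groups are half-open (lower, upper], so 20 keV belongs
  to the 10–20 keV group and exactly-10-keV scatter counts as removal.
- Ray boundaries: aperture membership is inclusive at the cone edge, and the
  ray tracer advances by 1e-9 of the in-grid parameter to pick the entered
  voxel robustly; chord sums match the in-grid segment length to 1e-9.
- The MC voxel locator uses floor (not integer truncation), so positions
  marginally below the low boundary terminate instead of looping.

## Known limitations

- P_0/P_1 only by default; no acceleration (DSA/CMFD), no reflective
  boundaries, no time dependence, no electron transport, no GPU path.
- Group constants at midpoint energies; no flux-weighted condensation.
- The MCNP-style deck exporter produces shape-compatible text (lattice
  geometry, material census, source card, per-cell energy-binned fluence
  tallies) for manual cross-checking; it has not been validated inside an
  actual MC production code, and its material cards are water-equivalent
  placeholders.
- The 1e6-history fixed-seed benchmark is reproducible but noisy per voxel;
  per-group RMSD tables at that scale mostly reflect tally noise in the
  low-weight groups (reported as undefined where no reference voxel passes
  the 5% uncertainty cut).
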