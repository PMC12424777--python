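# Methods

## Scope and assumptions

`boldsim` simulates the transverse-signal decay caused by vessel-induced
B0 inhomogeneity.  Longitudinal relaxation, intrinsic T1/T2, vessel
permeability, flow and oxygen transport are outside the model: every spin
(or grid cell) carries unit magnitude and only its phase evolves.  A single
susceptibility offset Δχ is shared by all vessels, i.e. a uniform
oxygenation level.  The simulated voxel is surrounded by copies of itself:
diffusing spins wrap cyclically at its faces, and Fourier field solutions
use cyclic convolution.

Units are µm, ms, and tesla throughout; γ = 2.675×10⁸ rad s⁻¹ T⁻¹.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `b0` | 3 T | main field; offsets scale linearly |
| `delta_chi` | 4.15×10⁻⁷ | blood–tissue volume susceptibility (≈65% SO₂, 35% hct) |
| `diffusion_coefficient` | 1 µm²/ms | water self-diffusion, same in EV and IV |
| `timestep` | 0.2 ms | random-walk / convolution step; echo times must be multiples |
| `te_gradient_echo`, `te_spin_echo` | 30, 70 ms | readout times; the SE pulse is an ideal 180° at TE/2 |
| `total_time` | 120 ms | 600 recorded samples at t = j·δt |
| `n_spins` | 40 000 | Monte Carlo walkers per voxel; S.E. of a signal sample ≈ N⁻¹ᐟ² |
| `blood_volume_fraction` | 0.02 | in-voxel vessel volume target |
| `radii` | 1–60 µm (15 values) | vessel radius sweep; geometry is rescaled, not regrown |
| `n_voxels` | 10 | independent network realizations averaged in analyses |
| `edge_length_3d`, `edge_length_2d` | 149, 251 µm | base-voxel sizes giving ≈400 vessels at 2% |

One base network is generated per voxel id at the 1-µm radius; other radii
reuse it with every length multiplied by R/R₀, so the vessel arrangement —
and the volume fraction — are identical across the sweep.  All randomness
derives from one master seed through named `SeedSequence` streams keyed by
(domain, voxel) for geometry and (approach, radius, voxel) for spin walks:
approaches that share geometry see identical vessels but independent
walks, and any run is bit-for-bit reproducible.

## Geometry

**3D cylinders.** Orientations are isotropic (θ = acos(2u−1), φ uniform).
For each cylinder an anchor point is drawn uniformly on the square of
half-width L√3/2 on the plane orthogonal to the axis through the voxel
centre — the bound that covers every line meeting the cube, giving uniform
line density over the voxel.  All candidates are kept: cylinders whose axes
miss the cube still contribute extravascular field near the faces, playing
the role of surrounding vasculature (for this reason the 3D continuous
field is *not* additionally image-wrapped).  In-voxel volume is accounted
as πR² times the exact chord of the axis through the cube (end-cap
clipping ignored, error O(R/L)), and cylinders are added until the 2%
target is reached — about 400 per voxel at the defaults, with the
hit-count Monte Carlo oracle agreeing with the chord accounting to a few
percent.  Overlap between cylinders is permitted; at 2% its probability is
negligible.

**2D cylinders.** Circles with centres uniform over the square; the count
is exactly ⌈ζL²/(πR²)⌉ (402 at the defaults).  The square is treated as
periodic in-plane for both compartment labels and continuous fields
(minimum-image convention, nearest image only — the dipole field decays as
r⁻², so further image shells are negligible).  In the per-vessel-B0 mode
each circle carries its own isotropically drawn B0 direction; in the 3B0
mode the field is the weighted sum of ⅓ the vessel-parallel and ⅔ a single
vessel-perpendicular orientation (reference direction: +x), which makes
every vessel's interior offset exactly zero — the dipole is trace-free.

**Single vessel (1V).** One centred vessel in a voxel sized so that it
realises the nominal blood volume fraction (L = R·√(π/ζ) ≈ 12.5 R at 2%),
the classic single-vessel construction; its field is that of the isolated
vessel (no periodic images), so the intravascular space is exactly
homogeneous and the IV spin echo refocuses fully at every B0 angle.  Runs
at nine polar angles (10°–90°) are combined with sin θ weights
(Σ sin θ = 6.21503).

**Simplified VAN.** A stand-in for anatomical network synthesis: chains of
fixed-radius (2.85 µm) finite segments grown by a correlated random walk
(persistence parameter controls tortuosity), with occasional chains seeded
from existing nodes (junctions) and candidate segments rejected if they
approach an existing vessel within one diameter.  Segment length is set so
the configured density (26,100 segments/mm³ — the unit that yields ~30-µm
capillary segments) and the 2% volume target are met together.  Each voxel
gets its own seeded bed; achieved volume fraction is reported and the
simulated signals are volume-scaled (|S| → |S|^(ζ_nominal/ζ_actual)) to
the nominal fraction.  The stand-in preserves what the simulation
consumes — finite tortuous segments, junctions, a single radius — but not
branching-order statistics, pial/diving vessels or flow.

## Field solvers

Analytic fields sum the infinite-cylinder dipole expression over all
vessels, either continuously at arbitrary points or sampled at
cell-centred grid points (500/side in 3D ≈ 6.7 points per vessel diameter;
≥1000/side in 2D ≈ 8).  The Fourier solver multiplies the FFT of the
voxelized susceptibility map by the k-space dipole kernel
(1/3 − k_z²/|k|²)·B0 on the unpadded grid; the k = 0 element is set to
zero (zero-mean convention — a uniform susceptibility produces no offset,
and a voxelized sphere's interior mean vanishes).  Masks are cell-centred:
a grid element is intravascular iff its centre lies within a vessel.
Gridded fields are looked up by Monte Carlo spins with nearest-neighbour
(not interpolated) indexing.

## Diffusion engines

**Monte Carlo.** Per step and axis, displacements ~ N(0, 2Dδt); positions
wrap; a displacement that would change a spin's compartment is redrawn as a
whole, up to 100 times, after which the spin keeps its position for that
step (a counted diagnostic; at the default parameters freezes are rare).
Phase accrues from the field at the accepted position; the field is static,
so a frozen spin re-uses its previous offset.

**Deterministic diffusion (2D).** The kernel D_k = e^{−a} I_k(a) with
a = σ²/Δx² spans ±6σ and must contain ≥13 elements, otherwise a
resolution error directs the caller to refine the grid; after truncation
it is renormalized to unit sum so diffusion conserves magnetization
exactly.  Convolution is separable (two 1D passes — exact for isotropic
independent diffusion and far cheaper than a 2D kernel) with wrapped
padding.  Impermeability: with w = kernel∗(IV indicator), the fraction
(1−w) of an IV cell's magnetization that lands extravascularly is returned
to that source cell (and symmetrically for EV cells), which conserves each
compartment's sum to machine precision.  This cell-local restitution is an
approximate reconstruction of the published correction-factor scheme; its
testable contract is exact compartment conservation, and the engine as a
whole matches the Monte Carlo engine on matched problems within 3 Monte
Carlo standard errors.  Grid sizing follows the configured rule (15,860
per side at R = 60 µm, scaled ∝R, rounded up to a multiple of ten, floor
1000); note that at the default σ = 0.632 µm this inherited constant does
not itself satisfy the 13-element kernel rule at the largest radii — the
kernel check, not the sizing rule, is authoritative, and a configurable
cell-count ceiling guards memory.

## Analyses

NRMSD = 100·√(mean_t |S−S_ref|²)/σ_ref with σ_ref the temporal standard
deviation of the (complex) reference; the metric is invariant to a global
phase.  Rates are single-echo log magnitudes, ΔR2(′) = −ln|S(TE)|/TE.
Boxerman tables report, per radius and compartment, the rate of the
voxel-mean complex signal plus mean ± SD of per-voxel rates (no SD for the
single-voxel 1V approach).  Fingerprinting dictionaries hold the
voxel-mean total-signal magnitude normalized by its temporal average, one
entry per radius; a test signal (normalized identically) is assigned the
radius maximizing R² = 1 − SS_res/SS_tot, with the test as data and the
entry as model; ties go to the smaller radius with a logged warning.
Field-offset histograms are unit-area densities in ppb of B0 (1-ppb bins
over ±300 ppb by default, matching the scale of the offsets at 3 T), per
compartment, averaged across voxels with an SD band.

## Desk-scale operating points

The default configuration (40,000 spins × 10 voxels × 15 radii × several
approaches) is an overnight run.  The shipped presets scale it down while
preserving the qualitative orderings: `unit` (one vessel, 100 spins,
50 steps), `matched-2d` (one small 2D voxel run by both diffusion
engines), `mini-fingerprint` (5,000 spins, 2 voxels, all 15 radii), and
the test suite uses 2,500 spins where full sweeps are exercised.  The
benchmark script uses ten voxels with a 200³ grid for the field histogram
and the 5,000-spin/2-voxel sweep for fingerprinting.  At these sizes Monte
Carlo noise per signal sample is ~1.4×10⁻², enough to separate adjacent
dictionary radii; what desk scale does *not* reproduce is the full-scale
precision of NRMSD curves between closely agreeing approaches.

## Known limitations

- The synthetic geometries emulate capillary-like beds; real cortical
  vasculature has radius heterogeneity, structured orientations (pial and
  diving vessels) and oxygenation gradients that these generators do not
  model, so passing tests show engine correctness, not anatomical realism.
- The single-vessel (1V) approach as implemented is the idealized
  construction (isolated field, exact 2% cell); published variants differ
  in unstated voxel-sizing details, and its biases here are smaller than
  some reported implementations.
- Deterministic diffusion is 2D only, and only fully impermeable or fully
  permeable walls exist in that engine.
- The Fourier solver is less accurate at vessel walls (susceptibility
  discontinuities); errors concentrate in the intravascular space, which
  occupies few grid cells.
- Out-of-scope physics: intrinsic relaxation, exchange, distinct IV/EV
  diffusion coefficients, flow, arbitrary pulse sequences beyond one GE
  readout and one SE.
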