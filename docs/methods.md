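# Methods

## The model

`dsbsim` implements a one-bead-per-residue, implicit-solvent model of
multichain protein systems in the dynamic structure-based (DSB) family:
attractive contacts are not fixed by a native structure but form and break
during the run according to geometric criteria, which makes the model
suitable for intrinsically disordered, gluten-like proteins.

Internal units: length in Å, energy in the contact depth ε, time in
τ ≈ 1 ns, mass in units of the average residue mass m (a parameter; the
conventional value is ~120 Da, but only ratios enter the dynamics). Room
temperature corresponds to k_BT between 0.3 ε and 0.38 ε; the default is
the midpoint, k_BT = 0.35 ε. One τ is exactly 200 integrator steps
(dt = τ/200).

Equation of motion (per bead): m r̈ = F − γ ṙ + Γ with γ = 2m/τ
(overdamped regime) and white noise of variance σ² = 2γk_BT — the noise is
the only thermostat. The integrator is BAOAB: the
friction/noise sub-step is applied exactly (v → e^{−γdt/m} v + ξ), so a
free particle reproduces both the Maxwell–Boltzmann distribution and the
velocity decay rate γ/m without time-step error; with γ = 0 and no noise
the scheme reduces to velocity Verlet (used by the energy-conservation
regression test).

### Potential terms

* **Bonds**: V = k (r − r_b)² with k = 50 ε Å⁻², r_b = 3.8 Å. The spring
  constant is quoted directly in ε Å⁻², i.e. there is **no ½ prefactor**;
  a 1 Å stretch costs 50 ε.
* **Chain stiffness**: tabulated bond-angle and dihedral potentials
  (cubic-spline interpolated; the dihedral table is periodic). Any
  two-column table can be loaded. The shipped default is a synthetic
  stand-in — a gentle harmonic angle bias around 105° (4 ε/rad²) and a
  weak cosine-series dihedral (amplitudes 0.3 ε and 0.2 ε) — chosen to
  keep chains flexible and disordered, since the random-coil tables of
  the original parameterization are not distributed with this package.
* **Excluded volume**: V_r = ε[(r₀/r)¹² − 2(r₀/r)⁶ + 1] for r ≤ r₀ = 5 Å
  and exactly 0 beyond; V_r and its derivative vanish at the cutoff.
  Next-nearest neighbors along a chain (j = i+2) interact through V_r
  only.
* **Contacts**: full 6–12 wells, depth ε (4ε for disulfides and the
  adhesive walls), minimum at 5 Å (backbone–backbone), 6.8 Å
  (backbone–side chain), or a pairwise matrix (side chain–side chain).
  The ss matrix is a stand-in: the sum of per-residue effective radii
  ordered by side-chain volume (2.25 Å for Gly up to 3.6 Å for Trp),
  configurable. While a contact's activation is λ < 1 the pair potential
  is the cross-fade (1−λ)V_r + λV_LJ, so energy is continuous through
  contact birth and death.
* **Electrostatics**: Debye–Hückel with a distance-dependent relative
  permittivity ε_r(r) = κ·r, κ = 4 Å⁻¹, giving an effective 1/r² Coulomb
  times exp(−r/λ_D). The Debye length (default 10 Å) and the Coulomb
  prefactor (default 195 ε·Å, from e²/4πε₀ with ε ≈ 1.7 kcal/mol) are not
  part of the printed parameter set and are configurable. Charges: D/E
  −1, K/R +1, H neutral. The term is truncated-and-shifted at
  min(2λ_D, 20 Å). Gluten-like systems are essentially uncharged, so
  these defaults are rarely exercised.
* **Walls** (slab geometry, Z): repulsive (ε/9)(σ/z)⁹ with σ = 0.5 nm.
  The printed wall formula has an attractive sign and a singularity at
  contact; solid walls require repulsion, so the repulsive form is the
  default. When adhesion is switched on, a per-residue wall contact
  cross-fades the repulsion into a full 6–12 well of depth 4ε (minimum at
  5 Å), using the same quasi-adiabatic λ machinery as pair contacts.

### Directional dynamic contacts

Local frames from beads (i−1, i, i+1): the in-plane bisector at i defines
n̂ (−n̂ ≈ side-chain direction) and the cross product of adjacent bond
vectors defines b̂ (≈ backbone hydrogen-bond direction). Termini and
collinear triples have no frame and sit out of directional contacts for
that step. A backbone slot requires |b̂·r̂| ≥ 0.5; a side-chain slot
requires (−n̂)·r̂ ≥ 0.5 toward the partner. These cosine cutoffs and the
capture range (distance < 1.1·r₀) are implementation choices — the source
parameterization does not print them — and are configurable.

Contacts switch on over 10 τ (λ: 0→1, linear) and switch off the same way
once r > (3/2)·r₀/2^{1/6} ≈ 1.336 r₀ (6.68 Å for bb). Coordination
limits: every backbone offers 2 slots; side-chain capacity is a per-type
stand-in table (1 for Gly, 2 for most, 3 for large side chains).
Candidates are accepted greedily by (distance, i, j) under the limits —
deterministic and physically sensible. Cys–Cys pairs use the side-chain
mechanism with depth 4ε and at most one disulfide per cysteine. Go-mapped
pairs (read from a contact-map file) are permanently attractive and
bypass geometry and slot accounting.

The optional solvation rule counts neighbors within 0.75 nm and shifts a
residue's coordination capacity by ±1 (sign configurable) when the count
exceeds a threshold n_t; it is disabled by default, consistent with the
finding that it does not change results.

### Numerical choices

* Soft-core linearization: the r⁻¹² pair cores continue linearly (C¹)
  below 2.5 Å and the z⁻⁹/z⁻¹² wall cores below 2 Å. The energies there
  (thousands of ε) are thermally unreachable, so equilibrium properties
  are unaffected; the linearization only prevents numerically unbounded
  forces when a pathological overlap occurs (e.g. a bead overtaken by a
  moving wall during squeezing).
* Neighbor search: a displacement-buffered Verlet pair list built by an
  exhaustive O(N²) numba kernel (rebuilt when any bead moves half the
  2 Å skin). At desk scale (N ≲ 2000) this is faster than cell-list
  bookkeeping and trivially identical to the all-pairs reference.
* Minimum image: the force kernels use fractional rounding (exact while
  cutoffs are below half the cell extents and the shear tilt is
  moderate); the public `minimum_image` performs an exact adaptive image
  search valid for any tilt.
* Contact updates run every `check_every` integrator steps (default 10;
  20 in the desk-scale schedule = 0.1 τ, far below the 10 τ switching
  time). λ values are computed from phase timestamps, so ramps complete
  in exactly 10 τ regardless of the stride.
* Determinism: one master seed; the SAW generator, thermostat noise
  (numpy PCG64, pre-drawn per block) and all fixture generators derive
  from it. Identical seeds give bitwise-identical trajectories.

## Simulation protocol

1. **SAW start** in a dilute cubic cell (ρ_start = 0.05 nm⁻³ < 0.1):
   chains grown as self-avoiding random walks (bond 3.8 Å, hard core
   3.8 Å) and placed so no inter-chain pair is within 7.6 Å — beyond any
   contact-capture range.
2. **Equilibration** (200,000 τ at full scale; every span scales by one
   factor).
3. **Squeeze**: every box dimension shrinks at 0.02 Å/τ with dynamics
   running and coordinates remapped affinely, stopping exactly at the
   target density (to ≪0.1%). "Every direction" includes the wall
   separation.
4. **Equilibration**, then **wall adhesion** switches on (4ε wells,
   quasi-adiabatic), then a third equilibration.
5. **Oscillatory deformation**: cycles of period 40,000 τ alternating
   normal strain (X stretched by 1 + A sin, Z compressed by the inverse;
   volume conserved) and shear (Y cell vector tilted by A·aₓ·sin). The
   amplitude is not printed; default A = 0.1. Each cycle returns the cell
   exactly to its original shape.

## Diagnostics

* **Cavities**: a grid of probe balls (radius 1.9 Å — half the
  coarse-grained length unit; a water-sized probe would be meaningless
  between 3.8 Å beads — spacing 1 Å, one grid orientation by default).
  Balls within (1.9 + 3.8) Å of a bead are occupied; the 3.8 Å occlusion
  radius is the coarse-grained length unit (configurable). Empty balls
  reachable from the box faces are outside (6-neighbor flood fill); the
  rest are cavities, clustered into components; volume = ball count ×
  grid-cell volume. Extra grid orientations (rotations about Z) keep a
  ball only if it is interior in every orientation (intersection rule).
  A slab variant treats X/Y periodically and seeds the exterior at the
  wall-adjacent layers; the sweep uses it because the simulation cell is
  genuinely a slab.
* **Entanglements**: primitive-path analysis. Termini stay pinned; each
  chain shortens by vertex removal and midpoint straightening, with any
  move vetoed if its swept triangle is crossed by another chain's segment
  (Möller–Trumbore tests, minimum-image segment placement in X/Y).
  Convergence: relative length decrease < 10⁻⁶ per sweep; contour length
  is non-increasing by construction. A pair of chains is entangled when a
  residual kink of one path is blocked by the other chain; the blocking
  chain is identified by the first intersecting segment.
* **Observables**: single-frame axis profiles (time-averaging washes the
  cavities out, so late single frames are the informative ones; default
  bin 2 Å); g(r) with minimum-image distances and an exact slab
  correction to the ideal-gas shell normalization (factor 1 − r/2L_z);
  per-chain R_ee, R_g and the relative shape anisotropy
  W = [(λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²] / [2(λ₁+λ₂+λ₃)²] ∈ [0, 1]
  from the gyration-tensor eigenvalues (one common convention for an
  "asphericity parameter"; 0 = isotropic, 1 = rod).
* **Regimes**: ρ = 0 infinitely dilute; ρ < 1 nm⁻³ dilute; 1–3 nm⁻³
  intermediate (connected network, large cavities); ρ > 3 nm⁻³ dense
  (homogeneous, many small cavities). Thresholds are configurable —
  they are system-type dependent.

## Synthetic data

The fixture generator supplies every input the tests need:

* `gluten_like_system` — chains with a deterministic per-chain
  composition: 35% Gln, 15% Pro, 15% Gly, 2% Cys, remainder drawn from
  uncharged residues. This mimics the Q/P/G-rich, essentially uncharged,
  disulfide-capable character of gluten proteins; it does not reproduce
  any real gliadin/glutenin sequence, sequence correlations (e.g. PQQP
  repeats), or the real length distribution (real chains are 100–800
  residues; fixtures default to 50).
* geometric objects with analytically known answers: straight rods
  (R_ee, R_g closed forms), hollow bead shells (enclosed sphere volume),
  interlocked open rings (exactly one entangled pair), ideal-gas clouds
  (g(r) = 1), and chains confined to disjoint Z slabs (guaranteed
  unentangled).

Passing tests on these fixtures validate the machinery — forces,
switching bookkeeping, detectors, statistics — under controlled geometry;
they do not demonstrate that the model reproduces any measured property
of real gluten.

## Desk-scale study conditions and their limits

The full-scale protocol (4271 residues, 200,000 τ equilibrations) is a
cluster workload. The desk-scale sweep shipped with the package uses 10
chains × 50 residues (500 beads), equilibration spans of 100 τ, squeezing
at 2 Å/τ, two oscillation cycles of 60 τ, densities
{0, 0.5, 1, 2, 3, 3.5, 4} nm⁻³ and 3 seeds per density — a complete run
of the entire protocol per (ρ, seed) in ~30 s.

What this scale does and does not show:

* Chain compaction with density reproduces cleanly: free chains
  (ρ = 0) have mean R_g ≈ 16 Å versus ≈ 11 Å in the dense regime, with
  the same direction of change as the full-scale result.
* The non-monotonic cavity statistics (a maximum of the biggest-cavity
  volume near ρ ≈ 1 and a minimum of the cavity count near ρ ≈ 2) do
  **not** emerge at 500–1000 beads. They require an intermediate-density
  network that encloses solvent voids much larger than the 5.7 Å probe
  reach. In a ≤10 nm box, (a) voids of that size always connect to a box
  face, and (b) the adhesive walls consume most of the material — a
  monolayer on both walls needs ≈2(L/3.8)² beads, which at ρ = 3.5 is
  ~380 of the 500 available. Measured desk-scale cavity volumes instead
  grow monotonically with ρ (interstitial pockets of an increasingly
  filled box). This is a finite-size limitation of the study conditions,
  not of the detector: on analytic fixtures (hollow shells) the detector
  is exact to the grid resolution.
* Pairwise entanglements are rare at desk scale: 50-mers are at or below
  the entanglement length of flexible bead-spring chains, so sweep counts
  are near zero at all densities and carry no usable trend.

## Known limitations

* The angle/dihedral tables, ss distance matrix, coordination tables,
  directional cosine cutoffs, capture range, Debye length and Coulomb
  prefactor are documented stand-ins, not a fit to data.
* The shear minimum image in the force kernel assumes |tilt| < aₓ/2 and
  cutoffs below half the cell (both enforced by the protocol driver).
* Entanglement crossing tests place each foreign segment at its single
  nearest periodic image; paths comparable in length to the cell could
  in principle interact through two images at once.
* Cavity analysis of sheared (mid-cycle) frames is not supported; frames
  are analyzed after cycles return the cell to rectangular shape.
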