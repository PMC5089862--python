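# Methods

`cytocrowd` simulates coarse-grained models of a crowded bacterial
cytoplasm — polydisperse spheres at cytoplasmic volume fraction — with
Brownian dynamics (BD), and provides the full trajectory-analysis toolbox
used in whole-cytoplasm modelling studies: windowed mean-square
displacements and diffusion fits, rotational correlation analysis,
coordination numbers and group-resolved weak ("quinary") association
statistics, proximal radial distribution functions with voxel-counted
accessible volumes, 3D ligand density maps, and structural observables.

## Units

Lengths in Å, times in ps, temperatures in K, energies in kBT, charges in
elementary charges, diffusion constants in Å²/ps, viscosity input in
mPa·s. All conversions to SI live in `cytocrowd.units`.

## The coarse-grained model

Each macromolecule is a sphere whose radius `a` is its Stokes radius, so
its dilute-limit mobility is Stokes–Einstein, `D0 = kBT/(6πηa)` with the
viscosity of water (0.890 mPa·s at 298 K by default; the viscosity is a
parameter since no single value is canonical). Excluded volume between
spheres is a half-harmonic repulsion

    V(r) = k/2 (r − a_i − a_j − Δ)²   for r < a_i + a_j + Δ,   else 0

with Δ = 1 Å and k = 10 kBT/Δ², i.e. V = 5 kBT when spheres touch
(r = a_i + a_j). The potential is continuous and once differentiable at
its cutoff. Lennard-Jones and LJ+Coulomb forms are provided for
small-particle mixture experiments; there the quoted particle size is a
radius and the LJ minimum (Rmin) sits at `a_i + a_j`, so equal-size 2 Å
particles peak near 4 Å separation. Coulomb interactions use a Bjerrum
length of ~7 Å (ε_r = 80, 298 K) with minimum-image truncation at L/2 —
adequate for the small, weakly charged mixture boxes; no Ewald summation.

## Integration

Two schemes propagate the overdamped dynamics:

* **first-order** (Ermak–McCammon): Δx = (D/kBT)·F·dt + ξ, ξ Gaussian
  with per-axis variance 2·D·dt;
* **predictor–corrector** (Iniesta–de la Torre, the default): a predictor
  step followed by a corrector using the force averaged between the
  predictor endpoints, reusing the same noise realisation. In a harmonic
  well its stationary-variance bias is O((κDdt)²) versus O(κDdt) for the
  first-order scheme; the test suite measures both.

The production timestep follows the rule dt = 0.0005·a²/D(a) for the
smallest sphere; with a_min = 15.8 Å this evaluates to 8 ps, used for all
crowded runs. A step moving any particle more than a quarter box aborts
the run with the offending particle named. Noise comes from a
counter-based Philox stream keyed on the run seed, so trajectories are
bit-reproducible regardless of chunking.

An optional far-field hydrodynamic variant propagates with the
Rotne–Prager–Yamakawa diffusion matrix (unequal radii, symmetric positive
definite for non-overlapping spheres) and Cholesky-correlated noise in a
midpoint scheme. RPY is divergence-free, so no spurious-drift term is
needed. Near-field lubrication corrections are out of scope; the dense
O(N³) cost restricts this path to small systems.

Pair forces are evaluated either all-pairs or with a linked-cell grid
(cell edge ≥ the interaction range, used when ≥ 4 cells fit per box
edge); both paths are exact with respect to the cutoff and are tested to
agree to round-off. With ribosome-sized spheres present the pairwise
range (≈ 250 Å) forces the all-pairs path, which is the production route
for the crowded runs.

## Synthetic systems

All generators are pure functions of their parameters and a seed.

* **Brownian walkers / rigid rotors** supply exact ground truth for the
  estimators: per-axis step variance 2·D·dt; isotropic small-angle
  rotational diffusion whose first-rank axis autocorrelation decays as
  exp(−2·Drot·τ).
* **Packed configurations**: random sequential insertion, largest sphere
  first; at dense packings leftover particles are placed randomly and
  relaxed by capped-force BD followed by a zero-noise capped-force
  descent, because at thermal equilibrium the soft 5 kBT contact always
  leaves a few pairs transiently interpenetrating — a deterministic
  descent is required to reach a strictly overlap-free snapshot. Works to
  φ ≈ 0.5; insertion is refused above φ = 0.55.
* **The `mg_like` composition** emulates one cytoplasm subsection:
  ribosome-sized (125 Å × 3) and GroEL-sized (85 Å × 3) complexes,
  tRNA-sized RNA (24 Å × 30) and 180 proteins spanning 15.8–55 Å, 216
  spheres per subunit. It is a synthetic stand-in: the published
  composition lives in supplementary material that is not machine-readable
  here, so radii were chosen from typical hydrodynamic radii of the real
  components and the smallest radius (15.8 Å) from inverting the 8 ps
  timestep rule. The box follows the convention of 8 subunit copies in a
  (106.2 nm)³ box, scaled as (scale/8)^(1/3), which pins the sphere volume
  fraction at 0.39 for this composition independent of scale.
* **LJ mixtures**: 2 Å 'A' particles plus an equal-nominal-volume partner
  ('B' 2 Å, 'C' 3.509 Å, 'D' 5.570 Å; each component nominally 3400 ų in
  an (18.666 Å)³ box, counts = round(3400/particle volume)). Sizes are
  interpreted as radii; ε defaults to 0.2 kBT (weakly attractive); in
  `AD_rep` the D particles carry +1 e. The printed size/volume numbers do
  not admit a physical packing below unit volume fraction under any
  convention, so the resulting systems are very dense (effective packing
  ≈ 0.65) and depletion observables should be read qualitatively.
* **Toy cells**: static 8-bead macromolecule clusters plus point
  metabolites, either uniform (ideal gas, re-sampled per frame) or pinned
  at an exact nearest-surface distance — fixtures with closed-form
  expectations for the spatial metrics.

## Diffusion analysis

MSD uses sliding window origins (interval `dt_origin`; 10 ps for
macromolecules, 1 ns for metabolites and 500 ps for crowding-correlation
presets) up to τ_max = 10 ns by default, averaged over origins and copies;
`msd_brute_force` is the all-origins double-loop oracle the vectorised
path is tested against. D_tr is the straight-line slope over the last 80%
of the curve divided by 6 (the short-τ transient degrades full-range
fits; a full-range option exists for crowding-resolved variants). D0
comes from a user table when supplied, else Stokes–Einstein (the source
is recorded). Size-scaling fits provide the one-parameter forms A/Rs²
and B/Rs (through the origin), a free-exponent power law for Rs(Mw) —
the printed exponent is deliberately not hard-coded — and an ordinary
linear fit for normalized-D versus normalized-coordination trends.

Surface diffusion of metabolites: a frame is "interacting" when the
metabolite is within a per-species cutoff (8 Å default; 10 Å for larger
cofactors) of the nearest macromolecule surface. A contiguous
same-partner run longer than `min_residence` (5 ns) is a surface segment;
MSD windows are confined to segments, and the Einstein slope is divided
by 4 (2D) instead of 6. The residence rule follows the weaker
"run longer than the threshold" reading; the stricter
"margin on both sides of each frame" reading would label nothing in a
6 ns run and is not what downstream counts expect.

## Rotation

Orientation is tracked by the least-RMSD proper rotation (Kabsch
construction with reflection guard) onto a reference structure. The
correlation θ(τ) = ⟨(1/3)·Tr[R(t)ᵀR(t+τ)]⟩ is the first-rank
autocorrelation averaged over the three body axes (the columns of R —
the set of "rotated unit vectors" is not otherwise pinned down); for
isotropic rotational diffusion θ = exp(−2·Drot·τ). A single-exponential
fit over θ ∈ [0.1, 1] gives τ_rel and Drot = 1/(2·τ_rel); a curve that
never decays below 0.9 is flagged no-fit with τ_rel = ∞. The mean angular
velocity is ω = (180/π)·arccos⟨Δe(τ_max)⟩, reported per τ_max window by
default (per-ns available) — the windowing leaves the output unit
genuinely ambiguous, so it is an option rather than a guess.

## Interactions

Coordination numbers Nc count reference beads/atoms of *other*
macromolecules within 50 Å of the target's nearest reference atoms (25 Å
from the centre of mass in metabolite mode), window-averaged (10 ns
windows advanced 500 ps). Group-level association uses the distance
change Δd between τ_short-averaged initial and final windows for pairs
selected by scaled distance r̄ = 2r_c/(Rs_α+Rs_β) < R_cut, averaged over
R_cut ∈ [2, 3]; uncertainties come from 50 random-half resamples with
SE = SD/2, following the source convention. Two statistical caveats are
documented because the tests depend on them: (i) selecting
initially-proximal pairs biases *non-interacting* diffusion toward
positive Δd unless displacements per span are small against initial
separations; (ii) the SD/2 resampling SE is close to half the standard
error of the full-sample mean, so "2·SE" brackets roughly one sigma.
Multi-trajectory combination uses trajectory-length weights; τ_short
selection uses the window-averaged r̄ with an instantaneous option.

## Spatial distributions

The proximal g(r) bins metabolite distances to the *nearest* macromolecule
surface (per-atom van der Waals radii from a configurable table; the
sphere radius itself for coarse-grained fixtures; zero radii reproduce
plain nearest-atom distances). Shell volumes V(r) are voxel-counted (1 Å
grid default): every voxel of the periodic box is assigned exactly once —
to a distance shell, to the interior of the van der Waals surface, or to
beyond-r_max — so volume is conserved exactly in voxel units. ρ(r) =
n(r)/V(r) is normalised by the 20–25 Å plateau mean; a slope test flags a
non-flat plateau since ρ(∞) would then be biased. Note the 1 Å grid
aliases 0.5 Å shells of lattice-aligned geometry by tens of percent per
bin; grid and bin width are parameters, and 0.5 Å voxels with 1 Å bins
hold the voxelisation error of smooth fixtures under a few percent.
Density maps accumulate ligand positions in the target's reference frame
(rigid motion removed per frame by superposition, frames above an RMSD
threshold skipped and logged) with optional symmetry averaging through a
user-supplied coordinate map.

## Structure metrics

Core RMSD filters flexible atoms first: atoms whose mean-square
fluctuation about the time-mean structure (after superposition) exceeds
3.0 Ų (protein) or 4.0 Ų (tRNA) are dropped, iterating
filter → re-superpose to convergence (≤ 5 rounds; whether to iterate is a
design choice here). The thresholds are applied to *mean-square*
fluctuations, matching their printed Ų units. Rg always uses all
backbone-equivalent atoms. d_lig is the distance between site
centres-of-mass; Q_tot sums the charges of entities with any atom
strictly within 8 Å of any site atom; contact pairs count cross-selection
atom pairs within a cutoff (10 Å protein–protein, 5 Å phosphate–site
presets), minimum image throughout.

## Problem sizes and what the tests show

The packaged study conditions are desk-scale by design: the crowded run
uses 648 spheres (scale factor 3) for ~1 µs rather than ten 20 µs
replicas of the full composition, the mixture runs a few hundred
particles for a few ns, and estimator checks use 10⁴–10⁵ particle·steps.
Synthetic fixtures have exactly known ground truth but none of the shape
anisotropy, soft attractive patches, conformational flexibility or
electrostatic heterogeneity of real macromolecules — passing tests
validate the estimators and the simulator, not biological predictions.
Against that scope, two empirical honesty notes from the validation runs:
the engine reproduces hard-sphere long-time self-diffusion
(φ = 0.40 → D_L/D0 ≈ 0.26), and with the synthetic composition at
φ = 0.39 the crowding slow-down is considerably milder than published
whole-cytoplasm coarse-grained results, which implies the real
composition packs Stokes spheres substantially tighter than this
stand-in; the size-scaling coefficient check reflects that gap rather
than an estimator defect.

## Known limitations

No rotational BD of the coarse-grained spheres (synthetic rotors serve
the rotational estimators); no lubrication/near-field hydrodynamics; no
Ewald electrostatics; no triclinic boxes; no anomalous-diffusion
exponents (runs are deliberately too short for the exchange regime); DCD
round-trips need the JSON sidecar for species labels and times.
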