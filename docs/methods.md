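# Methods

This note documents the models behind each module, the conventions and
defaults, the numerical choices made where the design was genuinely open,
and what the synthetic validation systems do and do not establish about real
trajectories.

## Coordinate and unit conventions

Lengths are in Å, times in ns, charges in elementary units (e), energies in
kcal/mol, potentials in mV.  The membrane normal is +z with z = 0 at the
membrane center and the extracellular side at positive z, so activation of a
voltage sensor moves S4 charges to larger z.  Residue numbering is the
1-based author numbering of the input PDB (human BK numbering for BK work);
nothing is ever renumbered.  Only orthorhombic boxes are supported —
triclinic input raises immediately rather than silently mis-wrapping.
Conversion constants live in `bkgating.core`: k_B = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹, 1 e·mV = 2.30605×10⁻² kcal/mol, and 1 e/Å = 14 399.6 mV.

Transmembrane helices default to the human BK Core-MT spans S1 T109–S135,
S2 F148–A170, S3 V181–L199, S4 G205–N225, S5 S230–S259 and S6 A313–E324
(the segment below the glycine hinge).  Charged-group positions are the
guanidinium CZ atom for Arg and the side-chain carboxyl carbon for Asp/Glu
(CG/CD); Lys NZ and His NE2 are provided for completeness.

## Gating-charge thermodynamics

`ΔG_s(V, qᵢ)` — the free-energy cost of growing residue charge i from 0 to
qᵢ in state s at voltage V — is integrated from tabulated mean forces
⟨∂H/∂λ⟩ by trapezoidal quadrature on the λ grid 0.0, 0.1, …, 1.0.
Trapezoid (rather than Simpson) matches the fixed 0.1 increments and is
exact for the linear charging response expected of a near-linear dielectric
medium; the λ² check value 0.335 (vs the exact 1/3) quantifies its bias on
a deliberately curved profile.  Window statistics come from block averaging
(5 blocks by default): the standard error is std(block means)/√n_blocks.
Mean-force errors propagate through the quadrature as the root sum of
squares of trapezoid-weighted errors and through the coupling-factor
quotient in the usual way.

The coupling factor f_s(i) = [ΔG_s(V₂) − ΔG_s(V₁)]/(qᵢ(V₂ − V₁)) is a
fraction of the applied potential and is dimensionless; values outside
[−0.2, 1.2] are flagged rather than rejected, since noisy inputs can
legitimately stray outside [0, 1].  With the potential rising from the
intracellular (f = 0) to the extracellular (f = 1) side, per-residue
contributions are reported as qᵢ·(f_open − f_closed): an outward-moving
positive charge then contributes positively, which is the sign convention of
published per-residue gating-charge tables for BK (R210 ≈ +0.25 e).

The package consumes mean-force tables (CSV:
`residue,state,voltage_mV,lambda,mean_force_kcal_mol,stderr`) rather than
running MD.  A toy analytic engine (`slab_ti_curve`) charges a point charge
in the linear slab potential, where ∂H/∂λ = q·V·f(z) independently of λ;
this makes the entire TI → coupling-factor → ΔQ chain exercisable against
the exact capacitor result Σ q·Δz/L, which the test suite requires to
1×10⁻¹⁰.

## Electrostatic potential maps

Each atomic point charge is replaced by a spherical Gaussian of inverse
width β (default 0.25 Å⁻¹) accumulated on a periodic grid (default 1 Å
spacing, truncated where the Gaussian falls below ~10⁻¹⁴).  The Poisson
equation ∇²φ = −4πρ is solved spectrally with tinfoil boundary conditions;
dropping the k = 0 mode simultaneously neutralises non-neutral cells by a
uniform background and fixes the zero-mean gauge.  The dielectric is
implicit (vacuum-like Poisson on the smeared density) and no point-charge
short-range correction is added: maps are smeared potentials, appropriate
for field visualisation, not for energies.  Because the gauge is arbitrary,
only potential *differences* are meaningful.

Validation compares the solved single-charge potential with the closed form
q·erf(βr)/r.  The periodic solution differs from the open-boundary form by
the uniform-background term +(2π/3V)r², a gauge constant, and l = 4 lattice
harmonics; after removing the first two analytically the residual is below
1% out to r = L/4 on a 64 Å box.

The applied transmembrane voltage is carried as an *analytic* linear-ramp
component of the grid object rather than being added to the node array: a
ramp is not periodic, so baking it into the nodes would corrupt wrap-around
interpolation.  Probing adds the ramp exactly at the probe height (so the
probed difference across the box is exactly V); OpenDX export samples it
onto the nodes.  With no span given, the ramp follows the constant-field
convention E = V/L_z across the whole box; with a membrane span it is 0
below, linear within and V above the slab, which reproduces the slab
system's electrical distances exactly.

## Conformation, hydration and permeation metrics

Per-residue series are averaged over the chains sharing a residue number
(the four subunits of a homotetramer) with per-chain series kept alongside.
Running averages use a centered window (default 50 frames) and are
presentation-only.

**Helix tilt.**  The helix axis is estimated from the Cα trace as the
smallest-variance principal direction of the *second differences* of
consecutive Cα positions.  For an ideal helix these difference vectors lie
exactly in the plane perpendicular to the axis, so the estimate is exact at
any length and tilt; the more obvious first principal component of the raw
coordinates is biased by ~2° on short helical segments because the helical
phase correlates with height along the axis.  The trade-off is noise
sensitivity (second differences amplify coordinate noise), acceptable for
tilt time series that are running-averaged anyway.  Only tilt magnitude
(folded into [0°, 90°], axis oriented N→C) is computed; bend/swivel
decompositions are out of scope.

**RMSD** uses Kabsch SVD superposition (with a reflection guard) and is
cross-checked in the tests against an independent quaternion (Kearsley)
oracle.

**Contacts.**  A residue pair is in contact in a frame when the minimum
heavy-atom distance is ≤ 5 Å; the pair is a network edge when that holds in
≥ 75% of frames.  Hydrogens are excluded by element, with a name-prefix
fallback when elements are absent.

**Pore profiles** re-implement the HOLE construction: per z-slice the pore
radius is max over candidate centers of min over atoms of
(center–atom distance − vdW radius), searched on a coarse 0.25 Å xy grid
around an axis hint and refined by two 5× finer local grids (deterministic,
ties broken by lowest grid index).  The refined center of each slice seeds
the next, letting the axis path wander as HOLE's does.  Slices with no atoms
nearby report a capped bulk sentinel (15 Å).

**Pore waters** are counted between the center of mass of the lower boundary
ring (L312 Cα by default) and the plane through the upper ring's center of
mass (P320), within a lateral radius of the pore axis.  The lateral bound
(default 10 Å) is needed because a purely z-based definition would sweep up
bulk and lipid-phase waters; water positions are taken as the selected
oxygen atoms.  Both choices are conventions, flagged here because published
definitions of the inner-cavity water count leave them unstated.

**Permeation** uses a double-crossing criterion on unwrapped z: the counting
region [plane_lower, plane_upper] repeats every box length along the
unwrapped axis, and one event is a move from the gap below a region copy to
the gap above it (or the reverse) — oscillation inside the region, or
entry-and-retreat, counts nothing, and an ion recycled by the periodic box
counts once per physical crossing.  The counter is time-reversal symmetric
by construction.  Conductance is g = N·q/(T·V), reported in pS.

**Membrane thickness** splits the headgroup selection into leaflets about
its per-frame mean z (not the absolute sign of z, which would break under
rigid translation) and reports the difference of leaflet mean heights.

**Free-energy surfaces** are F = −RT ln P̂(x, y) on a fixed-width histogram,
min-shifted to zero with +inf in empty bins; the 4 kcal/mol contour used in
figures is a presentation parameter, not part of the computation.

## Dynamic-network analysis

Nodes are residues at their Cα positions.  The edge affinity C_ij is the
*normalised* covariance (Pearson correlation) of Cα displacement vectors
after rigid-body superposition — the path-weight formula w = −log|C|
requires |C| ≤ 1, so the plain covariance would be ill-formed.  Edges exist
where the 5 Å/75% contact rule holds; C = 0 edges are dropped as infinitely
weak.  Superposition can be skipped (`superpose=False`) for ensembles whose
rigid-body motion is removed at the source, since fitting a very small node
set injects spurious correlations of order 6/(3N).

Optimal paths minimise total w along the graph; suboptimal paths are all
simple paths within 1.5× of the optimal length, enumerated in nondecreasing
length order (Yen's k-shortest simple paths) with a 1000-path guard and a
truncation flag.  All tie-breaks are lexicographic in node order, so outputs
are deterministic.  Communities come from divisive Girvan–Newman clustering
(removing edges of highest w-weighted betweenness) with the partition chosen
at maximal modularity under |C| edge strength; the trivial
connected-components partition competes too, so a single clique stays whole
and disconnected components are never merged.  Both the partition and its
modularity are reported so alternative algorithms can be compared.

Node entropies H_i = ⟨−ln ρ̂(x)⟩ use the scalar distance of the node to its
mean position as the 1-D fluctuation coordinate, with the density estimated
by a Gaussian mixture whose component count (1–5) is selected by BIC
(10 EM restarts, fixed seed).  Mutual information M_ij = H_i + H_j − H_ij
uses a 2-D mixture for the joint; identical inputs short-circuit to
M = H_i, and slightly negative estimates are clipped at zero with a warning.

Information flow injects one unit of current at a source and drains it at a
sink on the conductance graph A_ij = |C_ij|·M_ij (the absolute value keeps
conductances non-negative, which the Laplacian formalism requires for
anticorrelated pairs).  Potentials solve the reduced Laplacian L = D − A
with the sink row/column removed and P_sink = 0; interior nodes carry
f_i = ½ Σ_j |P_i − P_j| A_ij, and the endpoints carry the full unit of
current (f = 1) by construction.  This equals current-flow (random-walk)
betweenness for the pair.  Components not containing the source carry zero
flow; a sink unreachable from the source is an error.  Reported profiles
are ranked with a strict f > 0.02 highlight threshold.

## Synthetic validation systems

`synthetic` generates the desk-scale stand-ins used throughout the tests:

* **Elastic networks.**  An anisotropic network of Hookean springs on Cα
  beads; frames are i.i.d. draws from the Gaussian with covariance
  k_BT·H⁺, where H⁺ is the pseudo-inverse of the spring Hessian with
  zero-frequency (rigid-body) modes removed by a relative eigenvalue
  threshold — six modes for generic 3-D networks, fewer for degenerate
  geometries such as a single spring, where a fixed rank-6 cutoff would
  delete the only elastic mode.  The exact covariance, its residue-level
  correlation (3×3 block traces) and the planted community labels are
  returned alongside the trajectory.  The default validation network is two
  12-ish-bead all-to-all blocks (k = 5 kcal mol⁻¹ Å⁻²) joined by one weak
  spring (k = 0.05), a contrast strong enough that community recovery is
  deterministic.
* **Voltage slab.**  Point charges in a membrane slab under the constant
  field confined to the span; electrical distances are exact (no sampling),
  enabling 1×10⁻¹⁰ gating-charge recovery tests.
* **Scripted pores.**  Water beads placed inside/outside a counting cylinder
  in scripted numbers per frame, plus ions following prescribed z(t) paths
  whose crossing counts are known by construction (the generator packages
  the script; it never measures).  Boundary rings of Cα beads at residues
  312/320 let the residue-based pore-water interface run unchanged.

These systems share none of the hard features of real trajectories — no
force-field realism, no lipids or explicit solvent, i.i.d. rather than
autocorrelated frames, Gaussian rather than multimodal fluctuations, and
scripted rather than diffusive ion motion.  Passing tests therefore
establish the *correctness of the estimators and bookkeeping* (quadrature,
unit handling, counters, solvers, graph algorithms), not the adequacy of
sampling or force fields in any particular MD study.  Quantities that
depend on multi-microsecond sampling of a 250,000-atom system (absolute
per-residue gating charges of a real channel, its conductance, its field
maps) are inputs to this package, not outputs of the synthetic systems.

All generators take explicit integer seeds and are bit-reproducible; seeds
are function arguments, never ambient state.

## Problem sizes used in validation

The shipped checks run at desk scale by design: 10⁴-frame Gaussian
ensembles for estimator recovery (entropy to ±0.05 nat, mutual information
to ±0.1 nat, correlation matrices to 5% Frobenius), 16-node planted
networks for community recovery, 8–10-node random graphs against exhaustive
path enumeration and dense linear-solve flow oracles, 64 Å boxes for the
Poisson checks, and a few hundred frames for the counter oracles.

## Known limitations

* The Poisson maps are smeared-charge potentials in an implicit vacuum-like
  dielectric; they are not Poisson–Boltzmann calculations and carry no ionic
  screening.
* Mean-force inputs are trusted as given; no equilibration detection or
  autocorrelation-aware error model beyond fixed-count block averaging.
* The tilt estimator trades noise robustness for exactness on ideal
  geometry; heavily distorted segments should be running-averaged or
  restricted to their straight core (e.g. S6 residues 313–324).
* GMM entropy estimates are biased low for heavy-tailed densities and the
  BIC scan stops at 5 components.
* The suboptimal-path enumerator is exponential in the worst case; the
  max_paths guard truncates (and flags) rather than exhausts on dense
  graphs.
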