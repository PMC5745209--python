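# Methods

This note documents the models, parameters and design choices behind the
package; the README gives the user-facing overview.

## Interaction model

All energetics are pairwise and intermolecular:
`E_inter = E_Coulomb + E_LJ + ΔG_sol`.

* **Lennard-Jones.** 12-6 form `V(r) = ε_ij [(R_ij/r)^12 − 2 (R_ij/r)^6]`
  with per-type parameters (Rii, εii) from the published AutoDock 4 table
  shipped as `wns/data/atom_types.tsv`, geometric-mean combining for ε and
  arithmetic-mean combining for R.  No van-der-Waals weighting factor is
  applied: the excluded-type calibration arithmetic (a ~1 kcal/mol X–O
  value at r = 2 Å) only holds for raw 12-6 values.
* **Electrostatics.** Coulomb with the 332.0637 kcal·Å/(mol·e²) constant
  and a *constant* dielectric (default 1, configurable).  This is a
  deliberate deviation from distance-dependent dielectrics used by some
  docking engines; it keeps the term analytic and testable.
* **Solvation.** `ΔG_sol` is a hook accepting any callable
  `(target, ligand) → kcal/mol`; the default contributes zero.  Grid-based
  desolvation maps are out of scope.
* **Degenerate inputs.** Pair distances below 0.1 Å are evaluated at
  0.1 Å, and per-pair force magnitudes are clamped at 50 kcal/(mol·Å), so
  clashes stay finite and integrable; both clamps are logged constants in
  `wns.forcefield`.

## Excluded-type calibration

Covered surface is marked with the reserved atom type `X`: zero charge
and a tiny well depth ε_X = 10⁻⁴ kcal/mol.  R_X is solved in closed form
from the repulsion-cap condition `V_XY(r_probe) = v_cap` (defaults: 2 Å,
1 kcal/mol): with `x = (R_ij/r_probe)^6` the 12-6 form gives
`ε_ij (x² − 2x) = v_cap`, whose repulsive root is
`x = 1 + √(1 + v_cap/ε_ij)`, and the combining rule inverts to
`R_X = 2 R_ij − R_Y`.  Against oxygen this yields R_X ≈ 3.149 Å (≈3.15);
carbon and hydrogen give 2.42 and 4.95 Å, mean ≈ 3.51 Å.  The shipped
default X entry uses the field-adopted average of 3.6 Å; both the per-type
solutions and the 3.2 Å oxygen-rounded variant are selectable through
`WrapperConfig.r_x`.  `calibrate_excluded_type` also emits three scenario
curves (solved R_X, ±1 Å) illustrating why too-large R_X widens the
ligand-free zone and too-small R_X leaves residual attraction.

## Wrapper

Each cycle: dock `n_runs` copies → greedy energy-ordered clustering
(2 Å pose-RMSD tolerance, no alignment — poses share the target frame) →
rank by `e_inter` → retain bound cluster representatives → exclude the
covered interface → recompute coverage.  Design points:

* **Docking state.** Retained copies are merged into the docking target
  as X-typed pseudo-atoms, exactly like their surrounding target atoms.
  Excluding only the target atoms is not enough: second-shell target atoms
  keep the covered site attractive and the search keeps re-docking there.
  With the copies physically present (uncharged, weakly repulsive), covered
  sites saturate and the search moves on.
* **Retention screens.** Only representatives with `e_inter < 0` are
  retained; a cycle with none triggers EC_W.  A candidate is also dropped
  if any heavy atom comes within 1.5 Å of an excluded atom (clash with a
  covered zone) or within 2.0 Å of an already retained copy's heavy atoms
  — the latter guarantees the monolayer no-overlap invariant, which the
  weak X repulsion alone cannot enforce between same-cycle representatives.
  Control mode (`exclusion_enabled: false`) disables the exclusion marking
  and both screens and demonstrably produces multi-layer aggregates.
* **Coverage.** "Ligand-free surface" is the summed per-atom
  solvent-accessible area of the *target* atoms computed in the presence
  of all retained copies (copies occlude), normalised by the bare-target
  area; Shrake–Rupley with a 1.4 Å probe, per-atom radii Rii/2, 480 sphere
  points by default (doubling changes totals by well under 1%).
* **Termination.** Coverage below 1% of the initial area, or EC_W, or
  three consecutive cycles whose placements were all screened out
  (docking is reseeded per cycle, so one barren cycle is not saturation),
  or a 50-cycle guard.  With small rigid toy ligands EC_W often fires
  first, leaving a few percent of the surface uncovered in narrow gaps the
  ligand cannot occupy — the exit rule, not the 1% figure, is the
  invariant.  A final trim removes copies farther than 3.5 Å from the
  target.

Either all docked poses or representatives only can be retained per cycle
(`retain: all|representatives`); representatives are the default.

## Toy docking backend

`wns.dockkit.dock` runs `n_runs` independent Metropolis Monte-Carlo
chains of a rigid ligand (Gaussian translation steps of 1 Å, rotation
steps of 15°, kT = 1 kcal/mol, 2,000 steps by default) over the target
bounding box, propagated in lock-step and returning each chain's
best-energy snapshot.  It is deterministic per request seed and exists to
make the protocol testable end to end; ligand flexibility and production
search engines belong to external backends implementing the
`DockingBackend` contract.

## Toy shaking engine

`wns.dynamics.shake` integrates each copy as an overdamped rigid body:
the centre feels the analytic LJ+Coulomb force from the target plus
Gaussian noise with variance `2 kT Δt / γ`; orientations perform small
diffusive rotations (no torque integration — pocket capture and escape in
these fixtures are translation-dominated).  Copies interact with each
other through repulsive-only (WCA-truncated) LJ contacts clamped at
5 kcal/(mol·Å) per pair: enough to keep a dissociating copy from drifting
into an occupied pocket, deliberately weaker than the target-force clamp
so a contact cannot mechanically eject a pocket-bound copy.  Temperature
follows a triangular ramp from 27 °C to the schedule ceiling and back:
50 °C for ligands with MW ≤ 300 g/mol, 80 °C above (exactly 300 takes the
50 °C branch; configurable).  Nominal phase lengths are 5 ns (restrained
pre-shake), 20 ns (annealing cycles) and 20 ns (flexible refinement),
mapped to steps via `steps_per_ns` (default 10,000).  The target is fixed
during restrained phases; during the flexible refinement its atoms are
harmonically tethered (k = 10 kcal/mol/Å²) with their own thermal noise
and no ligand back-reaction.  Integrator defaults Δt = 0.01, γ = 1 give
~0.11 Å r.m.s. thermal steps at 300 K; any per-step displacement above
2 Å aborts with advice to reduce the step.  The Langevin bath replaces
explicit solvent: hydration structure, water-mediated contacts and
friction anisotropy are *not* modelled, so external MD trajectories can be
fed to the Shaker as multi-model PDB instead.

## Shaker

Per-copy, per-frame metrics: minimum heavy-atom distance to the target,
E_LJ (always with the target's *standard*, pre-exclusion typing), and
centroid displacement from the first frame.  The filter cascade is fixed
in order, each discard recording the step that fired:

| step | rule | default |
|------|------|---------|
| F1 | final-frame min target distance > d_diss | 4.5 Å |
| F2 | centroid displacement > d_drift through the trailing window | 5.0 Å |
| F3 | mean E_LJ over the trailing window > e_mean_cap | −1.0 kcal/mol |
| F4 | final-frame E_LJ > 0 | — |

with a trailing window of 20% of frames.  The thresholds are package
defaults exposed in the config; they were chosen so that a copy bound in
a multi-kcal/mol pocket passes comfortably while a detached or
surface-drifting copy fails at least one screen.  F3 and F4 are both
energy screens: reordering them cannot change which copies survive, only
the recorded reason.

The protocol runs one restrained pre-shake, then annealing cycles until
EC_S (≥75% eliminated) or a 10-cycle guard; washed survivors keep their
last-frame conformations, are clustered greedily by centroid distance
(default limit 3.5 Å; a 6 Å wide-pocket variant and a pose-RMSD mode are
selectable — centroid distance is the default because last-frame
conformers across different pockets make pose-RMSD ill-conditioned),
refined with the flexible phase, and ranked by E_LJ (or E_LJ+E_Coulomb
via config).  SR is reported raw and rounded to the nearest integer; zero
survivors yield an `N/0` sentinel.  Skipping the restrained phases is
permitted but flags the run `protocol-incomplete`; on the mixed fixture it
demonstrably leaves loose binders in the final set.  EC_S is evaluated on
washed copy counts *before* final clustering.

## Metrics

`pocket_aligned_rmsd` selects reference-target residues with any heavy
atom within 5 Å of the reference ligand, Kabsch-superposes the model
target onto the reference on those residues' heavy atoms, applies the
transform to the model ligand and returns the heavy-atom RMSD with
name-resolved atom correspondence (symmetry-equivalent atoms are not
deduplicated).  Heavy atoms only, in both alignment and RMSD.

## Synthetic fixtures and what they show

`make_toy_target` builds a *solid* pseudo-atom ball (radius 10 Å, 2.2 Å
cubic lattice with small deterministic jitter, ~330 atoms) rather than a
hollow shell: a hollow shell has a solvent-accessible interior that the
blind search would happily wrap, making the coverage criterion depend on
a physically meaningless inner surface.  Pockets are carved as 4.6 Å
cavities just under the surface; the lining is re-typed to oxygen and its
charge is solved — jointly across pockets by Gauss–Seidel sweeps, since
each lining's monopole shifts the others — so the companion ligand's
local energy minimum matches the requested depth (verified within 20% by
grid scan in the tests).  The default study conditions: two pockets at
−10 and −5 kcal/mol for the wrapping fixture; six −10 kcal/mol pockets
plus 18 flat-surface copies (the mixed, 24-copy fixture) for shaking,
where pocket copies are "stayers" and flat copies (−2 to −3 kcal/mol,
a few kT) are "leavers".  Labelled trajectories move stayers with < 1 Å
rigid jitter and leavers linearly outward beyond 10 Å.

Passing tests on these fixtures show that the bookkeeping, exclusion
logic, exit criteria, filters and ranking behave as specified, and that
the physics engines produce the qualitative behaviour the protocol relies
on (strong sites found first, weak binders shaken off faster, higher
ceilings accelerating dissociation).  They do not show chemical accuracy
on real proteins: real targets are flexible, hydrated, irregularly shaped
and their ligands are flexible — all outside the toy engines.

## Problem sizes

The test suite and the acceptance script shrink sampling effort, not the
method: docking cycles use 40–60 runs × 400–600 MC steps (defaults
100 × 2,000), dynamics use 200 steps/ns (default 10,000), and surface
areas use 240–480 sphere points.  These sizes were fixed as the package's
standard desk-scale conditions; all are plain config values.

## Known limitations

* Rigid ligands in both toy engines; flexibility enters only through
  external backends.
* No solvation term by default; no distance-dependent dielectric.
* The toy shaker can occasionally lose a genuine binder through a
  copy–copy collision when a dissociating copy transits an occupied
  pocket (at most one of six pocket binders across tested seeds), and a
  late-lingering loose binder can survive if EC_S is reached first; both
  are reported honestly in run outputs.
* Monolayer coverage of small rigid ligands saturates by EC_W at a few
  percent uncovered surface when remaining gaps are narrower than the
  ligand.
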