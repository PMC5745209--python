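"""Wrapper: iterative blind-docking cycles building a ligand monolayer.

Each cycle docks ``n_runs`` ligand copies over the not-yet-covered target
surface, clusters and ranks them, retains the bound cluster representatives,
and then *excludes* the covered interface: every target heavy atom within
the interface tolerance (3.5 Å) of a retained ligand heavy atom is re-typed
to the excluded type ``"X"`` — zero partial charge, calibrated short-range
repulsive LJ parameters — so the next cycle can only dock to unbound
surface.  Cycles stop when the ligand-free fraction of the initial
solvent-accessible surface drops below 1%, when a cycle yields no bound
cluster representative (all-positive interaction energies, the EC_W
criterion), or when a max-cycle guard fires.  A final trimming removes
copies more than 3.5 Å from the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dockkit import (
    DockingBackend,
    DockingRequest,
    LigandPose,
    cluster_poses,
    dock,
    rank_poses,
    representatives,
)
from .errors import WnsError
from .metrics import asa
from .structio import EXCLUDED_TYPE, AtomRecord, ParameterTable, Structure

log = logging.getLogger(__name__)


@dataclass
class WrapperConfig:
    """Tunable parameters of the wrapping loop (distances in Å)."""

    # docking backend settings, per cycle
    n_runs: int = 100
    mc_steps: int = 2000
    translation_step: float = 1.0
    rotation_step: float = 15.0
    mc_temperature: float = 1.0
    dielectric: float = 1.0
    # wrapping proper
    cluster_rmsd_tol: float = 2.0
    interface_tolerance: float = 3.5
    asa_exit_fraction: float = 0.01
    trim_distance: float = 3.5
    max_cycles: int = 50
    retain: str = "representatives"     # or "all"
    exclusion_enabled: bool = True      # False = control mode (no repulsion)
    clash_distance: float = 1.5         # pose heavy atom vs excluded atom
    overlap_distance: float = 2.0       # pose heavy atom vs retained copies
    r_x: float = 3.6                    # excluded-type pair-distance default
    eps_x: float = 1e-4
    asa_n_points: int = 480
    asa_probe: float = 1.4


@dataclass
class CycleStats:
    cycle: int
    poses_added: int
    asa_fraction: float
    best_e_inter: float | None


@dataclass
class WrapState:
    """Mutable wrapping state: target exclusions, retained copies, log."""

    target: Structure
    retained_poses: list[LigandPose] = field(default_factory=list)
    cycle_log: list[CycleStats] = field(default_factory=list)
    initial_asa: float = 0.0


@dataclass
class MonolayerComplex:
    """A target wrapped in N retained ligand copies, with provenance."""

    target: Structure
    copies: list[LigandPose]
    cycle_log: list[CycleStats] = field(default_factory=list)
    initial_asa: float = 0.0

    @property
    def n(self) -> int:
        return len(self.copies)


# ---------------------------------------------------------------------------
# Exclusion marking
# ---------------------------------------------------------------------------

def mark_excluded(
    state: WrapState,
    tolerance: float = 3.5,
    table: ParameterTable | None = None,
) -> WrapState:
    """Re-type target heavy atoms near retained copies to the excluded type.

    Every target heavy atom within *tolerance* of any retained ligand heavy
    atom gets atom type ``"X"``, zero partial charge and the calibrated X
    LJ parameters.  The flag is sticky: once excluded, always excluded.
    """
    if not state.retained_poses:
        raise WnsError("mark_excluded requires at least one retained pose")
    table = table or ParameterTable.default()
    x_R, x_eps = table.lookup(EXCLUDED_TYPE)
    lig_xyz = np.vstack([p.heavy_coords() for p in state.retained_poses])
    tree = cKDTree(lig_xyz)
    for a in state.target.atoms:
        if a.is_excluded or not a.is_heavy:
            continue
        d, _ = tree.query(a.coords, k=1)
        if d <= tolerance:
            a.atom_type = EXCLUDED_TYPE
            a.charge = 0.0
            a.lj_R = x_R
            a.lj_eps = x_eps
            a.is_excluded = True
    return state


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _complex_atoms(state: WrapState):
    atoms = list(state.target.atoms)
    for p in state.retained_poses:
        s = p.as_structure()
        atoms.extend(s.atoms)
    return atoms


def ligand_free_asa_fraction(
    state: WrapState,
    n_points: int = 480,
    probe: float = 1.4,
    table: ParameterTable | None = None,
) -> float:
    """Uncovered fraction of the target's initial accessible surface.

    The target-atom ASA is recomputed in the presence of all retained ligand
    copies (copies occlude) and normalised by the bare-target ASA measured
    before wrapping started.
    """
    if state.initial_asa <= 0:
        raise WnsError("initial_asa must be computed on the bare target first")
    if not state.retained_poses:
        return 1.0
    atoms = _complex_atoms(state)
    nt = len(state.target.atoms)
    mask = np.zeros(len(atoms), dtype=bool)
    mask[:nt] = True
    res = asa(atoms, probe=probe, n_points=n_points, subset=mask, table=table)
    return float(res.per_atom[:nt].sum() / state.initial_asa)


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim(complex_: MonolayerComplex, distance: float = 3.5) -> MonolayerComplex:
    """Drop copies whose minimum heavy-atom distance to the target exceeds
    *distance*; mutates and returns the complex."""
    t_heavy = np.array(
        [a.coords for a in complex_.target.atoms if a.is_heavy]
    )
    tree = cKDTree(t_heavy)
    kept = []
    for p in complex_.copies:
        d, _ = tree.query(p.heavy_coords(), k=1)
        if float(np.min(d)) <= distance:
            kept.append(p)
    complex_.copies = kept
    return complex_


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _cycle_seed(seed: int, cycle: int) -> int:
    return int(np.random.SeedSequence([seed, cycle]).generate_state(1)[0] % (2**31))


def docking_state(state: WrapState, table: ParameterTable) -> Structure:
    """The target as the next docking cycle sees it.

    Retained ligand copies are part of the docking target, re-typed to the
    excluded type exactly like their surrounding target atoms: uncharged
    and weakly short-range repulsive, so covered sites are physically
    occupied but do not attract further copies.
    """
    if not state.retained_poses:
        return state.target
    x_R, x_eps = table.lookup(EXCLUDED_TYPE)
    merged = list(state.target.atoms)
    serial = max(a.serial for a in merged) if merged else 0
    for p in state.retained_poses:
        for a, xyz in zip(p.template.atoms, p.coords):
            serial += 1
            merged.append(AtomRecord(
                serial=serial, name=a.name, coords=np.asarray(xyz, dtype=float),
                atom_type=EXCLUDED_TYPE, charge=0.0, lj_R=x_R, lj_eps=x_eps,
                is_excluded=True, resname="XCP", resid=serial, chain="X",
                base_type=a.base_type, base_charge=0.0,
            ))
    return Structure(merged, label=state.target.label, meta=dict(state.target.meta))


def _min_heavy_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    tree = cKDTree(coords_b)
    d, _ = tree.query(coords_a, k=1)
    return float(np.min(d))


def run_wrapper(
    target: Structure,
    ligand: Structure,
    config: WrapperConfig | None = None,
    seed: int = 0,
    backend: DockingBackend = dock,
    table: ParameterTable | None = None,
) -> MonolayerComplex:
    """Wrap *target* into a monolayer of *ligand* copies.

    Returns the trimmed complex together with the per-cycle log
    (cycle, poses added, ligand-free ASA fraction, best representative
    interaction energy).  Deterministic for a fixed seed and backend.
    """
    config = config or WrapperConfig()
    table = (table or ParameterTable.default()).with_x_radius(config.r_x, config.eps_x)
    state = WrapState(target=target.copy())
    state.initial_asa = asa(
        state.target, probe=config.asa_probe, n_points=config.asa_n_points, table=table
    ).total
    if state.initial_asa <= 0:
        raise WnsError("bare target has zero accessible surface")

    next_copy_id = 1
    zero_streak = 0
    for cycle in range(1, config.max_cycles + 1):
        request = DockingRequest(
            target_state=docking_state(state, table)
            if config.exclusion_enabled else state.target,
            ligand_template=ligand,
            n_runs=config.n_runs,
            n_steps=config.mc_steps,
            translation_step=config.translation_step,
            rotation_step=config.rotation_step,
            temperature=config.mc_temperature,
            dielectric=config.dielectric,
            seed=_cycle_seed(seed, cycle),
            cycle=cycle,
        )
        if not any(not a.is_excluded for a in request.target_state.atoms):
            # nothing left to dock to: the whole surface is covered
            frac = ligand_free_asa_fraction(
                state, n_points=config.asa_n_points, probe=config.asa_probe, table=table
            )
            state.cycle_log.append(CycleStats(cycle, 0, frac, None))
            break
        try:
            poses = backend(request)
        except WnsError:
            log.exception("docking backend failed in cycle %d; partial log kept", cycle)
            raise
        cluster_poses(poses, rmsd_tol=config.cluster_rmsd_tol)
        rank_poses(poses, key="e_inter")
        reps = representatives(poses)
        candidates = (
            reps if config.retain == "representatives"
            else sorted(poses, key=lambda p: p.e.e_inter)
        )

        best = min((p.e.e_inter for p in reps), default=None)
        bound = [p for p in candidates if p.e.e_inter < 0.0]
        if not bound:
            # EC_W: every cluster representative repulsive — surface saturated
            frac = ligand_free_asa_fraction(
                state, n_points=config.asa_n_points, probe=config.asa_probe, table=table
            )
            state.cycle_log.append(CycleStats(cycle, 0, frac, best))
            break

        x_coords = np.array(
            [a.coords for a in state.target.atoms if a.is_excluded]
        )
        added = 0
        for p in bound:
            hc = p.heavy_coords()
            if config.exclusion_enabled:
                if x_coords.size and _min_heavy_distance(hc, x_coords) < config.clash_distance:
                    continue
                retained_xyz = [q.heavy_coords() for q in state.retained_poses]
                if retained_xyz and _min_heavy_distance(
                    hc, np.vstack(retained_xyz)
                ) < config.overlap_distance:
                    continue
            p.copy_id = next_copy_id
            next_copy_id += 1
            state.retained_poses.append(p)
            added += 1

        if added and config.exclusion_enabled:
            mark_excluded(state, tolerance=config.interface_tolerance, table=table)
            x_coords = np.array(
                [a.coords for a in state.target.atoms if a.is_excluded]
            )
        frac = ligand_free_asa_fraction(
            state, n_points=config.asa_n_points, probe=config.asa_probe, table=table
        )
        state.cycle_log.append(CycleStats(cycle, added, frac, best))
        if frac < config.asa_exit_fraction:
            break
        # A cycle whose placements were all screened out is not yet
        # saturation — the next cycle reseeds the search; three barren
        # cycles in a row are.
        zero_streak = zero_streak + 1 if added == 0 else 0
        if zero_streak >= 3:
            break

    result = MonolayerComplex(
        target=state.target,
        copies=list(state.retained_poses),
        cycle_log=state.cycle_log,
        initial_asa=state.initial_asa,
    )
    return trim(result, distance=config.trim_distance)


def cycle_log_table(complex_: MonolayerComplex) -> str:
    """The per-cycle log as a tab-separated table."""
    lines = ["cycle\tN_added\tasa_fraction\tbest_e_inter"]
    for c in complex_.cycle_log:
        best = "nan" if c.best_e_inter is None else f"{c.best_e_inter:.3f}"
        lines.append(f"{c.cycle}\t{c.poses_added}\t{c.asa_fraction:.4f}\t{best}")
    return "\n".join(lines)
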