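"""Blind-docking backend contract plus a built-in rigid-body MC docker.

A docking backend is any callable taking a :class:`DockingRequest` and
returning scored :class:`LigandPose` objects.  The built-in backend,
:func:`dock`, runs ``n_runs`` independent Metropolis Monte-Carlo chains of a
rigid ligand over the whole target bounding box and returns the best-energy
snapshot of each chain.  It exists so the wrapping loop is exercisable and
deterministic on a desktop; production users plug in an external engine
through the same contract (see :data:`DockingBackend`).

An external AutoDock-style adapter would: write the current target state
(with exclusions applied) as PDBQT, run the engine for ``n_runs`` poses,
parse the resulting poses back into :class:`LigandPose` objects and score
them with :func:`wns.forcefield.intermolecular_energy`.  Executing such an
adapter is outside this package's scope; the contract is the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DockingError
from .forcefield import EnergyBreakdown, PairGrid
from .structio import Structure


@dataclass
class LigandPose:
    """One placed ligand copy in the target frame.

    ``coords`` are the placed coordinates of the template's atoms, in
    template order; charges/types/LJ parameters live on the template.
    """

    template: Structure
    coords: np.ndarray
    e: EnergyBreakdown | None = None
    cycle: int = 1
    run_id: int = 0
    cluster_id: int | None = None
    rank: int | None = None
    seed: int | None = None
    copy_id: int | None = None
    is_representative: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.template.atoms), 3):
            raise ValueError("pose atom count must equal template atom count")

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.template.heavy_mask()]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def as_structure(self, label: str = "") -> Structure:
        s = self.template.copy()
        s.set_coords(self.coords)
        s.label = label or f"pose-c{self.cycle}r{self.run_id}"
        return s


@dataclass
class DockingRequest:
    """Inputs of one blind-docking cycle."""

    target_state: Structure          # current exclusions already applied
    ligand_template: Structure
    n_runs: int = 100
    n_steps: int = 2000
    translation_step: float = 1.0    # Å, Gaussian proposal scale
    rotation_step: float = 15.0      # degrees, Gaussian proposal scale
    temperature: float = 1.0         # Metropolis kT, kcal/mol
    box_margin: float = 3.0          # Å beyond the target bounding box
    dielectric: float = 1.0
    seed: int = 0
    cycle: int = 1

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


DockingBackend = Callable[[DockingRequest], list[LigandPose]]


def _place(template_local: np.ndarray, rotmats: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Apply per-chain rotations and translations to centred template coords."""
    return np.einsum("bij,aj->bai", rotmats, template_local) + centers[:, None, :]


def dock(request: DockingRequest) -> list[LigandPose]:
    """Rigid-body Metropolis MC blind docking; one pose per independent run.

    All chains are propagated in lock-step (vectorised across runs); each
    chain keeps its best-energy snapshot, which becomes its returned pose.
    Deterministic for a fixed request (including seed).
    """
    target = request.target_state
    ligand = request.ligand_template
    if not any(not a.is_excluded for a in target.atoms):
        raise DockingError("no dockable surface: every target atom is excluded")
    grid = PairGrid(target, ligand, dielectric=request.dielectric)
    rng = np.random.default_rng(np.random.SeedSequence(request.seed))

    t_xyz = grid.target_coords
    lo = t_xyz.min(axis=0) - request.box_margin
    hi = t_xyz.max(axis=0) + request.box_margin
    local = ligand.coords() - ligand.coords().mean(axis=0)

    B = request.n_runs
    centers = rng.uniform(lo, hi, size=(B, 3))
    rots = Rotation.random(B, random_state=np.random.RandomState(
        int(np.random.SeedSequence(request.seed).generate_state(1)[0]) % (2**32 - 1)
    )).as_matrix()

    coords = _place(local, rots, centers)
    e_c, e_lj = grid.energies(coords)
    energy = e_c + e_lj
    best_energy = energy.copy()
    best_centers = centers.copy()
    best_rots = rots.copy()

    kT = max(request.temperature, 1e-9)
    rot_sigma = np.deg2rad(request.rotation_step)
    for _ in range(request.n_steps):
        trial_centers = centers + rng.normal(0.0, request.translation_step, size=(B, 3))
        np.clip(trial_centers, lo, hi, out=trial_centers)
        dr = Rotation.from_rotvec(rng.normal(0.0, rot_sigma, size=(B, 3))).as_matrix()
        trial_rots = np.einsum("bij,bjk->bik", dr, rots)
        trial_coords = _place(local, trial_rots, trial_centers)
        te_c, te_lj = grid.energies(trial_coords)
        trial_energy = te_c + te_lj
        accept = rng.random(B) < np.exp(np.minimum((energy - trial_energy) / kT, 0.0))
        centers[accept] = trial_centers[accept]
        rots[accept] = trial_rots[accept]
        energy[accept] = trial_energy[accept]
        improved = energy < best_energy
        best_energy[improved] = energy[improved]
        best_centers[improved] = centers[improved]
        best_rots[improved] = rots[improved]

    best_coords = _place(local, best_rots, best_centers)
    e_c, e_lj = grid.energies(best_coords)
    poses = []
    for b in range(B):
        poses.append(
            LigandPose(
                template=ligand,
                coords=best_coords[b],
                e=EnergyBreakdown(e_coulomb=float(e_c[b]), e_lj=float(e_lj[b])),
                cycle=request.cycle,
                run_id=b,
                seed=request.seed,
            )
        )
    return poses


# ---------------------------------------------------------------------------
# Clustering and ranking
# ---------------------------------------------------------------------------

_RANK_KEYS = {
    "e_inter": lambda e: e.e_inter,
    "e_lj": lambda e: e.e_lj,
    "e_lj+e_coulomb": lambda e: e.e_lj + e.e_coulomb,
}


def _pose_rmsd(a: LigandPose, b: LigandPose) -> float:
    # poses share the target frame and template atom order: no alignment
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def cluster_poses(poses: Sequence[LigandPose], rmsd_tol: float = 2.0) -> list[LigandPose]:
    """Energy-ordered greedy clustering; mutates and returns the poses.

    Poses are visited by ascending ``e_inter``; each joins the first cluster
    whose representative (its lowest-energy member) lies within *rmsd_tol*,
    else opens a new cluster.  Representatives get ``is_representative``.
    """
    for p in poses:
        if p.e is None:
            raise DockingError("cannot cluster unscored poses")
        p.cluster_id = None
        p.is_representative = False
    order = sorted(poses, key=lambda p: (p.e.e_inter, p.cycle, p.run_id))
    reps: list[LigandPose] = []
    for p in order:
        for cid, rep in enumerate(reps):
            if _pose_rmsd(p, rep) <= rmsd_tol:
                p.cluster_id = cid
                break
        else:
            p.cluster_id = len(reps)
            p.is_representative = True
            reps.append(p)
    return list(poses)


def representatives(poses: Sequence[LigandPose]) -> list[LigandPose]:
    reps = [p for p in poses if p.is_representative]
    return sorted(reps, key=lambda p: p.e.e_inter)


def rank_poses(poses: Sequence[LigandPose], key: str = "e_inter") -> list[LigandPose]:
    """Assign 1-based ranks by ascending *key*; ties break on (cycle, run_id).

    Rank 1 is the strongest (lowest-energy) pose.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; choose from {sorted(_RANK_KEYS)}")
    fn = _RANK_KEYS[key]
    for p in poses:
        if p.e is None:
            raise DockingError("cannot rank unscored poses")
    order = sorted(poses, key=lambda p: (fn(p.e), p.cycle, p.run_id))
    for i, p in enumerate(order, start=1):
        p.rank = i
    return list(poses)
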