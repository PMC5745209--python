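"""Deterministic synthetic test beds with designed ground truth.

Toy targets are solid pseudo-atom balls (cubic lattice, carbon typing) with
pocket cavities carved into the surface; the cavity lining is re-typed to
oxygen and charged so that the interaction-energy minimum for the companion
ligand matches a requested well depth.  Toy ligands are small rigid
pseudo-atom bodies with a nominal molecular weight that drives the
annealing schedules.  Labelled trajectories place "stayer" copies jittering
in place and "leaver" copies drifting off the surface, giving the filter
cascade a ground truth to recover.  Every generator is a pure function of
its seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from .dockkit import LigandPose
from .errors import WnsError
from .forcefield import EnergyBreakdown, PairGrid
from .structio import AtomRecord, ParameterTable, Structure, TrajectorySeries
from .wrapper import MonolayerComplex

#: Fixed, well-separated pocket axes (unit vectors) for up to six pockets.
_POCKET_AXES = np.array([
    [0.0, 0.0, 1.0],
    [0.0, 0.0, -1.0],
    [1.0, 0.0, 0.0],
    [-1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
    [0.0, -1.0, 0.0],
])


def _atom(serial: int, name: str, xyz, atom_type: str, charge: float,
          table: ParameterTable, resid: int | None = None,
          chain: str = "A") -> AtomRecord:
    lj_R, lj_eps = table.lookup(atom_type)
    return AtomRecord(
        serial=serial, name=name, coords=np.asarray(xyz, dtype=float),
        atom_type=atom_type, charge=charge, lj_R=lj_R, lj_eps=lj_eps,
        resname="TOY", resid=resid if resid is not None else serial, chain=chain,
    )


def make_toy_ligand(
    n_atoms: int = 4,
    mw_target: float = 120.0,
    seed: int = 0,
    charge_total: float = 0.6,
    table: ParameterTable | None = None,
) -> Structure:
    """A rigid pseudo-ligand of 1-10 atoms around a central carbon.

    Satellite atoms sit 1.4 Å from the centre on deterministic tetrahedral
    (then octahedral) directions; the second atom is an oxygen, the rest
    carbons.  ``meta["mw"]`` records the nominal molecular weight that the
    annealing scheduler consumes.
    """
    if not 1 <= n_atoms <= 10:
        raise WnsError("toy ligands have 1-10 atoms")
    if mw_target <= 0:
        raise WnsError("mw_target must be positive")
    table = table or ParameterTable.default()
    dirs = np.array([
        [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
        [1, 1, -1], [-1, -1, -1], [1, -1, 1], [-1, 1, 1], [2, 0, 0],
    ], dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    q = charge_total / n_atoms
    atoms = [_atom(1, "C1", [0.0, 0.0, 0.0], "C", q, table, chain="L")]
    for i in range(1, n_atoms):
        t = "O" if i == 1 else "C"
        atoms.append(
            _atom(i + 1, f"{t}{i + 1}", 1.4 * dirs[i - 1], t, q, table, chain="L")
        )
    s = Structure(atoms, label="toy-ligand", meta={"mw": float(mw_target)})
    for a in s.atoms:
        a.resname = "LIG"
        a.resid = 1
    return s


def _pocket_axes(n_pockets: int, rng: np.random.Generator) -> np.ndarray:
    if n_pockets <= len(_POCKET_AXES):
        return _POCKET_AXES[:n_pockets].copy()
    axes = [v for v in _POCKET_AXES]
    for _ in range(200):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.dot(v, u) < 0.5 for u in axes):
            axes.append(v)
            if len(axes) == n_pockets:
                return np.array(axes)
    raise WnsError("could not place non-overlapping pockets")


def make_toy_target(
    n_pockets: int = 2,
    depths=(-10.0, -5.0),
    seed: int = 0,
    radius: float = 10.0,
    spacing: float = 2.2,
    carve_radius: float = 4.6,
    ligand: Structure | None = None,
    table: ParameterTable | None = None,
) -> tuple[Structure, list[np.ndarray]]:
    """A solid pseudo-atom ball with charged pocket cavities of set depth.

    Returns the target and the ground-truth pocket centres.  For each
    pocket a cavity is carved near the surface, the lining atoms become
    charged oxygens, and the lining charge is solved (the Coulomb part is
    linear in it) so the companion ligand's interaction-energy minimum in
    the cavity approximates the requested depth; the generator verifies the
    achieved depth on a local grid and is deterministic per seed.
    """
    if n_pockets < 1:
        raise WnsError("need at least one pocket")
    depths = [float(d) for d in depths]
    if len(depths) != n_pockets:
        raise WnsError("one depth per pocket required")
    if any(d >= 0 for d in depths):
        raise WnsError("pocket depths are negative energies (kcal/mol)")
    table = table or ParameterTable.default()
    ligand = ligand or make_toy_ligand(table=table)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    axes = _pocket_axes(n_pockets, rng)

    k = int(np.ceil(radius / spacing))
    pts = []
    for ix, iy, iz in itertools.product(range(-k, k + 1), repeat=3):
        p = np.array([ix, iy, iz], dtype=float) * spacing
        if np.linalg.norm(p) <= radius:
            pts.append(p)
    pts = np.array(pts)
    pts = pts + rng.normal(0.0, 0.08, size=pts.shape)   # break lattice symmetry

    centers = [(radius - 2.0) * u for u in axes]
    keep = np.ones(len(pts), dtype=bool)
    lining = np.zeros(len(pts), dtype=int) - 1
    for pk, c in enumerate(centers):
        d = np.linalg.norm(pts - c, axis=1)
        keep &= d >= carve_radius
        lining[(d >= carve_radius) & (d < carve_radius + spacing)] = pk

    atoms: list[AtomRecord] = []
    lining_idx: dict[int, list[int]] = {pk: [] for pk in range(n_pockets)}
    serial = 0
    for i in np.flatnonzero(keep):
        serial += 1
        pk = lining[i]
        t = "O" if pk >= 0 else "C"
        atoms.append(_atom(serial, f"{t}{serial}", pts[i], t, 0.0, table))
        if pk >= 0:
            lining_idx[pk].append(serial - 1)
    target = Structure(atoms, label="toy-target")

    # Solve the lining charges so each pocket's local energy minimum hits
    # its requested depth.  The Coulomb term is linear in the per-pocket
    # lining charge, but every pocket's lining also contributes a monopole
    # background at the other pockets, so all charges are solved jointly by
    # Gauss-Seidel sweeps over the pockets, re-locating each local argmin as
    # the charges move.  A charge may come out positive when the bare LJ
    # well is already deeper than asked.
    lig_local = ligand.coords() - ligand.coords().mean(axis=0)
    span = np.arange(-1.5, 1.51, 0.25)
    offsets = np.array([[x, y, z] for x in span for y in span for z in span])
    for pk in range(n_pockets):
        if not lining_idx[pk]:
            raise WnsError("pocket cavity has no lining atoms; adjust geometry")
    coords_pk = [
        lig_local[None, :, :] + (c[None, :] + offsets)[:, None, :] for c in centers
    ]
    zero = PairGrid(target, ligand)
    e_lj_pk = [zero.energies(coords)[1] for coords in coords_pk]
    # unit Coulomb response: pocket pj's lining at -1 e, everything else 0
    e_unit = np.empty((n_pockets, n_pockets), dtype=object)
    for pj in range(n_pockets):
        probe = target.copy()
        for a in probe.atoms:
            a.charge = 0.0
        for j in lining_idx[pj]:
            probe.atoms[j].charge = -1.0
        gridj = PairGrid(probe, ligand)
        for pk in range(n_pockets):
            e_unit[pk, pj] = gridj.energies(coords_pk[pk])[0]
    q = np.zeros(n_pockets)
    for _ in range(12):
        moved = 0.0
        for pk in range(n_pockets):
            total = e_lj_pk[pk] + sum(q[pj] * e_unit[pk, pj] for pj in range(n_pockets))
            p_star = int(np.argmin(total))
            own = e_unit[pk, pk][p_star]
            if abs(own) < 1e-9:
                continue
            background = total[p_star] - q[pk] * own
            q_new = (depths[pk] - (background - 0.0)) / own
            moved = max(moved, abs(q_new - q[pk]))
            q[pk] = q_new
        if moved < 1e-5:
            break
    for pk in range(n_pockets):
        for j in lining_idx[pk]:
            target.atoms[j].charge = -q[pk]                # lining carries -q each
            target.atoms[j].base_charge = -q[pk]
    return target, [np.asarray(c) for c in centers]


def surface_sites(
    target: Structure,
    ligand: Structure,
    directions: np.ndarray,
    t_range=(6.0, 18.0),
    t_step: float = 0.25,
) -> list[np.ndarray]:
    """Energy-minimal contact positions along given outward directions.

    For each unit direction the ligand centroid is scanned radially and the
    lowest-energy placement returned — a cheap way to seat copies on flat
    surface patches.
    """
    grid = PairGrid(target, ligand)
    local = ligand.coords() - ligand.coords().mean(axis=0)
    ts = np.arange(*t_range, t_step)
    sites = []
    for u in np.atleast_2d(directions):
        u = u / np.linalg.norm(u)
        pos = ts[:, None] * u[None, :]
        e_c, e_lj = grid.energies(local[None, :, :] + pos[:, None, :])
        sites.append(pos[int(np.argmin(e_c + e_lj))])
    return sites


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def make_mixed_complex(
    n_deep: int = 6,
    n_flat: int = 18,
    depth: float = -10.0,
    seed: int = 0,
    table: ParameterTable | None = None,
) -> tuple[MonolayerComplex, dict[int, str]]:
    """A wrapped complex with copies in deep pockets and on flat surface.

    One copy sits at each of *n_deep* pocket minima ("stay" ground truth)
    and *n_flat* copies rest on bare surface patches away from the pockets
    ("leave" ground truth).  Returns the complex and the copy-id label map.
    """
    table = table or ParameterTable.default()
    ligand = make_toy_ligand(table=table)
    target, centers = make_toy_target(
        n_pockets=n_deep, depths=[depth] * n_deep, seed=seed,
        ligand=ligand, table=table,
    )
    grid = PairGrid(target, ligand)
    local = ligand.coords() - ligand.coords().mean(axis=0)
    copies: list[LigandPose] = []
    labels: dict[int, str] = {}

    span = np.arange(-1.5, 1.51, 0.25)
    offsets = np.array([[x, y, z] for x in span for y in span for z in span])
    for c in centers:
        pos = c[None, :] + offsets
        e_c, e_lj = grid.energies(local[None, :, :] + pos[:, None, :])
        best = pos[int(np.argmin(e_c + e_lj))]
        copies.append(LigandPose(template=ligand, coords=local + best))

    dirs = _fibonacci_directions(max(n_flat * 8, 64))
    axes = _POCKET_AXES[:n_deep]
    flat_dirs = [u for u in dirs if np.max(axes @ u) < 0.8]
    candidates = surface_sites(target, ligand, np.array(flat_dirs))
    taken = [p.centroid() for p in copies]
    placed = 0
    for site in candidates:
        if placed == n_flat:
            break
        if taken and np.min(np.linalg.norm(np.array(taken) - site, axis=1)) < 4.5:
            continue
        copies.append(LigandPose(template=ligand, coords=local + site))
        taken.append(site)
        placed += 1
    if placed < n_flat:
        raise WnsError("not enough separated flat surface sites; reduce n_flat")

    for i, p in enumerate(copies, start=1):
        p.copy_id = i
        labels[i] = "stay" if i <= n_deep else "leave"
        e_c, e_lj = grid.energies(p.coords)
        p.e = EnergyBreakdown(e_coulomb=float(e_c), e_lj=float(e_lj))
    cmplx = MonolayerComplex(target=target, copies=copies)
    return cmplx, labels


def make_labeled_trajectory(
    complex_: MonolayerComplex,
    stay_ids: set[int],
    leave_ids: set[int],
    seed: int = 0,
    n_frames: int = 50,
    jitter: float = 0.2,
    leave_distance: float = 14.0,
) -> tuple[TrajectorySeries, dict[int, str]]:
    """A synthetic trajectory with known stay/dissociate ground truth.

    Stayers jitter rigidly around their start (net displacement < 1 Å);
    leavers drift linearly outward to beyond *leave_distance* with the same
    jitter on top.  Returns the trajectory and the label map.
    """
    ids = {p.copy_id for p in complex_.copies}
    if (stay_ids | leave_ids) - ids:
        raise WnsError("labels reference unknown copy ids")
    if stay_ids & leave_ids:
        raise WnsError("a copy cannot both stay and leave")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB]))
    t_center = complex_.target.coords().mean(axis=0)

    atoms = []
    copy_atoms: dict[int, np.ndarray] = {}
    serial = 0
    frames = np.zeros((n_frames, sum(len(p.template.atoms) for p in complex_.copies), 3))
    for p in complex_.copies:
        idx = np.arange(serial, serial + len(p.template.atoms))
        copy_atoms[p.copy_id] = idx
        for a, xyz in zip(p.template.atoms, p.coords):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, name=a.name, coords=np.asarray(xyz, dtype=float),
                    atom_type=a.atom_type, charge=a.charge, lj_R=a.lj_R,
                    lj_eps=a.lj_eps, resname="LIG", resid=p.copy_id, chain="L",
                )
            )
        out = p.centroid() - t_center
        out = out / np.linalg.norm(out)
        for f in range(n_frames):
            wobble = rng.normal(0.0, jitter, size=3)
            norm = np.linalg.norm(wobble)
            if norm > 0.9:
                wobble *= 0.9 / norm
            drift = np.zeros(3)
            if p.copy_id in leave_ids:
                drift = out * (leave_distance * f / max(n_frames - 1, 1))
            frames[f, idx, :] = p.coords + wobble + drift
    labels = {i: ("stay" if i in stay_ids else "leave" if i in leave_ids else "unlabeled")
              for i in ids}
    traj = TrajectorySeries(
        coords=frames, atoms=atoms, copy_atoms=copy_atoms,
        remarks=[f"LABELED FIXTURE SEED {seed}"],
    )
    return traj, labels
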