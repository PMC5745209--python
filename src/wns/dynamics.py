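"""Toy shaking engine: rigid-body Langevin dynamics with annealing schedules.

Each ligand copy is an overdamped rigid body: its centre feels the analytic
Lennard-Jones + Coulomb force from the target plus Gaussian thermal noise,
and its orientation performs small diffusive rotations (no torque
integration).  The temperature follows a triangular simulated-annealing
profile from the base temperature up to the schedule ceiling and back.
Target atoms are immobile for the backbone-restrained phases and
harmonically tethered (with their own thermal noise) for the fully flexible
refinement phase.  The engine replaces explicit-solvent molecular dynamics
with a Langevin bath: hydration structure is not modelled, and externally
produced multi-model PDB trajectories can be fed to the Shaker instead via
:mod:`wns.structio`.

Annealing ceilings follow the ligand's molecular weight: light ligands
(MW <= 300 g/mol) are shaken up to 50 °C, heavy ones (MW >= 300) up to
80 °C; exactly 300 takes the 50 °C branch (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DynamicsError, WnsError
from .structio import AtomRecord, TrajectorySeries
from .forcefield import PairGrid
from .wrapper import MonolayerComplex

#: Gas constant, kcal/(mol·K).
R_GAS = 0.0019872

PHASES = ("MD_B", "MD_BSA", "MD_F")

#: Nominal trajectory lengths per phase, ns.
PHASE_NS = {"MD_B": 5.0, "MD_BSA": 20.0, "MD_F": 20.0}

PHASE_RESTRAINT = {
    "MD_B": "backbone_restrained",
    "MD_BSA": "backbone_restrained",
    "MD_F": "fully_flexible",
}


@dataclass(frozen=True)
class AnnealSchedule:
    """One annealing phase: ceiling temperature, duration, target restraint."""

    phase: str
    t_max_celsius: float
    duration_steps: int
    restraint: str
    t_base_celsius: float = 27.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.duration_steps <= 0:
            raise ValueError("duration must be positive")
        if self.phase == "MD_BSA" and self.t_max_celsius not in (50.0, 80.0):
            raise ValueError("MD_BSA ceiling must be 50 or 80 °C")


def schedule_for(
    mw: float,
    phase: str,
    steps_per_ns: int = 10_000,
    mw_cutoff: float = 300.0,
    high_temp_at_boundary: bool = False,
) -> AnnealSchedule:
    """Build the annealing schedule for a ligand of molecular weight *mw*.

    MD_BSA ramps to 50 °C for light ligands (mw <= cutoff) and 80 °C for
    heavy ones; MD_B and MD_F run flat at the 27 °C base temperature.
    Durations map the nominal phase lengths (5 ns for MD_B, 20 ns for
    MD_BSA/MD_F) onto toy steps via *steps_per_ns*.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if phase not in PHASES:
        raise WnsError(f"unknown phase {phase!r}; choose from {PHASES}")
    if phase == "MD_BSA":
        light = mw < mw_cutoff or (mw == mw_cutoff and not high_temp_at_boundary)
        t_max = 50.0 if light else 80.0
    else:
        t_max = 27.0
    steps = max(1, int(round(PHASE_NS[phase] * steps_per_ns)))
    return AnnealSchedule(
        phase=phase,
        t_max_celsius=t_max,
        duration_steps=steps,
        restraint="target_fixed" if phase != "MD_F" else "fully_flexible",
    )


@dataclass
class DynamicsParams:
    """Integrator knobs of the toy Langevin engine."""

    dt: float = 0.01                 # toy time unit per step
    gamma: float = 1.0               # translational friction
    gamma_rot: float = 3.0           # rotational friction
    tether_k: float = 10.0           # kcal/(mol·Å²), MD_F target tether
    frame_stride: int | None = None  # None: ~100 frames per run
    noise: bool = True
    dielectric: float = 1.0
    max_step_displacement: float = 2.0   # Å, stability guard
    cc_force_clamp: float = 5.0      # kcal/(mol·Å); copy-copy push ceiling


def _temperature_profile(schedule: AnnealSchedule, n_steps: int) -> np.ndarray:
    """Triangular ramp base -> ceiling -> base, in Kelvin."""
    s = np.arange(n_steps, dtype=float)
    frac = 1.0 - np.abs(2.0 * s / max(n_steps - 1, 1) - 1.0)
    t_c = schedule.t_base_celsius + (schedule.t_max_celsius - schedule.t_base_celsius) * frac
    return t_c + 273.15


def shake(
    complex_: MonolayerComplex,
    schedule: AnnealSchedule,
    seed: int = 0,
    params: DynamicsParams | None = None,
) -> TrajectorySeries:
    """Shake the ligand copies of a wrapped complex; emit a trajectory.

    Deterministic per seed.  Frames contain the ligand-copy atoms only
    (chain L, residue id = copy id); header remarks record the schedule,
    the seed and the integrator settings.
    """
    if complex_.n < 1:
        raise WnsError("complex has no ligand copies to shake")
    params = params or DynamicsParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1]))

    copies = complex_.copies
    template = copies[0].template
    nl = len(template.atoms)
    for p in copies:
        if len(p.template.atoms) != nl:
            raise WnsError("all copies must share one ligand template")

    grid = PairGrid(complex_.target, template, dielectric=params.dielectric)
    target_xyz0 = grid.target_coords.copy()
    target_xyz = target_xyz0.copy()

    C = len(copies)
    centers = np.array([p.centroid() for p in copies])
    locals_ = np.array([p.coords - p.centroid() for p in copies])   # (C, nl, 3)

    n_steps = schedule.duration_steps
    stride = params.frame_stride or max(1, n_steps // 100)
    temps = _temperature_profile(schedule, n_steps)
    mobile_target = schedule.restraint == "fully_flexible"

    # copy-copy excluded volume: repulsive-only (WCA-truncated) LJ between
    # atoms of different copies, so one copy cannot drift into a pocket
    # already occupied by another
    lR = np.array([a.lj_R for a in template.atoms])
    le = np.array([a.lj_eps for a in template.atoms])
    cc_R = (lR[:, None] + lR[None, :]) / 2.0              # (nl, nl)
    cc_eps = np.sqrt(le[:, None] * le[None, :])
    not_self = ~np.eye(C, dtype=bool)

    def copy_copy_forces(coords: np.ndarray) -> np.ndarray:
        if C == 1:
            return np.zeros((1, nl, 3))
        diff = coords[:, None, :, None, :] - coords[None, :, None, :, :]  # (C,C,nl,nl,3)
        r2 = np.maximum(np.sum(diff * diff, axis=-1), 0.01)
        r = np.sqrt(r2)
        x = (cc_R[None, None] / r) ** 6
        dvdr = -12.0 * cc_eps[None, None] * (x * x - x) / r
        dvdr = np.where((r < cc_R[None, None]) & not_self[:, :, None, None], dvdr, 0.0)
        # Clamp well below the target-force clamp: copy-copy contacts must
        # block interpenetration without being able to shove a pocket-bound
        # copy past its anchoring forces.
        np.clip(dvdr, -params.cc_force_clamp, params.cc_force_clamp, out=dvdr)
        return np.sum((-dvdr / r)[..., None] * diff, axis=(1, 3))         # (C, nl, 3)

    frames = [np.concatenate(locals_ + centers[:, None, :], axis=0)]
    for step in range(n_steps):
        kT = R_GAS * temps[step]
        coords = locals_ + centers[:, None, :]
        if mobile_target:
            grid.target_coords = target_xyz
        forces = (grid.forces(coords) + copy_copy_forces(coords)).sum(axis=1)
        dx = forces * (params.dt / params.gamma)
        if params.noise:
            dx = dx + rng.normal(
                0.0, np.sqrt(2.0 * kT * params.dt / params.gamma), size=(C, 3)
            )
        step_len = np.linalg.norm(dx, axis=1)
        if np.any(step_len > params.max_step_displacement):
            raise DynamicsError(
                f"per-step displacement {step_len.max():.2f} Å exceeds "
                f"{params.max_step_displacement} Å; reduce dt or forces"
            )
        centers = centers + dx
        if params.noise:
            rot_sigma = np.sqrt(2.0 * kT * params.dt / params.gamma_rot)
            dr = Rotation.from_rotvec(rng.normal(0.0, rot_sigma, size=(C, 3)))
            locals_ = np.einsum("cij,caj->cai", dr.as_matrix(), locals_)
        if mobile_target:
            dt_g = params.dt / params.gamma
            target_xyz = target_xyz - params.tether_k * (target_xyz - target_xyz0) * dt_g
            if params.noise:
                target_xyz = target_xyz + rng.normal(
                    0.0, np.sqrt(2.0 * kT * dt_g), size=target_xyz.shape
                )
        if (step + 1) % stride == 0 or step == n_steps - 1:
            frames.append(np.concatenate(locals_ + centers[:, None, :], axis=0))
    grid.target_coords = target_xyz0

    atoms: list[AtomRecord] = []
    copy_atoms: dict[int, np.ndarray] = {}
    serial = 0
    for ci, p in enumerate(copies):
        cid = p.copy_id if p.copy_id is not None else ci + 1
        idx = []
        for a in p.template.atoms:
            rec = dc_replace(a, serial=serial + 1, chain="L", resid=cid, resname="LIG",
                             coords=a.coords.copy())
            atoms.append(rec)
            idx.append(serial)
            serial += 1
        copy_atoms[cid] = np.array(idx, dtype=int)

    remarks = [
        f"PHASE {schedule.phase} TMAX {schedule.t_max_celsius:.0f} C "
        f"TBASE {schedule.t_base_celsius:.0f} C RESTRAINT {schedule.restraint}",
        f"STEPS {n_steps} STRIDE {stride} DT {params.dt} GAMMA {params.gamma}",
        f"SEED {seed} NOISE {int(params.noise)}",
    ]
    return TrajectorySeries(
        coords=np.array(frames), atoms=atoms, copy_atoms=copy_atoms, remarks=remarks
    )
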