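"""Shaker: trajectory filtering, washing, exit criterion, final clustering.

Shaking a wrapped complex produces trajectories of the ligand copies; for
every copy and frame the Shaker derives the closest heavy-atom distance to
the target, the Lennard-Jones interaction energy (with the target's
standard, pre-exclusion typing) and the centroid displacement from the
starting pose.  A fixed four-step filter cascade — two distance screens,
then two E_LJ screens — eliminates dissociated copies, whose coordinates
are then removed ("washing").  Annealing cycles repeat until at least 75%
of the initial copies are eliminated (EC_S), after which survivors are
clustered, refined with a fully flexible phase, and ranked by E_LJ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .dockkit import LigandPose, rank_poses
from .dynamics import DynamicsParams, schedule_for, shake
from .errors import WnsError
from .forcefield import EnergyBreakdown, PairGrid
from .structio import ParameterTable, Structure, TrajectorySeries
from .wrapper import MonolayerComplex

log = logging.getLogger(__name__)


@dataclass
class CopyMetrics:
    """Per-frame target-interaction series of one ligand copy."""

    copy_id: int
    min_distance: np.ndarray      # Å, closest heavy-atom pair per frame
    e_lj: np.ndarray              # kcal/mol per frame
    displacement: np.ndarray      # Å, centroid displacement from frame 0

    def __post_init__(self) -> None:
        n = len(self.min_distance)
        if len(self.e_lj) != n or len(self.displacement) != n:
            raise ValueError("metric series lengths must match frame count")


@dataclass
class FilterParams:
    """Thresholds of the four-step elimination cascade."""

    d_diss: float = 4.5        # Å; F1: final-frame min target distance
    d_drift: float = 5.0       # Å; F2: sustained centroid displacement
    e_mean_cap: float = -1.0   # kcal/mol; F3: mean E_LJ over the window
    window_frac: float = 0.2   # trailing fraction of frames for F2/F3


@dataclass
class FilterDecision:
    copy_id: int
    keep: bool
    reason: str | None         # "F1".."F4" for discards


def restore_base_typing(target: Structure, table: ParameterTable | None = None) -> Structure:
    """A copy of *target* with pre-exclusion types, charges and parameters."""
    table = table or ParameterTable.default()
    out = target.copy()
    for a in out.atoms:
        lj_R, lj_eps = table.lookup(a.base_type)
        a.atom_type = a.base_type
        a.charge = a.base_charge
        a.lj_R = lj_R
        a.lj_eps = lj_eps
        a.is_excluded = False
    return out


def compute_metrics(
    traj: TrajectorySeries,
    target: Structure,
    copies: list[int] | None = None,
    table: ParameterTable | None = None,
    dielectric: float = 1.0,
) -> list[CopyMetrics]:
    """Distance, E_LJ and displacement series for each copy in a trajectory.

    E_LJ uses the target's standard (non-excluded) typing regardless of the
    exclusion state the Wrapper left behind.
    """
    base_target = restore_base_typing(target, table)
    t_heavy = base_target.heavy_coords()
    out = []
    wanted = set(copies) if copies is not None else None
    for cid in sorted(traj.copy_atoms):
        if wanted is not None and cid not in wanted:
            continue
        idx = traj.copy_atoms[cid]
        records = [traj.atoms[i] for i in idx]
        sub = Structure([dc_replace(a, serial=k + 1) for k, a in enumerate(records)],
                        label=f"copy{cid}")
        xyz = traj.coords[:, idx, :]                       # (F, nc, 3)
        heavy = sub.heavy_mask()
        diff = xyz[:, heavy, None, :] - t_heavy[None, None, :, :]
        dmin = np.sqrt(np.sum(diff * diff, axis=-1)).min(axis=(1, 2))
        grid = PairGrid(base_target, sub, dielectric=dielectric)
        _, e_lj = grid.energies(xyz)
        centroids = xyz.mean(axis=1)
        disp = np.linalg.norm(centroids - centroids[0], axis=1)
        out.append(CopyMetrics(copy_id=cid, min_distance=dmin, e_lj=np.atleast_1d(e_lj),
                               displacement=disp))
    if not out:
        raise WnsError("trajectory copy map matched no requested copies")
    return out


def apply_filters(
    metrics: list[CopyMetrics],
    params: FilterParams | None = None,
) -> list[FilterDecision]:
    """Run the four-step cascade; each discard records the step that fired.

    F1: dissociated — final-frame min target distance above ``d_diss``.
    F2: drifted — centroid displacement above ``d_drift`` through the whole
    trailing window.  F3: weakly bound — mean E_LJ over the trailing window
    above ``e_mean_cap``.  F4: repulsive — final-frame E_LJ positive.
    """
    if not metrics:
        raise WnsError("no copy metrics to filter")
    params = params or FilterParams()
    out = []
    for m in metrics:
        n = len(m.min_distance)
        w = max(1, int(np.ceil(params.window_frac * n)))
        reason = None
        if m.min_distance[-1] > params.d_diss:
            reason = "F1"
        elif np.all(m.displacement[-w:] > params.d_drift):
            reason = "F2"
        elif float(np.mean(m.e_lj[-w:])) > params.e_mean_cap:
            reason = "F3"
        elif m.e_lj[-1] > 0.0:
            reason = "F4"
        out.append(FilterDecision(copy_id=m.copy_id, keep=reason is None, reason=reason))
    return out


def wash(complex_: MonolayerComplex, discard: set[int]) -> MonolayerComplex:
    """Remove the discarded copies' coordinates; surviving ids are stable."""
    known = {p.copy_id for p in complex_.copies}
    unknown = discard - known
    if unknown:
        raise WnsError(f"unknown copy ids: {sorted(unknown)}")
    complex_.copies = [p for p in complex_.copies if p.copy_id not in discard]
    return complex_


def ec_s_reached(n_initial: int, n_current: int, threshold: float = 0.75) -> bool:
    """True once the eliminated fraction reaches *threshold* (default 75%)."""
    if n_initial < 1:
        raise WnsError("n_initial must be >= 1")
    if n_current > n_initial:
        raise WnsError("current copy count exceeds the initial count")
    return (n_initial - n_current) / n_initial >= threshold


@dataclass(frozen=True)
class SRValue:
    """Shaker Rate N/n: wrapped copies per final cluster representative."""

    N: int
    n: int

    @property
    def raw(self) -> float | None:
        return None if self.n == 0 else self.N / self.n

    @property
    def rounded(self) -> int | None:
        # report convention: nearest integer, halves away from zero
        return None if self.n == 0 else int(np.floor(self.N / self.n + 0.5))

    @property
    def display(self) -> str:
        return f"{self.N}/0" if self.n == 0 else f"{self.rounded}"


def shaker_rate(N: int, n: int) -> SRValue:
    """SR = N/n; undefined (``"N/0"`` sentinel) when no representative survives."""
    if n < 0 or N < 0:
        raise WnsError("counts must be non-negative")
    return SRValue(N=N, n=n)


# ---------------------------------------------------------------------------
# Final clustering
# ---------------------------------------------------------------------------

def cluster_final(
    poses: list[LigandPose],
    dist_limit: float = 3.5,
    metric: str = "centroid",
) -> list[LigandPose]:
    """Greedy energy-ordered clustering of survivor poses; returns reps.

    Poses are visited by ascending E_LJ; each joins the first cluster whose
    representative lies within *dist_limit* (centroid distance by default,
    pose RMSD with ``metric="rmsd"``), else opens a new cluster.  A 6 Å
    limit is the wide-pocket variant.
    """
    if metric not in ("centroid", "rmsd"):
        raise ValueError(f"unknown cluster metric {metric!r}")
    for p in poses:
        if p.e is None:
            raise WnsError("cannot cluster unscored poses")
        p.cluster_id = None
        p.is_representative = False
    order = sorted(poses, key=lambda p: (p.e.e_lj, p.cycle, p.run_id))
    reps: list[LigandPose] = []
    for p in order:
        for cid, rep in enumerate(reps):
            if metric == "centroid":
                d = float(np.linalg.norm(p.centroid() - rep.centroid()))
            else:
                d = float(np.sqrt(np.mean(np.sum((p.coords - rep.coords) ** 2, axis=-1))))
            if d <= dist_limit:
                p.cluster_id = cid
                break
        else:
            p.cluster_id = len(reps)
            p.is_representative = True
            reps.append(p)
    return reps


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ShakerConfig:
    filters: FilterParams = field(default_factory=FilterParams)
    ec_s_threshold: float = 0.75
    max_bsa_cycles: int = 10
    cluster_dist_limit: float = 3.5
    cluster_metric: str = "centroid"
    final_rank_key: str = "e_lj"       # or "e_lj+e_coulomb"
    skip_md_b: bool = False
    skip_md_bsa: bool = False
    run_md_f: bool = True
    steps_per_ns: int = 10_000
    mw_cutoff: float = 300.0
    high_temp_at_boundary: bool = False
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)


@dataclass
class StageLog:
    stage: str
    n_before: int
    n_after: int
    reasons: dict[str, int]


@dataclass
class ShakerResult:
    survivors: list[LigandPose]
    n: int
    N_initial: int
    sr: SRValue
    cycles_run: int
    ranks: dict[int, int]
    casualty_log: list[StageLog]
    ec_s_met: bool
    protocol_complete: bool


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, 0x5A, stage]).generate_state(1)[0] % (2**31))


def _ligand_mw(complex_: MonolayerComplex, default: float = 100.0) -> float:
    if complex_.copies:
        return float(complex_.copies[0].template.meta.get("mw", default))
    return default


def _score_pose(p: LigandPose, grid: PairGrid) -> None:
    e_c, e_lj = grid.energies(p.coords)
    p.e = EnergyBreakdown(e_coulomb=float(e_c), e_lj=float(e_lj))


def run_shaker(
    complex_: MonolayerComplex,
    config: ShakerConfig | None = None,
    seed: int = 0,
    dynamics_backend=shake,
    table: ParameterTable | None = None,
) -> ShakerResult:
    """Run the full shaking protocol on a wrapped complex.

    One restrained phase (MD_B analog) first, then annealing cycles
    (MD_BSA analog, ceiling from the ligand MW) until EC_S or the cycle
    guard; survivors keep their last-frame conformations, get clustered,
    refined with a fully flexible phase (MD_F analog) and ranked by E_LJ
    (or E_LJ + E_Coulomb via config).  Skipping the restrained phases is
    allowed but flags the result protocol-incomplete.
    """
    config = config or ShakerConfig()
    if complex_.n < 1:
        raise WnsError("complex has no ligand copies")
    N_initial = complex_.n
    for i, p in enumerate(complex_.copies, start=1):
        if p.copy_id is None:
            p.copy_id = i
    mw = _ligand_mw(complex_)
    base_target = restore_base_typing(complex_.target, table)
    casualty_log: list[StageLog] = []
    stage_counter = 0

    def run_stage(stage_name: str, phase: str) -> None:
        nonlocal stage_counter
        stage_counter += 1
        schedule = schedule_for(
            mw, phase, steps_per_ns=config.steps_per_ns,
            mw_cutoff=config.mw_cutoff,
            high_temp_at_boundary=config.high_temp_at_boundary,
        )
        traj = dynamics_backend(
            complex_, schedule, seed=_stage_seed(seed, stage_counter),
            params=config.dynamics,
        )
        metrics = compute_metrics(traj, complex_.target, table=table)
        decisions = apply_filters(metrics, config.filters)
        discard = {d.copy_id for d in decisions if not d.keep}
        reasons: dict[str, int] = {}
        for d in decisions:
            if d.reason:
                reasons[d.reason] = reasons.get(d.reason, 0) + 1
        # survivors adopt their last-frame conformations
        last = traj.coords[-1]
        for p in complex_.copies:
            if p.copy_id in traj.copy_atoms:
                p.coords = last[traj.copy_atoms[p.copy_id]].copy()
        n_before = complex_.n
        wash(complex_, discard)
        casualty_log.append(
            StageLog(stage=stage_name, n_before=n_before, n_after=complex_.n,
                     reasons=reasons)
        )

    if not config.skip_md_b:
        run_stage("MD_B", "MD_B")

    bsa_cycles = 0
    if not config.skip_md_bsa:
        while (
            complex_.n > 0
            and not ec_s_reached(N_initial, complex_.n, config.ec_s_threshold)
            and bsa_cycles < config.max_bsa_cycles
        ):
            bsa_cycles += 1
            run_stage(f"MD_BSA:{bsa_cycles}", "MD_BSA")

    ec_s = complex_.n == 0 or ec_s_reached(N_initial, complex_.n, config.ec_s_threshold)

    if complex_.n == 0:
        warnings.warn("no ligand copy survived shaking; SR undefined")
        return ShakerResult(
            survivors=[], n=0, N_initial=N_initial, sr=shaker_rate(N_initial, 0),
            cycles_run=bsa_cycles, ranks={}, casualty_log=casualty_log,
            ec_s_met=ec_s,
            protocol_complete=not (config.skip_md_b or config.skip_md_bsa),
        )

    grid = PairGrid(base_target, complex_.copies[0].template)
    for p in complex_.copies:
        _score_pose(p, grid)
    reps = cluster_final(
        complex_.copies, dist_limit=config.cluster_dist_limit,
        metric=config.cluster_metric,
    )

    if config.run_md_f and reps:
        refine = MonolayerComplex(
            target=complex_.target, copies=reps,
            cycle_log=complex_.cycle_log, initial_asa=complex_.initial_asa,
        )
        stage_counter += 1
        schedule = schedule_for(
            mw, "MD_F", steps_per_ns=config.steps_per_ns,
            mw_cutoff=config.mw_cutoff,
            high_temp_at_boundary=config.high_temp_at_boundary,
        )
        traj = dynamics_backend(
            refine, schedule, seed=_stage_seed(seed, stage_counter),
            params=config.dynamics,
        )
        last = traj.coords[-1]
        for p in reps:
            if p.copy_id in traj.copy_atoms:
                p.coords = last[traj.copy_atoms[p.copy_id]].copy()
            _score_pose(p, grid)

    rank_poses(reps, key=config.final_rank_key)
    ranks = {p.copy_id: p.rank for p in reps}
    n = len(reps)
    return ShakerResult(
        survivors=sorted(reps, key=lambda p: p.rank),
        n=n,
        N_initial=N_initial,
        sr=shaker_rate(N_initial, n),
        cycles_run=bsa_cycles,
        ranks=ranks,
        casualty_log=casualty_log,
        ec_s_met=ec_s,
        protocol_complete=not (config.skip_md_b or config.skip_md_bsa),
    )


def report_table(result: ShakerResult) -> str:
    """Survivor report as a tab-separated table plus a summary line."""
    lines = ["copy_id\trank\te_lj\te_inter"]
    for p in result.survivors:
        lines.append(f"{p.copy_id}\t{p.rank}\t{p.e.e_lj:.3f}\t{p.e.e_inter:.3f}")
    lines.append(
        f"# N={result.N_initial} n={result.n} SR={result.sr.display} "
        f"cycles={result.cycles_run} ec_s={result.ec_s_met} "
        f"protocol={'complete' if result.protocol_complete else 'protocol-incomplete'}"
    )
    return "\n".join(lines)
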