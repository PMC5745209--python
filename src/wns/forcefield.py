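"""Pairwise intermolecular energetics and excluded-atom-type calibration.

The interaction energy between a target and a ligand is the sum of a
Coulomb term, a 12-6 Lennard-Jones term and a pluggable solvation term::

    E_inter = E_Coulomb + E_LJ + dG_sol

with the 12-6 form V(r) = eps_ij * [(R_ij/r)^12 - 2 (R_ij/r)^6], geometric-
mean combining for the well depth and arithmetic-mean combining for the
pair distance.  Raw (unscaled) 12-6 values are used throughout: the
excluded-type calibration arithmetic below only reproduces the ~1 kcal/mol
short-range cap when no van-der-Waals weighting is applied.  Electrostatics
use a constant dielectric (default 1); the solvation term defaults to zero
and accepts any user callable.

The excluded atom type ``"X"`` marks target atoms already buried under
docked ligand copies.  Its well depth is tiny (1e-4 kcal/mol) and its pair
distance R_X is calibrated so the X-Y repulsion reaches a chosen cap
(~1 kcal/mol) at r = 2 Å — roughly a covalent bond plus 0.5 Å — and decays
to nothing just beyond, so new ligand copies are pushed off covered surface
without creating wide ligand-free zones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterLookupError
from .structio import EXCLUDED_TYPE, ParameterTable, Structure

log = logging.getLogger(__name__)

#: Electrostatic conversion constant, kcal·Å/(mol·e²).
COULOMB_K = 332.0637

#: Pair distances below this are clamped to keep clash energies finite, Å.
CLASH_CLAMP = 0.1


@dataclass(frozen=True)
class PairParams:
    """Combined Lennard-Jones parameters of one atom-type pair."""

    eps_ij: float   # kcal/mol
    R_ij: float     # Å

    def __post_init__(self) -> None:
        if self.eps_ij < 0:
            raise ValueError("eps_ij must be non-negative")
        if self.R_ij <= 0:
            raise ValueError("R_ij must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Additive decomposition of the intermolecular interaction energy."""

    e_coulomb: float
    e_lj: float
    dg_sol: float = 0.0

    @property
    def e_inter(self) -> float:
        return self.e_coulomb + self.e_lj + self.dg_sol


@dataclass
class CalibrationResult:
    """Solved excluded-type parameters and the scenario curves behind them."""

    eps_X: float
    R_X_per_Y: dict[str, float]
    R_X_mean: float
    #: scenario name -> (Y type, R_X used, r grid, V_XY(r) samples)
    scenario_curves: dict[str, tuple[str, float, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


def combine(a: tuple[float, float], b: tuple[float, float]) -> PairParams:
    """Combine two per-type ``(Rii, epsii)`` entries into pair parameters.

    Geometric mean for the well depth, arithmetic mean for the pair distance
    (the AutoDock convention).
    """
    (Ra, ea), (Rb, eb) = a, b
    return PairParams(eps_ij=float(np.sqrt(ea * eb)), R_ij=(Ra + Rb) / 2.0)


def combine_types(table: ParameterTable, type_a: str, type_b: str) -> PairParams:
    return combine(table.lookup(type_a), table.lookup(type_b))


def lj_pair(r, p: PairParams):
    """12-6 Lennard-Jones energy at separation *r* (Å), kcal/mol.

    Accepts scalars or arrays; the minimum is exactly ``-eps_ij`` at
    ``r == R_ij``.  Separations below the clash clamp are evaluated at the
    clamp distance.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    r = np.maximum(r, CLASH_CLAMP)
    x = (p.R_ij / r) ** 6
    v = p.eps_ij * (x * x - 2.0 * x)
    return float(v) if v.ndim == 0 else v


def coulomb_pair(r, q1: float, q2: float, dielectric: float = 1.0):
    """Coulomb energy of two point charges at separation *r* (Å), kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    r = np.maximum(r, CLASH_CLAMP)
    v = COULOMB_K * q1 * q2 / (dielectric * r)
    return float(v) if v.ndim == 0 else v


# ---------------------------------------------------------------------------
# Structure-level energies
# ---------------------------------------------------------------------------

class PairGrid:
    """Precomputed per-pair parameter arrays for one target/ligand pairing.

    Docking and dynamics evaluate the same target against thousands of
    ligand placements; caching eps_ij, R_ij and charge products as
    (n_target, n_ligand) arrays makes each evaluation a few vectorised
    numpy expressions.
    """

    def __init__(
        self,
        target: Structure,
        ligand: Structure,
        dielectric: float = 1.0,
        use_base_types: bool = False,
        table: ParameterTable | None = None,
    ):
        if not target.atoms or not ligand.atoms:
            raise ValueError("both structures must be non-empty")
        self.dielectric = float(dielectric)
        self.target_coords = target.coords()
        if use_base_types:
            table = table or ParameterTable.default()
            t_params = [table.lookup(a.base_type) for a in target.atoms]
            t_charge = np.array([a.base_charge for a in target.atoms])
        else:
            t_params = [(a.lj_R, a.lj_eps) for a in target.atoms]
            t_charge = np.array([a.charge for a in target.atoms])
        l_params = [(a.lj_R, a.lj_eps) for a in ligand.atoms]
        l_charge = np.array([a.charge for a in ligand.atoms])
        tR = np.array([p[0] for p in t_params])[:, None]
        te = np.array([p[1] for p in t_params])[:, None]
        lR = np.array([p[0] for p in l_params])[None, :]
        le = np.array([p[1] for p in l_params])[None, :]
        self.eps_ij = np.sqrt(te * le)                    # (nt, nl)
        self.R_ij = (tR + lR) / 2.0
        self.qq = COULOMB_K * t_charge[:, None] * l_charge[None, :] / self.dielectric

    def distances(self, ligand_coords: np.ndarray) -> np.ndarray:
        """Pairwise distances; ligand_coords is (..., nl, 3)."""
        diff = self.target_coords[:, None, :] - ligand_coords[..., None, :, :]
        return np.sqrt(np.maximum(np.sum(diff * diff, axis=-1), CLASH_CLAMP**2))

    def energies(self, ligand_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(e_coulomb, e_lj) summed over pairs, for one or many placements.

        *ligand_coords* is (nl, 3) or (batch..., nl, 3); the returned arrays
        drop the pair axes.
        """
        r = self.distances(ligand_coords)                 # (..., nt, nl)
        x = (self.R_ij / r) ** 6
        e_lj = np.sum(self.eps_ij * (x * x - 2.0 * x), axis=(-2, -1))
        e_c = np.sum(self.qq / r, axis=(-2, -1))
        return e_c, e_lj

    #: per-pair force-magnitude clamp, kcal/(mol·Å); keeps clash forces finite
    FORCE_CLAMP = 50.0

    def forces(self, ligand_coords: np.ndarray) -> np.ndarray:
        """Analytic force on each ligand atom, kcal/(mol·Å); (..., nl, 3).

        Per-pair force magnitudes are clamped (like the clash-distance
        clamp on energies) so transient overlaps stay integrable.
        """
        diff = ligand_coords[..., None, :, :] - self.target_coords[:, None, :]  # (...,nt,nl,3)
        r2 = np.maximum(np.sum(diff * diff, axis=-1), CLASH_CLAMP**2)
        r = np.sqrt(r2)
        x = (self.R_ij / r) ** 6
        # dV/dr for LJ is -12 eps (x^2 - x)/r; Coulomb contributes -qq/r^2.
        dvdr = -12.0 * self.eps_ij * (x * x - x) / r - self.qq / r2
        np.clip(dvdr, -self.FORCE_CLAMP, self.FORCE_CLAMP, out=dvdr)
        return np.sum((-dvdr / r)[..., None] * diff, axis=-3)


def intermolecular_energy(
    target: Structure,
    ligand: Structure,
    cutoff: float = 16.0,
    dielectric: float = 1.0,
    solvation=None,
) -> EnergyBreakdown:
    """Total target-ligand interaction energy with its decomposition.

    Sums Coulomb and 12-6 LJ over all pairs within *cutoff*; excluded target
    atoms (type ``"X"``) enter with zero charge and the calibrated X
    parameters (both already stored on the atoms).  ``solvation`` is an
    optional callable ``(target, ligand) -> kcal/mol`` providing the
    desolvation term; the default contributes zero.  Pairs closer than
    0.1 Å are evaluated at 0.1 Å (finite, logged).
    """
    if not target.atoms or not ligand.atoms:
        raise ValueError("both structures must be non-empty")
    t_xyz = target.coords()
    l_xyz = ligand.coords()
    diff = t_xyz[:, None, :] - l_xyz[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r < CLASH_CLAMP):
        log.warning(
            "clashing atom pair at r < %.1f Å; energy clamped", CLASH_CLAMP
        )
    within = r <= cutoff
    r = np.maximum(r, CLASH_CLAMP)
    t_charge = np.array([a.charge for a in target.atoms])
    l_charge = np.array([a.charge for a in ligand.atoms])
    tR = np.array([a.lj_R for a in target.atoms])[:, None]
    te = np.array([a.lj_eps for a in target.atoms])[:, None]
    lR = np.array([a.lj_R for a in ligand.atoms])[None, :]
    le = np.array([a.lj_eps for a in ligand.atoms])[None, :]
    eps_ij = np.sqrt(te * le)
    R_ij = (tR + lR) / 2.0
    x = (R_ij / r) ** 6
    e_lj = float(np.sum(np.where(within, eps_ij * (x * x - 2.0 * x), 0.0)))
    qq = COULOMB_K * t_charge[:, None] * l_charge[None, :] / dielectric
    e_c = float(np.sum(np.where(within, qq / r, 0.0)))
    dg = float(solvation(target, ligand)) if solvation is not None else 0.0
    return EnergyBreakdown(e_coulomb=e_c, e_lj=e_lj, dg_sol=dg)


# ---------------------------------------------------------------------------
# Excluded-type calibration
# ---------------------------------------------------------------------------

def solve_x_radius(
    y_params: tuple[float, float],
    eps_X: float = 1e-4,
    r_probe: float = 2.0,
    v_cap: float = 1.0,
) -> float:
    """Closed-form R_X such that V_XY(r_probe) equals v_cap.

    With x = (R_ij / r_probe)^6 the 12-6 form gives the quadratic
    eps_ij (x^2 - 2x) = v_cap whose repulsive root is
    x = 1 + sqrt(1 + v_cap/eps_ij); inverting the arithmetic-mean combining
    rule yields R_X = 2 R_ij - R_Y.
    """
    if v_cap <= 0:
        raise ValueError("v_cap must be positive")
    R_Y, eps_Y = y_params
    eps_ij = float(np.sqrt(eps_X * eps_Y))
    x = 1.0 + np.sqrt(1.0 + v_cap / eps_ij)
    R_ij = r_probe * x ** (1.0 / 6.0)
    return 2.0 * R_ij - R_Y


def calibrate_excluded_type(
    y_types=("O", "C", "H"),
    r_probe: float = 2.0,
    v_cap: float = 1.0,
    eps_X: float = 1e-4,
    table: ParameterTable | None = None,
    scenario_offset: float = 1.0,
    r_grid: np.ndarray | None = None,
) -> CalibrationResult:
    """Calibrate the excluded-type LJ parameters against common partners.

    For each partner type Y the pair distance R_X is solved so that the X-Y
    repulsion equals *v_cap* at *r_probe* (default: 1 kcal/mol at 2 Å); the
    per-Y solutions and their mean are returned.  Three scenario curves of
    V_X-O(r) illustrate the sensitivity: Sc2 at the solved R_X (short-range
    repulsion only), Sc1 at R_X + offset (repulsion zone too wide, large
    ligand-free zones) and Sc3 at R_X - offset (residual attraction,
    aggregation risk).
    """
    table = table or ParameterTable.default()
    if v_cap <= 0:
        raise ValueError("v_cap must be positive")
    per_y: dict[str, float] = {}
    for y in y_types:
        if y not in table:
            raise ParameterLookupError(f"unknown partner type {y!r}")
        per_y[y] = solve_x_radius(table.lookup(y), eps_X, r_probe, v_cap)
    mean = float(np.mean(list(per_y.values())))
    curves: dict[str, tuple[str, float, np.ndarray, np.ndarray]] = {}
    y0 = y_types[0]
    R_Y, eps_Y = table.lookup(y0)
    if r_grid is None:
        r_grid = np.linspace(1.0, 8.0, 141)
    for name, rx in (
        ("Sc1", per_y[y0] + scenario_offset),
        ("Sc2", per_y[y0]),
        ("Sc3", per_y[y0] - scenario_offset),
    ):
        p = combine((rx, eps_X), (R_Y, eps_Y))
        curves[name] = (y0, rx, r_grid.copy(), lj_pair(r_grid, p))
    return CalibrationResult(
        eps_X=eps_X, R_X_per_Y=per_y, R_X_mean=mean, scenario_curves=curves
    )
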