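"""Shared fixtures: toy systems, reduced-size run configurations, oracles.

Expensive artefacts (a wrapped monolayer, a full shaking run, the
enumeration docking oracle) are session-scoped; tests that mutate a complex
deep-copy it first.  All randomness is seed-fixed.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wns import fixtures as fx
from wns.dynamics import DynamicsParams
from wns.forcefield import PairGrid
from wns.shaker import ShakerConfig, run_shaker
from wns.structio import ParameterTable
from wns.wrapper import WrapperConfig, run_wrapper

#: Reduced problem sizes keeping the suite fast on one CPU; the method is
#: identical, only sampling effort shrinks.
FAST_WRAP = dict(n_runs=40, mc_steps=400, asa_n_points=240, max_cycles=40)
FAST_STEPS_PER_NS = 200


@pytest.fixture(scope="session")
def table() -> ParameterTable:
    return ParameterTable.default()


@pytest.fixture(scope="session")
def toy_ligand():
    return fx.make_toy_ligand()


@pytest.fixture(scope="session")
def two_pocket(toy_ligand):
    """Two-pocket toy target (depths -10/-5 kcal/mol) and its centres."""
    target, centers = fx.make_toy_target(n_pockets=2, depths=(-10.0, -5.0), seed=1)
    return target, centers


@pytest.fixture()
def fast_wrap_config() -> WrapperConfig:
    return WrapperConfig(**FAST_WRAP)


@pytest.fixture()
def fast_shaker_config() -> ShakerConfig:
    return ShakerConfig(steps_per_ns=FAST_STEPS_PER_NS)


@pytest.fixture(scope="session")
def wrapped(two_pocket, toy_ligand):
    """A finished wrapping run on the two-pocket fixture (seed 7)."""
    target, _ = two_pocket
    return run_wrapper(target, toy_ligand, WrapperConfig(**FAST_WRAP), seed=7)


@pytest.fixture(scope="session")
def mixed():
    """Mixed complex: 6 deep-pocket + 18 flat-surface copies, with labels."""
    return fx.make_mixed_complex(n_deep=6, n_flat=18, seed=3)


@pytest.fixture()
def mixed_copy(mixed):
    cmplx, labels = mixed
    return copy.deepcopy(cmplx), labels


@pytest.fixture(scope="session")
def shaker_result(mixed):
    """Full shaking protocol on a copy of the mixed complex (seed 1)."""
    cmplx, labels = mixed
    result = run_shaker(
        copy.deepcopy(cmplx), ShakerConfig(steps_per_ns=FAST_STEPS_PER_NS), seed=1
    )
    return result, labels


@pytest.fixture(scope="session")
def dock_oracle(two_pocket, toy_ligand):
    """Exhaustive enumeration of the global docking minimum.

    Translations on a grid over the bounding box (1.25 Å, refined locally to
    0.25 Å) crossed with the 24-element octahedral rotation group; returns
    (argmin centroid, energy).
    """
    target, _ = two_pocket
    grid = PairGrid(target, toy_ligand)
    local = toy_ligand.coords() - toy_ligand.coords().mean(axis=0)
    rots = Rotation.create_group("O").as_matrix()
    t_xyz = grid.target_coords
    lo, hi = t_xyz.min(axis=0) - 3.0, t_xyz.max(axis=0) + 3.0
    axes = [np.arange(lo[i], hi[i] + 1e-9, 1.25) for i in range(3)]
    P = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    radius = np.linalg.norm(P, axis=1)
    P = P[(radius > 4.0) & (radius < 15.0)]          # solid-ball surface zone
    best = (np.inf, None)
    for R in rots:
        loc = local @ R.T
        e_c, e_lj = grid.energies(loc[None, :, :] + P[:, None, :])
        tot = e_c + e_lj
        i = int(np.argmin(tot))
        if tot[i] < best[0]:
            best = (float(tot[i]), P[i])
    span = np.arange(-1.0, 1.01, 0.25)
    offs = np.array([[x, y, z] for x in span for y in span for z in span])
    P2 = best[1][None, :] + offs
    fin = (np.inf, None)
    for R in rots:
        loc = local @ R.T
        e_c, e_lj = grid.energies(loc[None, :, :] + P2[:, None, :])
        tot = e_c + e_lj
        i = int(np.argmin(tot))
        if tot[i] < fin[0]:
            fin = (float(tot[i]), P2[i])
    return fin[1], fin[0]


@pytest.fixture(scope="session")
def skipped_result(mixed):
    """Shaking with the restrained phases skipped (protocol-incomplete)."""
    cmplx, labels = mixed
    cfg = ShakerConfig(steps_per_ns=FAST_STEPS_PER_NS,
                       skip_md_b=True, skip_md_bsa=True)
    result = run_shaker(copy.deepcopy(cmplx), cfg, seed=1)
    return result, labels


@pytest.fixture()
def fast_dynamics() -> DynamicsParams:
    return DynamicsParams()
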