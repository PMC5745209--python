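"""Monolayer wrapping: exclusion marking, coverage, trimming, full loop."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from wns.dockkit import LigandPose
from wns.forcefield import EnergyBreakdown
from wns.metrics import asa
from wns.structio import AtomRecord, ParameterTable, Structure
from wns.wrapper import (
    MonolayerComplex,
    WrapperConfig,
    WrapState,
    ligand_free_asa_fraction,
    mark_excluded,
    run_wrapper,
    trim,
)


def _atom(serial, xyz, atom_type="C", charge=0.0):
    table = ParameterTable.default()
    lj_R, lj_eps = table.lookup(atom_type)
    return AtomRecord(serial=serial, name=f"{atom_type}{serial}",
                      coords=np.asarray(xyz, float), atom_type=atom_type,
                      charge=charge, lj_R=lj_R, lj_eps=lj_eps)


def _pose(xyz_list):
    tpl = Structure([_atom(i + 1, x) for i, x in enumerate(xyz_list)])
    p = LigandPose(template=tpl, coords=np.asarray(xyz_list, float))
    p.e = EnergyBreakdown(e_coulomb=0.0, e_lj=-1.0)
    return p


class TestMarkExcluded:
    def _state(self, target_xyz, pose_xyz):
        target = Structure([_atom(i + 1, x, charge=0.3) for i, x in enumerate(target_xyz)])
        return WrapState(target=target, retained_poses=[_pose(pose_xyz)],
                         initial_asa=1.0)

    def test_interface_tolerance_boundary(self):
        state = self._state([[3.4, 0, 0], [3.6, 0, 0]], [[0, 0, 0]])
        mark_excluded(state, tolerance=3.5)
        inside, outside = state.target.atoms
        assert inside.is_excluded
        assert not outside.is_excluded

    def test_excluded_atom_typing(self, table):
        state = self._state([[2.0, 0, 0]], [[0, 0, 0]])
        mark_excluded(state, tolerance=3.5)
        a = state.target.atoms[0]
        assert a.atom_type == "X"
        assert a.charge == 0.0
        assert (a.lj_R, a.lj_eps) == table.lookup("X")
        assert a.base_type == "C" and a.base_charge == 0.3

    def test_flag_is_sticky(self):
        state = self._state([[2.0, 0, 0]], [[0, 0, 0]])
        mark_excluded(state)
        # pose moves far away; re-marking must not clear the flag
        state.retained_poses = [_pose([[50, 0, 0]])]
        mark_excluded(state)
        assert state.target.atoms[0].is_excluded

    def test_requires_poses(self):
        state = WrapState(target=Structure([_atom(1, [0, 0, 0])]))
        with pytest.raises(Exception):
            mark_excluded(state)


class TestAsaFraction:
    def test_no_poses_gives_unity(self):
        target = Structure([_atom(1, [0, 0, 0])])
        state = WrapState(target=target, initial_asa=asa(target).total)
        assert ligand_free_asa_fraction(state) == 1.0

    def test_adding_a_pose_never_increases(self, two_pocket, toy_ligand):
        target, centers = two_pocket
        state = WrapState(target=target.copy(), initial_asa=asa(target).total)
        local = toy_ligand.coords() - toy_ligand.coords().mean(axis=0)
        fractions = [1.0]
        for c in centers:
            pose = LigandPose(template=toy_ligand, coords=local + c)
            pose.e = EnergyBreakdown(0.0, -1.0)
            state.retained_poses.append(pose)
            fractions.append(ligand_free_asa_fraction(state, n_points=240))
        assert all(b <= a + 1e-9 for a, b in zip(fractions, fractions[1:]))

    def test_enclosed_atom_triggers_exit_threshold(self):
        """A target fully tiled by occluders drops below the 1% exit level."""
        target = Structure([_atom(1, [0, 0, 0], "O")])
        state = WrapState(target=target, initial_asa=asa(target).total)
        # cage of copies tiling the whole surface
        shell = []
        g = np.arange(-1, 2, dtype=float)
        pts = np.array([[x, y, z] for x in g for y in g for z in g if (x, y, z) != (0, 0, 0)])
        pts = 3.2 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        state.retained_poses = [_pose([p]) for p in pts]
        assert ligand_free_asa_fraction(state, n_points=480) < 0.01

    def test_requires_initial_asa(self):
        state = WrapState(target=Structure([_atom(1, [0, 0, 0])]))
        with pytest.raises(Exception):
            ligand_free_asa_fraction(state)


class TestTrim:
    def _complex(self, dists):
        target = Structure([_atom(1, [0, 0, 0])])
        copies = [_pose([[d, 0.0, 0.0]]) for d in dists]
        for i, p in enumerate(copies, 1):
            p.copy_id = i
        return MonolayerComplex(target=target, copies=copies)

    def test_boundary(self):
        c = trim(self._complex([3.4, 3.6]), distance=3.5)
        assert [p.copy_id for p in c.copies] == [1]

    def test_identity_when_all_close(self):
        c = trim(self._complex([2.0, 3.0]), distance=3.5)
        assert c.n == 2


class TestRunWrapper:
    def test_terminates_by_coverage_or_saturation(self, wrapped):
        log = wrapped.cycle_log
        assert log, "wrapping must record at least one cycle"
        final = log[-1]
        assert final.asa_fraction < 0.01 or final.poses_added == 0

    def test_finds_both_designed_pockets(self, wrapped, two_pocket):
        _, centers = two_pocket
        centroids = np.array([p.centroid() for p in wrapped.copies])
        for c in centers:
            assert np.min(np.linalg.norm(centroids - c, axis=1)) < 3.0
        assert wrapped.n >= len(centers)

    def test_deep_pocket_filled_in_first_cycle(self, wrapped, two_pocket):
        _, centers = two_pocket
        first = np.array([p.centroid() for p in wrapped.copies if p.cycle == 1])
        assert np.min(np.linalg.norm(first - centers[0], axis=1)) < 3.0

    def test_coverage_monotone_nonincreasing(self, wrapped):
        fr = [c.asa_fraction for c in wrapped.cycle_log]
        assert all(b <= a + 1e-9 for a, b in zip(fr, fr[1:]))

    def test_first_cycle_finds_strongest_site(self, wrapped):
        best = [c.best_e_inter for c in wrapped.cycle_log if c.best_e_inter is not None]
        assert best[0] == min(best)

    def test_monolayer_no_overlap(self, wrapped):
        hc = [p.heavy_coords() for p in wrapped.copies]
        dmin = min(
            float(cKDTree(hc[j]).query(hc[i])[0].min())
            for i in range(len(hc)) for j in range(i + 1, len(hc))
        )
        assert dmin >= 2.0

    def test_trim_applied(self, wrapped):
        t_heavy = np.array([a.coords for a in wrapped.target.atoms if a.is_heavy])
        tree = cKDTree(t_heavy)
        for p in wrapped.copies:
            assert float(tree.query(p.heavy_coords())[0].min()) <= 3.5

    def test_exclusions_persist_in_returned_target(self, wrapped):
        assert any(a.is_excluded for a in wrapped.target.atoms)

    def test_deterministic(self, two_pocket, toy_ligand):
        target, _ = two_pocket
        cfg = WrapperConfig(n_runs=10, mc_steps=80, asa_n_points=120, max_cycles=2)
        a = run_wrapper(target, toy_ligand, cfg, seed=3)
        b = run_wrapper(target, toy_ligand, cfg, seed=3)
        assert a.n == b.n
        for pa, pb in zip(a.copies, b.copies):
            assert np.array_equal(pa.coords, pb.coords)

    def test_fully_excluded_target_exits_immediately(self, toy_ligand, table):
        x_R, x_eps = table.lookup("X")
        atoms = [AtomRecord(serial=i + 1, name=f"X{i+1}",
                            coords=np.array([2.0 * i, 0, 0]), atom_type="X",
                            charge=0.0, lj_R=x_R, lj_eps=x_eps,
                            is_excluded=True, base_type="C")
                 for i in range(4)]
        target = Structure(atoms)
        cfg = WrapperConfig(n_runs=5, mc_steps=20, asa_n_points=120)
        result = run_wrapper(target, toy_ligand, cfg, seed=0)
        assert result.n == 0
        assert len(result.cycle_log) == 1
        assert result.cycle_log[0].poses_added == 0

    def test_control_mode_without_repulsion_aggregates(self, two_pocket, toy_ligand):
        """Disabling the excluded-type repulsion reproduces multi-layer
        aggregation: some retained pair comes closer than the 2 Å monolayer
        bound, which never happens in normal mode."""
        target, _ = two_pocket
        cfg = WrapperConfig(n_runs=30, mc_steps=300, asa_n_points=240,
                            max_cycles=4, exclusion_enabled=False)
        result = run_wrapper(target, toy_ligand, cfg, seed=7)
        hc = [p.heavy_coords() for p in result.copies]
        assert len(hc) >= 2
        dmin = min(
            float(cKDTree(hc[j]).query(hc[i])[0].min())
            for i in range(len(hc)) for j in range(i + 1, len(hc))
        )
        assert dmin < 2.0
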