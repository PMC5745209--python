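"""Trajectory filtering, washing, exit criterion, final clustering, SR."""

import copy
import warnings

import numpy as np
import pytest

from wns import fixtures as fx
from wns.dockkit import LigandPose
from wns.errors import WnsError
from wns.forcefield import EnergyBreakdown
from wns.shaker import (
    CopyMetrics,
    FilterParams,
    ShakerConfig,
    apply_filters,
    cluster_final,
    compute_metrics,
    ec_s_reached,
    run_shaker,
    shaker_rate,
    wash,
)
from wns.structio import AtomRecord, ParameterTable, Structure, TrajectorySeries
from wns.wrapper import MonolayerComplex


def _atom(serial, xyz, atom_type="C", charge=0.0, **kw):
    table = ParameterTable.default()
    lj_R, lj_eps = table.lookup(atom_type)
    return AtomRecord(serial=serial, name=f"{atom_type}{serial}",
                      coords=np.asarray(xyz, float), atom_type=atom_type,
                      charge=charge, lj_R=lj_R, lj_eps=lj_eps, **kw)


class TestComputeMetrics:
    def _traj(self, frames):
        atoms = [_atom(1, frames[0][0], chain="L", resid=1),
                 _atom(2, frames[0][1], chain="L", resid=1)]
        return TrajectorySeries(coords=np.asarray(frames, float), atoms=atoms,
                                copy_atoms={1: np.array([0, 1])})

    def test_static_trajectory_constant_series(self):
        target = Structure([_atom(1, [0, 0, 0])])
        frames = [[[4, 0, 0], [5.4, 0, 0]]] * 3
        m = compute_metrics(self._traj(frames), target)[0]
        assert np.allclose(m.min_distance, 4.0)
        assert np.allclose(m.displacement, 0.0)
        assert np.allclose(m.e_lj, m.e_lj[0])

    def test_rigid_translation_jumps_displacement(self):
        target = Structure([_atom(1, [0, 0, 0])])
        base = np.array([[4.0, 0, 0], [5.4, 0, 0]])
        frames = [base, base, base + [0, 10, 0]]
        m = compute_metrics(self._traj(frames), target)[0]
        assert m.displacement[1] == pytest.approx(0.0)
        assert m.displacement[2] == pytest.approx(10.0)

    def test_min_distance_matches_double_loop(self):
        rng = np.random.default_rng(8)
        target = Structure([_atom(i + 1, rng.uniform(-3, 3, 3)) for i in range(3)])
        frames = rng.uniform(4, 9, size=(2, 2, 3))
        m = compute_metrics(self._traj(frames), target)[0]
        for f in range(2):
            dmin = min(
                float(np.linalg.norm(frames[f][j] - t.coords))
                for j in range(2) for t in target.atoms
            )
            assert m.min_distance[f] == pytest.approx(dmin, abs=1e-10)

    def test_uses_standard_typing_for_excluded_targets(self):
        # an excluded (X) target atom must be scored with its base C typing
        x = _atom(1, [0, 0, 0], "X", 0.0, is_excluded=True, base_type="C")
        target = Structure([x])
        frames = [[[4.0, 0, 0], [5.4, 0, 0]]]
        m = compute_metrics(self._traj(frames), target)[0]
        p_cc = 0.15 * ((4.0 / 4.0) ** 12 - 2 * (4.0 / 4.0) ** 6)
        p_far = 0.15 * ((4.0 / 5.4) ** 12 - 2 * (4.0 / 5.4) ** 6)
        assert m.e_lj[0] == pytest.approx(p_cc + p_far, rel=1e-9)


def _metrics(copy_id, dists, disps, eljs):
    return CopyMetrics(copy_id=copy_id, min_distance=np.asarray(dists, float),
                       e_lj=np.asarray(eljs, float),
                       displacement=np.asarray(disps, float))


class TestFilters:
    def test_cascade_reason_codes(self):
        n = 10
        bound = _metrics(1, [3] * n, [0.5] * n, [-8] * n)
        dissoc = _metrics(2, [3] * (n - 1) + [20], [0.5] * n, [-8] * n)
        drifter = _metrics(3, [3] * n, [1] * 8 + [6, 7], [-8] * n)
        weak = _metrics(4, [3] * n, [0.5] * n, [-0.2] * n)
        repulsive = _metrics(5, [3] * n, [0.5] * n, [-8] * 9 + [0.5])
        decisions = {d.copy_id: d for d in apply_filters(
            [bound, dissoc, drifter, weak, repulsive])}
        assert decisions[1].keep and decisions[1].reason is None
        assert decisions[2].reason == "F1"
        assert decisions[3].reason == "F2"
        assert decisions[4].reason == "F3"
        assert decisions[5].reason == "F4"

    def test_repulsive_final_frame_discarded_despite_contact(self):
        # windowed mean stays below the cap, but the final frame is repulsive
        m = _metrics(1, [2.5] * 10, [0.1] * 10, [-3] * 9 + [0.5])
        d = apply_filters([m], FilterParams(e_mean_cap=-0.5))[0]
        assert not d.keep and d.reason == "F4"

    def test_keep_set_independent_of_energy_screen_order(self):
        """F3 and F4 are both energy screens; swapping them must not change
        which copies survive (only the recorded reason may differ)."""
        rng = np.random.default_rng(0)
        metrics = []
        for i in range(30):
            n = 10
            metrics.append(_metrics(
                i,
                rng.uniform(2, 6, n),
                rng.uniform(0, 7, n),
                rng.uniform(-4, 1, n),
            ))
        params = FilterParams()
        keep_a = {d.copy_id for d in apply_filters(metrics, params) if d.keep}
        # manual conjunction with F4 evaluated before F3
        keep_b = set()
        for m in metrics:
            w = max(1, int(np.ceil(params.window_frac * len(m.min_distance))))
            ok = (m.min_distance[-1] <= params.d_diss
                  and not np.all(m.displacement[-w:] > params.d_drift)
                  and m.e_lj[-1] <= 0.0
                  and np.mean(m.e_lj[-w:]) <= params.e_mean_cap)
            if ok:
                keep_b.add(m.copy_id)
        assert keep_a == keep_b

    def test_conservation_partition(self):
        metrics = [_metrics(i, [3] * 5, [0] * 5, [-5] * 5) for i in range(4)]
        metrics.append(_metrics(9, [20] * 5, [0] * 5, [0] * 5))
        decisions = apply_filters(metrics)
        assert len(decisions) == len(metrics)
        kept = [d for d in decisions if d.keep]
        discarded = [d for d in decisions if not d.keep]
        assert len(kept) + len(discarded) == len(metrics)
        assert all(d.reason for d in discarded)
        assert all(d.reason is None for d in kept)

    def test_empty_metrics_rejected(self):
        with pytest.raises(WnsError):
            apply_filters([])


class TestWash:
    def _complex(self, n):
        target = Structure([_atom(1, [0, 0, 0])])
        copies = []
        for i in range(1, n + 1):
            tpl = Structure([_atom(1, [4.0 * i, 0, 0])])
            p = LigandPose(template=tpl, coords=np.array([[4.0 * i, 0, 0]]))
            p.copy_id = i
            copies.append(p)
        return MonolayerComplex(target=target, copies=copies)

    def test_empty_discard_is_identity(self):
        c = self._complex(3)
        wash(c, set())
        assert [p.copy_id for p in c.copies] == [1, 2, 3]

    def test_discard_all(self):
        c = self._complex(3)
        wash(c, {1, 2, 3})
        assert c.n == 0

    def test_stable_ids(self):
        c = self._complex(3)
        wash(c, {2})
        assert [p.copy_id for p in c.copies] == [1, 3]

    def test_unknown_id_rejected(self):
        with pytest.raises(WnsError):
            wash(self._complex(2), {9})


class TestExitCriterion:
    @pytest.mark.parametrize("N,n,expected", [
        (100, 25, True),    # exactly 75% eliminated
        (100, 26, False),
        (100, 0, True),
        (4, 1, True),
    ])
    def test_threshold(self, N, n, expected):
        assert ec_s_reached(N, n) is expected

    def test_errors(self):
        with pytest.raises(WnsError):
            ec_s_reached(0, 0)
        with pytest.raises(WnsError):
            ec_s_reached(5, 6)


class TestShakerRate:
    @pytest.mark.parametrize("N,n,rounded", [
        (68, 6, 11),
        (300, 13, 23),
        (92, 10, 9),
        (5, 5, 1),
    ])
    def test_reported_values(self, N, n, rounded):
        sr = shaker_rate(N, n)
        assert sr.rounded == rounded
        assert sr.raw == pytest.approx(N / n)

    def test_default_exit_threshold_equals_sr_four(self):
        # eliminating exactly 75% leaves N/4 copies: SR = 4
        assert shaker_rate(100, 25).rounded == 4
        assert ec_s_reached(100, 25, threshold=0.75)

    def test_zero_survivors_sentinel(self):
        sr = shaker_rate(24, 0)
        assert sr.raw is None and sr.rounded is None
        assert sr.display == "24/0"


class TestClusterFinal:
    def _pose(self, xyz, e_lj, run_id=0):
        tpl = Structure([_atom(1, [0, 0, 0])])
        p = LigandPose(template=tpl, coords=np.asarray(xyz, float).reshape(1, 3),
                       run_id=run_id)
        p.e = EnergyBreakdown(e_coulomb=0.0, e_lj=e_lj)
        return p

    def test_singleton(self):
        p = self._pose([0, 0, 0], -1.0)
        assert cluster_final([p]) == [p]

    def test_distance_limit_boundary(self):
        poses = [self._pose([0, 0, 0], -2.0), self._pose([7, 0, 0], -1.0, 1)]
        assert len(cluster_final(poses, dist_limit=6.0)) == 2
        assert len(cluster_final(poses, dist_limit=7.0)) == 1

    def test_partition_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        coords = rng.uniform(-8, 8, size=(8, 3))
        eljs = rng.uniform(-9, -1, size=8)
        poses = [self._pose(c, e, i) for i, (c, e) in enumerate(zip(coords, eljs))]
        reps = cluster_final(poses, dist_limit=3.5)
        # independent greedy re-implementation
        order = sorted(range(8), key=lambda i: eljs[i])
        oracle_reps, assign = [], {}
        for i in order:
            for cid, j in enumerate(oracle_reps):
                if np.linalg.norm(coords[i] - coords[j]) <= 3.5:
                    assign[i] = cid
                    break
            else:
                assign[i] = len(oracle_reps)
                oracle_reps.append(i)
        assert {i: poses[i].cluster_id for i in range(8)} == assign
        assert [p.run_id for p in reps] == oracle_reps


class TestRunShaker:
    def test_mixed_fixture_recovers_ground_truth(self, shaker_result):
        """Pocket-bound copies out-survive flat-surface copies; the loop
        stops at the 75% elimination criterion with SR >= 4."""
        result, labels = shaker_result
        assert result.ec_s_met
        surv_labels = [labels[p.copy_id] for p in result.survivors]
        assert "leave" not in surv_labels            # no dissociator survives
        assert len(surv_labels) >= 5                 # at most one stayer lost
        assert result.sr.raw >= 4.0
        assert result.protocol_complete

    def test_ranks_are_one_based_and_dense(self, shaker_result):
        result, _ = shaker_result
        assert sorted(result.ranks.values()) == list(range(1, result.n + 1))

    def test_single_pocket_copy_survives(self, mixed_copy, fast_shaker_config):
        cmplx, labels = mixed_copy
        stay = [p for p in cmplx.copies if labels[p.copy_id] == "stay"][:1]
        single = MonolayerComplex(target=cmplx.target, copies=stay)
        result = run_shaker(single, fast_shaker_config, seed=2)
        assert result.n == 1
        assert result.sr.rounded == 1
        assert result.cycles_run <= fast_shaker_config.max_bsa_cycles

    def test_all_dissociate_gives_sentinel(self, fast_shaker_config):
        target = Structure([_atom(1, [0, 0, 0])])
        tpl = Structure([_atom(1, [30.0, 0, 0])], meta={"mw": 100.0})
        p = LigandPose(template=tpl, coords=np.array([[30.0, 0, 0]]))
        p.copy_id = 1
        cmplx = MonolayerComplex(target=target, copies=[p])
        with pytest.warns(UserWarning, match="SR undefined"):
            result = run_shaker(cmplx, fast_shaker_config, seed=0)
        assert result.n == 0
        assert result.sr.display == "1/0"

    def test_skipping_restrained_phases_flagged_and_degraded(
        self, skipped_result, shaker_result
    ):
        """Going straight to the flexible refinement keeps loose binders that
        the full protocol eliminates."""
        result, labels = skipped_result
        assert not result.protocol_complete
        skipped_leavers = sum(
            1 for p in result.survivors if labels[p.copy_id] == "leave"
        )
        full_result, _ = shaker_result
        full_leavers = sum(
            1 for p in full_result.survivors if labels[p.copy_id] == "leave"
        )
        assert full_leavers == 0
        assert skipped_leavers > 0
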