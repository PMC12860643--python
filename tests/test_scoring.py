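"""Boltzmann weighting and the catalytic binding free energy."""

import math

import numpy as np
import pytest

from triadscan.model import PoseRecord, TriadscanError
from triadscan.scoring import (
    KT_298,
    boltzmann_weights,
    catalytic_binding_energy,
    is_catalytic_pose,
    rank_candidates,
    select_best_docking_pose,
)


def _pose(pid, e_tot, e_bind, d=(4.5, 3.2, 3.1), score=None):
    return PoseRecord(pid, e_tot, e_bind, d_ser_lig=d[0], d_ser_his=d[1],
                      d_his_acid=d[2], score=score)


NONCAT = (6.0, 3.2, 3.1)


class TestPosePredicate:
    @pytest.mark.parametrize(
        "d,expected",
        [
            ((4.9, 3.4, 3.4), True),
            ((5.0, 3.4, 3.4), False),  # strict bound on Ser-Lig
            ((4.0, 3.6, 3.0), False),
            ((4.0, 3.5, 3.0), False),  # strict bound on Ser-His
        ],
    )
    def test_strict_bounds(self, d, expected):
        assert is_catalytic_pose(_pose("p", 0, -5, d)) is expected

    def test_inclusive_mode_for_docking_distances(self):
        assert is_catalytic_pose(_pose("p", 0, -5, (4.0, 3.5, 3.5)), inclusive=True)

    def test_missing_distance_is_an_error(self):
        with pytest.raises(TriadscanError, match="d_ser_his"):
            is_catalytic_pose(PoseRecord("p", 0, -5, d_ser_lig=4.0, d_his_acid=3.0))


class TestBoltzmannWeights:
    def test_equal_energies_give_uniform_weights(self):
        np.testing.assert_allclose(boltzmann_weights([2.0] * 4), [0.25] * 4, atol=1e-12)

    def test_single_pose_gets_unit_weight(self):
        np.testing.assert_allclose(boltzmann_weights([7.0]), [1.0])

    def test_kt_log2_split(self):
        w = boltzmann_weights([0.0, KT_298 * math.log(2.0)], kT=KT_298)
        np.testing.assert_allclose(w, [2.0 / 3.0, 1.0 / 3.0], atol=1e-9)

    def test_weights_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e = rng.normal(0, 50, size=rng.integers(1, 40))
            assert boltzmann_weights(e).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_list_is_an_error(self):
        with pytest.raises(TriadscanError):
            boltzmann_weights([])


class TestCatalyticBindingEnergy:
    def test_all_catalytic_equal_energy_constant_binding(self):
        poses = [_pose(f"p{i}", 1.0, -10.0) for i in range(6)]
        score = catalytic_binding_energy(poses)
        assert score.e_cat == pytest.approx(-10.0, abs=1e-12)
        assert score.n_catalytic == 6

    def test_two_pose_symmetry(self):
        poses = [_pose("a", 0.0, -8.0), _pose("b", 0.0, -4.0)]
        assert catalytic_binding_energy(poses).e_cat == pytest.approx(-6.0)

    def test_worked_quarter_weight_example(self):
        """Ei = [0, kT ln 3] puts weights [3/4, 1/4]; only the second pose is
        catalytic, so <Eb> = 0.25 * (-3) = -0.75 without renormalisation."""
        kT = KT_298
        poses = [
            _pose("a", 0.0, -9.0, NONCAT),
            _pose("b", kT * math.log(3.0), -3.0),
        ]
        score = catalytic_binding_energy(poses, kT=kT)
        assert score.e_cat == pytest.approx(-0.75, abs=1e-9)
        assert score.n_catalytic == 1 and score.n_poses == 2

    def test_renormalised_variant(self):
        kT = KT_298
        poses = [
            _pose("a", 0.0, -9.0, NONCAT),
            _pose("b", kT * math.log(3.0), -3.0),
        ]
        score = catalytic_binding_energy(poses, kT=kT, renormalize=True)
        assert score.e_cat == pytest.approx(-3.0, abs=1e-9)

    def test_no_catalytic_pose_is_flagged_not_zero(self):
        poses = [_pose("a", 0.0, -9.0, NONCAT)]
        score = catalytic_binding_energy(poses)
        assert not score.defined
        assert math.isnan(score.e_cat)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        poses = [
            _pose(f"p{i}", float(e), float(b), (4.5, 3.2, 3.1) if i % 2 else NONCAT)
            for i, (e, b) in enumerate(zip(rng.normal(0, 5, 12), rng.normal(-8, 2, 12)))
        ]
        s0 = catalytic_binding_energy(poses)
        shifted = [
            PoseRecord(p.pose_id, p.E_total + 123.456, p.E_bind,
                       d_ser_lig=p.d_ser_lig, d_ser_his=p.d_ser_his,
                       d_his_acid=p.d_his_acid)
            for p in poses
        ]
        s1 = catalytic_binding_energy(shifted)
        assert s1.e_cat == pytest.approx(s0.e_cat, abs=1e-9)
        np.testing.assert_allclose(s1.weights, s0.weights, atol=1e-9)

    def test_high_temperature_limit_is_uniform(self):
        poses = [
            _pose("a", 0.0, -9.0), _pose("b", 5.0, -3.0), _pose("c", 9.0, -6.0, NONCAT)
        ]
        score = catalytic_binding_energy(poses, kT=1e6)
        expected = (2 / 3) * np.mean([-9.0, -3.0])
        assert score.e_cat == pytest.approx(expected, rel=1e-4)

    def test_low_temperature_limit_concentrates_on_ground_state(self):
        poses = [_pose("a", 0.0, -9.0), _pose("b", 5.0, -3.0)]
        assert catalytic_binding_energy(poses, kT=1e-3).e_cat == pytest.approx(-9.0)
        # ground state non-catalytic: its weight carries no binding energy
        poses2 = [_pose("a", 0.0, -9.0, NONCAT), _pose("b", 5.0, -3.0)]
        assert catalytic_binding_energy(poses2, kT=1e-3).e_cat == pytest.approx(0.0, abs=1e-9)

    def test_magnitude_bounded_by_largest_catalytic_binding(self):
        rng = np.random.default_rng(9)
        poses = [
            _pose(f"p{i}", float(e), float(b), (4.5, 3.2, 3.1) if i % 3 else NONCAT)
            for i, (e, b) in enumerate(zip(rng.normal(0, 3, 15), rng.normal(-6, 3, 15)))
        ]
        score = catalytic_binding_energy(poses)
        cap = max(
            abs(p.E_bind) for p in poses if is_catalytic_pose(p)
        )
        assert abs(score.e_cat) <= cap + 1e-12

    def test_naive_unshifted_oracle_equivalence(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0, 4, 20)
        b = rng.normal(-8, 2, 20)
        cat = rng.random(20) < 0.6
        poses = [
            _pose(f"p{i}", float(e[i]), float(b[i]),
                  (4.5, 3.2, 3.1) if cat[i] else NONCAT)
            for i in range(20)
        ]
        score = catalytic_binding_energy(poses, kT=KT_298)
        # direct textbook evaluation, no shift stabilisation
        q = np.sum(np.exp(-e / KT_298))
        pi = np.exp(-e / KT_298) / q
        naive = float(np.sum(pi[cat] * b[cat]))
        assert score.e_cat == pytest.approx(naive, rel=1e-9)


class TestDockingSelection:
    def test_best_valid_score_wins(self):
        poses = [_pose("a", 0, -5, score=-7.1), _pose("b", 0, -5, score=-6.0)]
        assert select_best_docking_pose(poses).pose_id == "a"

    def test_constraints_take_precedence_over_score(self):
        poses = [
            _pose("best", 0, -5, (4.0, 3.6, 3.0), score=-9.0),  # violates Ser-His
            _pose("valid", 0, -5, score=-6.0),
        ]
        assert select_best_docking_pose(poses).pose_id == "valid"

    def test_no_valid_pose_returns_none(self):
        poses = [_pose("a", 0, -5, (6.0, 3.6, 3.6), score=-9.0)]
        assert select_best_docking_pose(poses) is None


class TestRanking:
    def _scored(self, values):
        out = []
        for i, v in enumerate(values):
            poses = [_pose(f"p{i}", 0.0, v)]
            out.append((f"cand{i}", catalytic_binding_energy(poses)))
        return out

    def test_plain_sort_without_references(self):
        ranked = rank_candidates(self._scored([-3.0, -9.0, -6.0]))
        assert [r[0] for r in ranked] == ["cand1", "cand2", "cand0"]

    def test_reference_beat_count(self):
        ranked = rank_candidates(self._scored([-10.0]), references=[-5.0, -8.0, -12.0])
        assert ranked[0][2] == 2

    def test_stable_on_ties(self):
        ranked = rank_candidates(self._scored([-5.0, -5.0]))
        assert [r[0] for r in ranked] == ["cand0", "cand1"]
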