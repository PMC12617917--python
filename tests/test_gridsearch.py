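"""Tests for necklace combinatorics, exhaustive search, equiphase designs."""

import itertools
import math

import numpy as np
import pytest

from rhythmdesign import (
    ConstraintMask,
    Design,
    GridDesign,
    Partition,
    brute_force_optimal,
    count_necklaces,
    enumerate_necklaces,
    equiphase_construct,
    equispaced_design,
    is_equiphase,
    multifreq_objective,
    naive_constrained_design,
    worstcase_eigenvalue,
)


def _rotations(mask):
    n = len(mask)
    return {tuple(mask[k:] + mask[:k]) for k in range(n)}


def _enumerate_rotation_classes(n, n_t):
    """Brute-force oracle: all masks with n ones, deduped by rotation."""
    seen, reps = set(), []
    for ones in itertools.combinations(range(n_t), n):
        mask = tuple(1 if k in ones else 0 for k in range(n_t))
        if mask in seen:
            continue
        seen |= _rotations(list(mask))
        reps.append(mask)
    return reps


class TestNecklaceCount:
    def test_single_bead(self):
        for n_t in (1, 5, 17):
            assert count_necklaces(1, n_t) == 1

    @pytest.mark.parametrize("n,n_t,expected", [(2, 4, 2), (4, 8, 10)])
    def test_known_small_counts(self, n, n_t, expected):
        # expected values frozen from the exhaustive rotation-dedup oracle
        assert count_necklaces(n, n_t) == expected
        assert len(_enumerate_rotation_classes(n, n_t)) == expected

    def test_matches_enumeration_oracle_all_small(self):
        for n_t in range(2, 13):
            for n in range(1, n_t + 1):
                assert count_necklaces(n, n_t) == \
                    len(_enumerate_rotation_classes(n, n_t)), (n, n_t)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            count_necklaces(5, 4)


class TestNecklaceEnumeration:
    @pytest.mark.parametrize("n,n_t", [(4, 8), (1, 5), (3, 9), (5, 12)])
    def test_yields_one_canonical_rep_per_class(self, n, n_t):
        masks = [g.mask for g in enumerate_necklaces(n, n_t)]
        assert len(masks) == count_necklaces(n, n_t)
        # pairwise rotation-inequivalent
        all_rots = set()
        for m in masks:
            rots = _rotations(list(m))
            assert not (rots & all_rots)
            all_rots |= rots
        # canonical = lexicographically smallest rotation
        for m in masks:
            assert m == min(_rotations(list(m)))

    def test_counts_match_formula_up_to_16(self):
        for n_t in range(2, 17):
            for n in range(1, n_t + 1):
                assert sum(1 for _ in enumerate_necklaces(n, n_t)) == \
                    count_necklaces(n, n_t)


class TestBruteForce:
    def test_unconstrained_attains_equispaced_bound(self):
        res = brute_force_optimal(4, Partition(8), [1.0])
        assert res.objective == pytest.approx(2.0, abs=1e-9)
        assert res.certificate["exhaustive"]

    def test_matches_plain_loop_oracle(self):
        # n=5 of 10 slots, two frequencies: compare against a direct scan
        freqs = [1.0, 2.0]
        best = -1.0
        for ones in itertools.combinations(range(10), 5):
            d = Design(np.array(ones) / 10)
            best = max(best, multifreq_objective(d, freqs).j_value)
        res = brute_force_optimal(5, Partition(10), freqs)
        assert res.objective == pytest.approx(best, abs=1e-10)

    def test_constrained_beats_naive(self):
        part = Partition(24)
        for window_slots in (4, 8, 10):
            con = ConstraintMask.rest_window(24, 0, window_slots)
            naive = naive_constrained_design(6, part, con)
            res = brute_force_optimal(6, part, [1.0], con)
            assert res.objective >= \
                multifreq_objective(naive, [1.0]).j_value - 1e-9

    def test_rotational_relabeling_invariance(self):
        part = Partition(16)
        con = ConstraintMask.rest_window(16, 0, 5)
        con_rot = ConstraintMask.rest_window(16, 3, 5)
        a = brute_force_optimal(4, part, [1.0], con)
        b = brute_force_optimal(4, part, [1.0], con_rot)
        assert a.objective == pytest.approx(b.objective, abs=1e-9)

    def test_cap_and_infeasibility_errors(self):
        with pytest.raises(ValueError, match="cap"):
            brute_force_optimal(8, Partition(48), [1.0], cap=1000)
        con = ConstraintMask.rest_window(12, 0, 10)
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            brute_force_optimal(6, Partition(12), [1.0], con)


class TestNaiveDesign:
    def test_empty_window_gives_equispaced(self):
        con = ConstraintMask([1] * 24)
        d = naive_constrained_design(6, Partition(24), con)
        assert np.allclose(d.times, equispaced_design(6).times)

    def test_eight_hour_window_layout(self):
        # 8 h window on a 24 h study: 8 points spanning the 16 h arc
        con = ConstraintMask.rest_window(48, 0, 16)
        d = naive_constrained_design(8, Partition(48), con)
        hours = np.sort(np.mod(d.times * 24, 24))
        expected = np.sort(np.mod(8 + 16 * np.arange(8) / 7, 24))
        assert np.allclose(hours, expected, atol=1e-9)

    def test_half_window_hand_oracle(self):
        # window = half the cycle, 4 points at 1/6-span spacing in the rest
        con = ConstraintMask.rest_window(12, 0, 6)
        d = naive_constrained_design(4, Partition(12), con)
        # arc [0.5, 1.0], endpoints inclusive: 0.5, 0.666.., 0.833.., 1->0
        assert np.allclose(d.times, [0.0, 0.5, 2 / 3, 5 / 6], atol=1e-9)

    def test_snap_collision_raises(self):
        con = ConstraintMask.rest_window(4, 0, 2)
        with pytest.raises(ValueError):
            naive_constrained_design(4, Partition(4), con, snap=True)


class TestEquiphase:
    def test_equispaced_is_equiphase_below_nyquist(self):
        d = equispaced_design(8)
        assert is_equiphase(d, 1)
        assert is_equiphase(d, 3)

    def test_phase_collapse_fails(self):
        # at its Nyquist rate the phases collapse onto two values
        assert not is_equiphase(equispaced_design(8), 4)

    def test_trivial_single_frequency_construction(self):
        d = equiphase_construct(4, [1])
        assert np.allclose(d.times, equispaced_design(4).times)

    def test_bifrequency_construction(self):
        d = equiphase_construct(12, [1, 12])
        rep = multifreq_objective(d, [1, 12])
        assert rep.j_value == pytest.approx(6.0, abs=1e-8)
        assert rep.per_frequency_xi_min[1.0] == pytest.approx(6.0, abs=1e-8)
        assert rep.per_frequency_xi_min[12.0] == pytest.approx(6.0, abs=1e-8)
        assert is_equiphase(d, 1)
        assert is_equiphase(d, 12)

    def test_trifrequency_construction(self):
        d = equiphase_construct(36, [1, 12, 336])
        rep = multifreq_objective(d, [1, 12, 336])
        assert rep.j_value == pytest.approx(18.0, abs=1e-8)
        for f in (1, 12, 336):
            assert is_equiphase(d, f)

    def test_infeasible_sample_size_reports_obstruction(self):
        with pytest.raises(ValueError, match="no equiphase construction"):
            equiphase_construct(16, [1, 12, 336])

    def test_construction_always_hits_half_n(self):
        for n, freqs in [(12, [1, 2]), (12, [1, 12]), (9, [1, 3]), (16, [1, 4])]:
            d = equiphase_construct(n, freqs)
            assert multifreq_objective(d, freqs).j_value == \
                pytest.approx(n / 2, abs=1e-8)
            for f in freqs:
                assert is_equiphase(d, f)


class TestGridTypes:
    def test_grid_design_round_trip(self):
        g = GridDesign([0, 1, 0, 1, 1, 0])
        assert g.n == 3 and g.n_t == 6
        assert np.allclose(g.to_design().times, [1 / 6, 3 / 6, 4 / 6])
        assert GridDesign.from_slots([1, 3, 4], 6) == g

    def test_partition_times(self):
        assert np.allclose(Partition(4).times, [0, 0.25, 0.5, 0.75])

    def test_rest_window_wraps(self):
        con = ConstraintMask.rest_window(8, 6, 4)  # slots 6,7,0,1 blocked
        assert con.allowed == (0, 0, 1, 1, 1, 1, 0, 0)
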