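"""The model core: T/O/R/M profiles, divergences, RD and the K fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fodm import (
    ComputationError,
    EffectiveAtomCloud,
    HydroProfile,
    InputError,
    chain_status,
    fit_gaussian_envelope,
    fit_k,
    kl_divergence,
    levitt_weight,
    modified_profile,
    observed_profile,
    orient,
    rd,
    theoretical_profile,
    uniform_profile,
)
from fodm.synthetic import SyntheticSpec, make_gaussian_micelle

from conftest import fit_k_oracle, kl_oracle, observed_oracle, random_rotation


def _cloud(positions, h=None):
    positions = np.asarray(positions, float)
    n = len(positions)
    if h is None:
        h = np.full(n, 0.5)
    return EffectiveAtomCloud([("A", i + 1, "") for i in range(n)],
                              ["UNK"] * n, positions, np.asarray(h, float))


def _profile(vals, kind="T"):
    vals = np.asarray(vals, float)
    return HydroProfile(kind, vals,
                        tuple(("A", i + 1, "") for i in range(len(vals))))


class TestOrient:
    def test_axis_aligned_cloud_unchanged(self):
        pos = np.array([[-3, 0, 0], [3, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 0.5], [0, 0, -0.5]], float)
        oriented, center, rot = orient(_cloud(pos))
        np.testing.assert_allclose(center, 0, atol=1e-12)
        np.testing.assert_allclose(np.abs(rot), np.eye(3), atol=1e-8)
        np.testing.assert_allclose(np.abs(oriented.positions), np.abs(pos), atol=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(30, 3)) * [10, 5, 2]
        a, _, _ = orient(_cloud(pos))
        b, _, _ = orient(_cloud(pos + np.array([10.0, 0, 0])))
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-8)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(size=(40, 3)) * [12, 6, 3]
        rot = random_rotation(rng)
        a, _, _ = orient(_cloud(pos))
        b, _, _ = orient(_cloud(pos @ rot.T))
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-8)

    def test_coincident_points_error(self):
        with pytest.raises(ComputationError, match="coincide"):
            orient(_cloud(np.zeros((5, 3))))


class TestEnvelope:
    def test_extent_over_six(self):
        oriented, _, _ = orient(_cloud([[-3, 0, 0], [3, 0, 0], [0, 0.1, 0]]))
        env = fit_gaussian_envelope(oriented, pad=0.0)
        assert env.sigma[0] == pytest.approx(1.0)

    def test_pad_enlarges_sigma(self):
        oriented, _, _ = orient(_cloud([[-3, 0, 0], [3, 0, 0], [0, 0.1, 0]]))
        env = fit_gaussian_envelope(oriented, pad=9.0)
        assert env.sigma[0] == pytest.approx((6 + 18) / 6)

    def test_toy_cloud_sigmas_are_extent_based(self, toy_cloud):
        oriented, _, _ = orient(toy_cloud)
        env = fit_gaussian_envelope(oriented)
        extent = oriented.positions.max(0) - oriented.positions.min(0)
        np.testing.assert_allclose(env.sigma, extent / 6)


class TestTheoretical:
    def test_two_mirror_points_split_evenly(self):
        oriented, _, _ = orient(_cloud([[-4, 0, 0], [4, 0, 0]]))
        env = fit_gaussian_envelope(oriented)
        t = theoretical_profile(oriented, env)
        np.testing.assert_allclose(t.values, [0.5, 0.5], atol=1e-12)

    def test_collinear_points_gaussian_ratio(self):
        """Centre/outer value ratio at x = 0, ±σ is e^{1/2}."""
        pos = np.array([[-1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]])
        cloud = _cloud(pos)
        oriented, _, _ = orient(cloud)
        # extent 2 → σx = 1/3; rescale positions so ±1 sits at ±σ
        env = fit_gaussian_envelope(oriented)
        sx = env.sigma[0]
        t = theoretical_profile(oriented, env)
        ratio = t.values[1] / t.values[0]
        assert ratio == pytest.approx(math.exp(0.5 / sx**2))
        # direct evaluation of the normalized vector
        raw = np.exp(-pos[:, 0] ** 2 / (2 * sx**2))
        np.testing.assert_allclose(t.values, raw / raw.sum(), atol=1e-12)


class TestLevittWeight:
    @pytest.mark.parametrize(
        "r,c,expected",
        [(0.0, 9.0, 1.0), (9.0, 9.0, 0.0), (4.5, 9.0, 0.369140625),
         (10.0, 9.0, 0.0), (1.0, 2.0, 0.369140625)],
    )
    def test_known_values(self, r, c, expected):
        assert levitt_weight(r, c) == pytest.approx(expected, abs=1e-12)

    def test_invalid_cutoff(self):
        with pytest.raises(InputError):
            levitt_weight(1.0, 0.0)

    @given(st.floats(0, 50), st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, r, c):
        assert 0.0 <= levitt_weight(r, c) <= 1.0


class TestObserved:
    def test_far_pair_equal_h_self_terms_only(self):
        o = observed_profile(_cloud([[0, 0, 0], [100, 0, 0]], [0.4, 0.4]), cutoff=9.0)
        np.testing.assert_allclose(o.values, [0.5, 0.5])

    def test_far_pair_one_zero_h(self):
        o = observed_profile(_cloud([[0, 0, 0], [100, 0, 0]], [1.0, 0.0]), cutoff=9.0)
        np.testing.assert_allclose(o.values, [1.0, 0.0])

    def test_five_residue_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        pos = rng.normal(size=(5, 3)) * 4
        h = rng.uniform(size=5)
        o = observed_profile(_cloud(pos, h), cutoff=9.0)
        np.testing.assert_allclose(o.values, observed_oracle(pos, h, 9.0),
                                   rtol=0, atol=1e-14)

    @pytest.mark.parametrize("n", [10, 25, 50])
    def test_oracle_equivalence_up_to_n50(self, n):
        rng = np.random.default_rng(n)
        pos = rng.normal(size=(n, 3)) * 8
        h = rng.uniform(size=n)
        o = observed_profile(_cloud(pos, h), cutoff=9.0)
        np.testing.assert_allclose(o.values, observed_oracle(pos, h, 9.0),
                                   rtol=0, atol=1e-13)

    def test_all_zero_scale_degenerate(self):
        with pytest.raises(ComputationError, match="degenerate"):
            observed_profile(_cloud([[0, 0, 0], [1, 0, 0]], [0.0, 0.0]))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(30, 3)) * 6
        h = rng.uniform(size=30)
        rot, shift = random_rotation(rng), np.array([3.0, -7.0, 2.0])
        a = observed_profile(_cloud(pos, h))
        b = observed_profile(_cloud(pos @ rot.T + shift, h))
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)


class TestUniformAndModified:
    def test_uniform_quarters(self):
        np.testing.assert_allclose(uniform_profile(4).values, 0.25)

    def test_uniform_single(self):
        assert uniform_profile(1).values[0] == 1.0

    @pytest.mark.parametrize("n", [3, 7, 100, 997])
    def test_uniform_sums_exactly_to_one(self, n):
        assert uniform_profile(n).values.sum() == 1.0

    def test_k_zero_is_t(self):
        t = _profile([0.5, 0.3, 0.2])
        np.testing.assert_allclose(modified_profile(t, 0.0).values, t.values)

    def test_k_one_is_uniform(self):
        t = _profile([0.7, 0.2, 0.1])
        np.testing.assert_allclose(modified_profile(t, 1.0).values, 1 / 3)

    def test_k_two_direct_arithmetic(self):
        t = _profile([0.5, 0.3, 0.2])
        np.testing.assert_allclose(modified_profile(t, 2.0).values,
                                   [0.25, 0.35, 0.40])

    def test_large_k_limit_is_inverted_gaussian(self):
        """As K grows, M approaches the normalized inversion T_MAX − T;
        the residual shrinks like 1/K."""
        t = _profile([0.5, 0.3, 0.2])
        inv = np.array([0.0, 0.2, 0.3])
        np.testing.assert_allclose(modified_profile(t, 1e3).values,
                                   inv / inv.sum(), atol=2e-3)
        np.testing.assert_allclose(modified_profile(t, 1e7).values,
                                   inv / inv.sum(), atol=1e-6)

    def test_negative_k_rejected(self):
        with pytest.raises(InputError):
            modified_profile(_profile([0.6, 0.4]), -0.1)


class TestDivergenceAndRd:
    def test_identical_profiles_zero(self):
        p = _profile([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_half_half_vs_quarter(self):
        assert kl_divergence(np.array([0.5, 0.5]),
                             np.array([0.25, 0.75])) == pytest.approx(0.20751875)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            kl_divergence(np.array([1.0]), np.array([0.5, 0.5]))

    def test_zero_denominator_without_floor_errors(self):
        with pytest.raises(ComputationError):
            kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    @given(st.lists(st.floats(0.01, 1), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 1), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nonnegativity(self, a, b):
        n = min(len(a), len(b))
        p = np.array(a[:n]) / sum(a[:n])
        q = np.array(b[:n]) / sum(b[:n])
        assert kl_divergence(p, q) >= -1e-12

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 1, 8); p /= p.sum()
        q = rng.uniform(0.01, 1, 8); q /= q.sum()
        assert kl_divergence(p, q) == pytest.approx(kl_oracle(p, q), abs=1e-12)

    def test_rd_zero_when_o_equals_t(self):
        t = _profile([0.5, 0.3, 0.2])
        r = uniform_profile(3, t.index)
        assert rd(_profile([0.5, 0.3, 0.2], "O"), t, r) == 0.0

    def test_rd_one_when_o_equals_r(self):
        t = _profile([0.5, 0.3, 0.2])
        r = uniform_profile(3, t.index)
        o = _profile(r.values, "O")
        assert rd(o, t, r) == 1.0

    def test_rd_composition_of_divergences(self):
        t = _profile([0.4, 0.35, 0.15, 0.1])
        o = _profile([0.3, 0.2, 0.25, 0.25], "O")
        r = uniform_profile(4, t.index)
        expected = kl_oracle(o.values, t.values) / (
            kl_oracle(o.values, t.values) + kl_oracle(o.values, r.values))
        assert rd(o, t, r) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_rd_warns_and_returns_zero(self):
        t = _profile([0.5, 0.5])
        r = uniform_profile(2, t.index)
        with pytest.warns(UserWarning):
            assert rd(_profile([0.5, 0.5], "O"), t, r) == 0.0


class TestFitK:
    def test_recovers_generator_k_exactly(self):
        t = _profile([0.4, 0.25, 0.2, 0.1, 0.05])
        o = modified_profile(t, 0.7)
        k, curve = fit_k(HydroProfile("O", o.values, o.index), t)
        assert k == 0.7
        assert curve[:, 1].min() == pytest.approx(0.0, abs=1e-12)

    def test_o_equals_t_gives_zero(self):
        t = _profile([0.4, 0.25, 0.2, 0.1, 0.05])
        k, _ = fit_k(HydroProfile("O", t.values.copy(), t.index), t)
        assert k == 0.0

    def test_uniform_o_gives_one(self):
        t = _profile([0.4, 0.25, 0.2, 0.1, 0.05])
        o = uniform_profile(5, t.index)
        k, _ = fit_k(HydroProfile("O", o.values, o.index), t)
        assert k == 1.0

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            t_vals = rng.uniform(0.01, 1, 12); t_vals /= t_vals.sum()
            o_vals = rng.uniform(0.01, 1, 12); o_vals /= o_vals.sum()
            t = _profile(t_vals)
            o = HydroProfile("O", o_vals, t.index)
            k, _ = fit_k(o, t)
            assert k == pytest.approx(fit_k_oracle(o_vals, t_vals, (0, 10, 0.1)))

    def test_empty_grid_rejected(self):
        t = _profile([0.6, 0.4])
        with pytest.raises(InputError):
            fit_k(HydroProfile("O", t.values, t.index), t, grid=(0, 1, -0.1))


class TestChainStatus:
    def test_micelle_cloud_scores_below_half(self):
        cloud = make_gaussian_micelle(SyntheticSpec(n_residues=150, seed=4))
        result = chain_status(cloud)
        assert result.status.rd < 0.5

    def test_profiles_normalized_and_consistent(self, toy_cloud):
        result = chain_status(toy_cloud)
        for prof in (result.t, result.o, result.r, result.m):
            assert abs(prof.values.sum() - 1.0) < 1e-9
            assert (prof.values >= 0).all()
        s = result.status
        assert s.rd == pytest.approx(s.dkl_ot / (s.dkl_ot + s.dkl_or))
        assert 0.0 <= s.rd <= 1.0

    def test_rigid_motion_leaves_status_unchanged(self, toy_cloud):
        rng = np.random.default_rng(17)
        rot, shift = random_rotation(rng), np.array([11.0, -4.0, 8.0])
        moved = toy_cloud.replace_positions(toy_cloud.positions @ rot.T + shift)
        a, b = chain_status(toy_cloud), chain_status(moved)
        assert a.status.rd == pytest.approx(b.status.rd, abs=1e-8)
        assert a.status.k == b.status.k
        np.testing.assert_allclose(a.t.values, b.t.values, atol=1e-8)
        np.testing.assert_allclose(a.o.values, b.o.values, atol=1e-8)

    def test_permuting_residues_permutes_profiles(self, toy_cloud):
        rng = np.random.default_rng(23)
        perm = rng.permutation(len(toy_cloud))
        shuffled = EffectiveAtomCloud(
            [toy_cloud.res_ids[i] for i in perm],
            [toy_cloud.res_names[i] for i in perm],
            toy_cloud.positions[perm], toy_cloud.h[perm],
        )
        a, b = chain_status(toy_cloud), chain_status(shuffled)
        np.testing.assert_allclose(b.t.values, a.t.values[perm], atol=1e-10)
        np.testing.assert_allclose(b.o.values, a.o.values[perm], atol=1e-10)
        assert b.status.rd == pytest.approx(a.status.rd, abs=1e-10)
        assert b.status.k == a.status.k
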