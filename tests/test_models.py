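"""Model evaluation, exact moments, identifiability and rank laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fishdyn as fd
from fishdyn.models import model_from_dict, model_to_dict


class TestTrajectoryEvaluation:
    def test_zero_amplitude_gives_baseline(self):
        m = fd.ContinuousCycleModel(baseline=[10.0, 7.0], amplitude=[0, 0],
                                    phase=[0.3, 1.0], noise_sd=[1, 1])
        for t in (0.0, 0.37, 2.5):
            assert np.allclose(fd.eval_mean_trajectory(m, t), [10.0, 7.0])

    def test_cosine_extremes(self):
        m = fd.ContinuousCycleModel(baseline=[10.0], amplitude=[5.0],
                                    phase=[0.0], noise_sd=[1.0])
        assert fd.eval_mean_trajectory(m, 0.0)[0] == pytest.approx(15.0)
        assert fd.eval_mean_trajectory(m, 0.5)[0] == pytest.approx(5.0)

    def test_periodicity(self, rng):
        m = fd.sample_cycle_params(5, rng_seed=rng)
        t = rng.uniform(0, 3, size=7)
        assert np.allclose(fd.eval_mean_trajectory(m, t),
                           fd.eval_mean_trajectory(m, t + m.period),
                           atol=1e-12)

    def test_burst_prob_constant_when_flat(self):
        m = fd.BurstCycleModel(mean_prob=[0.4, 0.2], amp=[[0.0], [0.0]],
                               phase=[[0.0], [0.0]])
        assert np.allclose(fd.eval_burst_prob(m, 0.123), [0.4, 0.2])

    def test_locked_model_touches_zero(self):
        m = fd.BurstCycleModel.locked([0.3], [0.0])
        # cos = -1 at half period
        assert fd.eval_burst_prob(m, 0.5)[0] == pytest.approx(0.0, abs=1e-12)

    def test_clipping_at_one(self):
        m = fd.BurstCycleModel(mean_prob=[0.9], amp=[[0.3]], phase=[[0.0]])
        assert fd.eval_burst_prob(m, 0.0)[0] == 1.0

    def test_global_factor_scales_and_clips(self):
        m = fd.BurstCycleModel(mean_prob=[0.4], amp=[[0.2]], phase=[[0.0]])
        assert fd.eval_burst_prob(m, 0.0, 0.5)[0] == pytest.approx(0.3)
        assert fd.eval_burst_prob(m, 0.0, 2.0)[0] == 1.0


class TestExactMoments:
    def test_quarter_phase_pair_uncorrelated(self):
        m = fd.BurstCycleModel(mean_prob=[0.5, 0.5], amp=[[0.2], [0.2]],
                               phase=[[0.0], [np.pi / 2]])
        assert fd.exact_moments(m).cov[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_deterministic_two_state_switch(self):
        m = fd.SwitchModel(state_prob=[0.5, 0.5],
                           burst_prob=[[1.0, 0.0], [1.0, 0.0]])
        assert fd.exact_moments(m).cov[0, 1] == pytest.approx(0.25)

    def test_global_noise_zero_reduces_to_plain_formula(self, small_cycle):
        noisy = fd.BurstCycleModel(mean_prob=small_cycle.mean_prob,
                                   amp=small_cycle.amp,
                                   phase=small_cycle.phase,
                                   global_noise_sd=0.0)
        assert np.allclose(fd.exact_moments(noisy).cov,
                           fd.exact_moments(small_cycle).cov, atol=1e-15)

    def test_monte_carlo_time_sampling_oracle(self, small_cycle, rng):
        """Closed-form pair covariance vs brute-force uniform time sampling."""
        n = 10 ** 6
        t = rng.uniform(0, 1, size=n)
        p = fd.eval_burst_prob(small_cycle, t)  # (genes, n)
        mc = (p[0] * p[1]).mean() - p[0].mean() * p[1].mean()
        se = np.std((p[0] - p[0].mean()) * (p[1] - p[1].mean())) / np.sqrt(n)
        closed = fd.exact_moments(small_cycle).cov[0, 1]
        assert abs(mc - closed) < 3 * se + 1e-9

    def test_quadrature_matches_closed_form_without_clipping(
            self, small_cycle):
        a = fd.exact_moments(small_cycle)
        b = fd.exact_moments(small_cycle, method="quadrature")
        assert np.allclose(a.cov, b.cov, atol=1e-9)
        assert np.allclose(a.mean, b.mean, atol=1e-9)

    def test_quadrature_with_global_noise(self):
        m = fd.sample_bursty_params(3, rng_seed=5, mean_range=(0.05, 0.15),
                                    rel_amp_range=(0.3, 0.7),
                                    global_noise_sd=0.25)
        a = fd.exact_moments(m)
        b = fd.exact_moments(m, method="quadrature")
        # clipping is essentially never active at these parameters
        assert np.allclose(a.cov, b.cov, atol=1e-7)

    def test_quadrature_honors_clipping(self):
        # strongly clipped model: closed form and quadrature must differ
        m = fd.BurstCycleModel(mean_prob=[0.9, 0.9], amp=[[0.9], [0.9]],
                               phase=[[0.0], [0.1]])
        a = fd.exact_moments(m).cov[0, 1]
        b = fd.exact_moments(m, method="quadrature").cov[0, 1]
        assert abs(a - b) > 1e-3

    def test_phase_shift_and_reflection_degeneracy(self, small_cycle, rng):
        """Snapshot moments cannot see a global phase shift or the direction
        of time around the cycle."""
        base = fd.exact_moments(small_cycle).cov
        for phase in (small_cycle.phase + rng.uniform(0, 2 * np.pi),
                      -small_cycle.phase):
            other = fd.BurstCycleModel(mean_prob=small_cycle.mean_prob,
                                       amp=small_cycle.amp, phase=phase)
            assert np.allclose(fd.exact_moments(other).cov, base, atol=1e-12)

    def test_switch_mc_oracle(self, small_switch, rng):
        n = 10 ** 5
        s = rng.choice(2, size=n, p=small_switch.state_prob)
        vals = small_switch.burst_prob[:, s]  # conditional burst probs
        mc_cov = np.cov(vals, bias=True)
        exact = fd.exact_moments(small_switch)
        prod = (vals - vals.mean(axis=1, keepdims=True))
        for i in range(small_switch.n_genes):
            for j in range(i + 1, small_switch.n_genes):
                se = np.std(prod[i] * prod[j]) / np.sqrt(n)
                assert abs(mc_cov[i, j] - exact.cov[i, j]) < 3 * se + 1e-9


class TestRankLaws:
    def test_zero_matrix_rank_zero(self):
        assert fd.covariance_rank(np.zeros((4, 4))) == 0

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            fd.covariance_rank(np.array([[1.0, 0.5], [0.0, 1.0]]))

    @pytest.mark.parametrize("n_harmonics,global_sd,expected", [
        (1, 0.0, 2), (1, 0.4, 3), (2, 0.0, 4), (2, 0.3, 5)])
    def test_cycle_rank_is_2h_plus_global(self, n_harmonics, global_sd,
                                          expected):
        rng = np.random.default_rng(7)
        n = 6
        amp = rng.uniform(0.02, 0.08, size=(n, n_harmonics))
        m = fd.BurstCycleModel(
            mean_prob=rng.uniform(0.2, 0.4, size=n), amp=amp,
            phase=rng.uniform(0, 2 * np.pi, size=(n, n_harmonics)),
            global_noise_sd=global_sd)
        assert fd.covariance_rank(fd.exact_moments(m).cov) == expected

    @pytest.mark.parametrize("n_states,expected", [(2, 1), (3, 2)])
    def test_switch_rank_is_states_minus_one(self, n_states, expected):
        m = fd.sample_switch_params(6, n_states, rng_seed=8)
        assert fd.covariance_rank(fd.exact_moments(m).cov) == expected


class TestDofReport:
    @pytest.mark.parametrize("family,n,k,attr,expected", [
        ("cycle", 25, 1, "n_parameters", 74),
        ("cycle", 10, 2, "n_unconstrained", 5),
        ("switch", 5, 2, "n_unconstrained", 1),
        ("switch", 6, 3, "n_unconstrained", 3),
        ("cycle", 2, 1, "n_parameters", 5),
        ("cycle", 25, 1, "n_unconstrained", 0),
    ])
    def test_printed_counts(self, family, n, k, attr, expected):
        assert getattr(fd.dof_report(family, n, k), attr) == expected

    def test_cov_rank_field(self):
        assert fd.dof_report("cycle", 10, 1).cov_rank == 2
        assert fd.dof_report("cycle", 10, 1, global_noise=True).cov_rank == 3
        assert fd.dof_report("switch", 10, 2).cov_rank == 1

    def test_small_gene_sets_cap_the_constraints(self):
        rep = fd.dof_report("cycle", 3, 1)
        assert rep.capped
        assert rep.n_constraints == 3 + 3  # means + all off-diagonals
        assert rep.n_unconstrained == 2

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(h=st.integers(1, 4), n=st.integers(20, 60))
    def test_large_n_formula_for_cycles(self, h, n):
        """Unconstrained count is H(2H-1)-1, independent of n for large n."""
        rep = fd.dof_report("cycle", n, h)
        assert not rep.capped
        assert rep.n_unconstrained == max(0, h * (2 * h - 1) - 1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(s=st.integers(2, 5), n=st.integers(20, 60))
    def test_large_n_formula_for_switches(self, s, n):
        assert fd.dof_report("switch", n, s).n_unconstrained \
            == s * (s - 1) // 2


def _cycle_moment_map(n, h):
    """Parameter vector -> observable moments, for Jacobian-rank counting."""
    def fun(theta):
        p = theta[:n]
        amp = theta[n:n + n * h].reshape(n, h)
        phase = theta[n + n * h:].reshape(n, h)
        m = fd.BurstCycleModel(mean_prob=p, amp=amp, phase=phase)
        ms = fd.exact_moments(m)
        iu = np.triu_indices(n, 1)
        return np.concatenate([ms.mean, ms.cov[iu]])
    return fun


def _switch_moment_map(n, s):
    def fun(theta):
        pfree = theta[:s - 1]
        prob = np.concatenate([pfree, [1.0 - pfree.sum()]])
        q = theta[s - 1:].reshape(n, s)
        ms = fd.exact_moments(fd.SwitchModel(state_prob=prob, burst_prob=q))
        iu = np.triu_indices(n, 1)
        return np.concatenate([ms.mean, ms.cov[iu]])
    return fun


def _jacobian_nullity(fun, theta0, eps=1e-6):
    f0 = fun(theta0)
    J = np.empty((f0.size, theta0.size))
    for k in range(theta0.size):
        e = np.zeros_like(theta0)
        e[k] = eps
        J[:, k] = (fun(theta0 + e) - fun(theta0 - e)) / (2 * eps)
    sv = np.linalg.svd(J, compute_uv=False)
    rank = int(np.sum(sv > 1e-7 * sv[0]))
    return theta0.size - rank


class TestIdentifiabilityOracle:
    """Brute-force check of the parameter counting: the nullity of the
    parameters-to-moments Jacobian at a generic point equals the number of
    flat directions, i.e. the unconstrained parameters plus (for cycles)
    the one overall phase."""

    @pytest.mark.parametrize("n,h,expected_nullity", [(6, 1, 1), (8, 2, 6)])
    def test_cycle_flat_directions(self, n, h, expected_nullity):
        rng = np.random.default_rng(21)
        theta0 = np.concatenate([
            rng.uniform(0.3, 0.5, size=n),
            rng.uniform(0.02, 0.1, size=n * h),
            rng.uniform(0, 2 * np.pi, size=n * h)])
        nullity = _jacobian_nullity(_cycle_moment_map(n, h), theta0)
        rep = fd.dof_report("cycle", n, h)
        assert not rep.capped
        assert nullity == expected_nullity == rep.n_unconstrained + 1

    @pytest.mark.parametrize("n,s", [(5, 2), (6, 3)])
    def test_switch_flat_directions(self, n, s):
        rng = np.random.default_rng(22)
        theta0 = np.concatenate([
            np.full(s - 1, 1.0 / s),
            rng.uniform(0.15, 0.85, size=n * s)])
        nullity = _jacobian_nullity(_switch_moment_map(n, s), theta0)
        assert nullity == fd.dof_report("switch", n, s).n_unconstrained


class TestModelValidationAndIO:
    def test_amplitude_exceeding_baseline_rejected(self):
        with pytest.raises(ValueError):
            fd.ContinuousCycleModel(baseline=[5.0], amplitude=[6.0],
                                    phase=[0.0], noise_sd=[1.0])

    def test_state_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            fd.SwitchModel(state_prob=[0.6, 0.5], burst_prob=[[0.1, 0.2]])

    def test_locked_model_requires_matching_amplitudes(self):
        with pytest.raises(ValueError):
            fd.BurstCycleModel(mean_prob=[0.3], amp=[[0.2]], phase=[[0.0]],
                               amplitude_locked=True)

    @pytest.mark.parametrize("factory", [
        lambda: fd.sample_cycle_params(3, rng_seed=1),
        lambda: fd.sample_bursty_params(3, rng_seed=2, global_noise_sd=0.3),
        lambda: fd.sample_bursty_params(3, rng_seed=3, locked=True),
        lambda: fd.sample_switch_params(3, 3, rng_seed=4),
    ])
    def test_round_trip_is_identity(self, factory, tmp_path):
        m = factory()
        path = tmp_path / "model.json"
        fd.write_model(m, path)
        m2 = fd.read_model(path)
        assert model_to_dict(m) == model_to_dict(m2)

    def test_unknown_schema_version_rejected(self):
        with pytest.raises(ValueError):
            model_from_dict({"schema_version": 99, "family": "switch"})
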