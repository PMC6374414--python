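import math

import numpy as np
import pytest

from conftest import deterministic_chain, uniform_model
from mpdyn import (Factor, HMMSpec, MarginalMessagePassing, Modality,
                   ObservationRecord, PosteriorMarginals,
                   VariationalMessagePassing, bethe_free_energy, bp_marginals,
                   brute_force_posterior, conjecture_check, entropy,
                   free_energy_report, jensen_gap, kl_divergence, log_evidence,
                   marginal_free_energies, pairwise_marginals, random_model,
                   sample_trajectory, validate_model, variational_free_energy)


def random_q(spec, rng):
    return PosteriorMarginals(
        [rng.dirichlet(np.ones(f.m), size=spec.T) for f in spec.factors])


def test_kl_zero_handling():
    assert kl_divergence(np.array([0.0, 1.0]), np.array([0.5, 0.5])) \
        == pytest.approx(math.log(2))
    assert kl_divergence(np.array([0.5, 0.5]), np.array([0.0, 1.0])) \
        == math.inf  # explicit flag, not an overflow
    assert kl_divergence(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == 0.0


def test_entropy_values():
    assert entropy(np.array([1.0, 0.0, 0.0])) == 0.0
    assert entropy(np.full(3, 1 / 3)) == pytest.approx(math.log(3))


def test_variational_free_energy_zero_on_deterministic():
    spec, obs = deterministic_chain(T=3)
    q = bp_marginals(spec, obs)
    assert variational_free_energy(spec, obs, q) == pytest.approx(0.0, abs=1e-9)


def test_single_step_free_energy_minimised_at_posterior():
    # one step: F(q) is minimised at q ∝ D * mu_A with minimum -ln P(o)
    spec = validate_model(HMMSpec(
        [Factor(B=np.eye(2), D=np.array([0.6, 0.4]))],
        [Modality(A=np.array([[0.8, 0.2], [0.2, 0.8]]), factor=0)], T=1))
    obs = ObservationRecord(np.zeros((1, 1), int))
    opt = np.array([0.6 * 0.8, 0.4 * 0.2])
    opt /= opt.sum()
    f_opt = variational_free_energy(spec, obs, [opt[None, :]])
    assert f_opt == pytest.approx(-log_evidence(spec, obs), abs=1e-9)
    for p in np.linspace(0.01, 0.99, 23):  # grid check of the minimum
        q = np.array([[p, 1 - p]])
        assert variational_free_energy(spec, obs, [q]) >= f_opt - 1e-12


def test_vmp_fixed_point_lowers_free_energy(two_factor_model):
    spec, obs = two_factor_model
    est = VariationalMessagePassing(spec).fit(obs)
    f_fit = variational_free_energy(spec, obs, est.marginals_)
    uniform = [np.full((spec.T, f.m), 1.0 / f.m) for f in spec.factors]
    assert f_fit <= variational_free_energy(spec, obs, uniform) + 1e-9


def test_bethe_equals_variational_for_independent_q(two_factor_model):
    spec, obs = two_factor_model
    rng = np.random.default_rng(0)
    q = random_q(spec, rng)
    q.pairs = [np.stack([np.outer(s[t], s[t + 1]) for t in range(spec.T - 1)])
               for s in q.singles]
    f_b = bethe_free_energy(spec, obs, q)
    f_v = variational_free_energy(spec, obs, q)
    assert f_b == pytest.approx(f_v, abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_bethe_exact_at_true_posterior(seed):
    """On an acyclic chain the Bethe free energy equals -ln P(o) exactly."""
    spec = random_model({"levels": (2, 3), "T": 4}, seed=seed)
    obs = sample_trajectory(spec, seed + 30)
    post = pairwise_marginals(spec, obs)
    assert bethe_free_energy(spec, obs, post) == pytest.approx(
        -log_evidence(spec, obs), abs=1e-9)


def test_bethe_rejects_inconsistent_pairs(two_factor_model):
    spec, obs = two_factor_model
    post = pairwise_marginals(spec, obs)
    post.pairs[0][0] = np.full_like(post.pairs[0][0],
                                    1.0 / post.pairs[0][0].size)
    with pytest.raises(ValueError, match="inconsistent"):
        bethe_free_energy(spec, obs, post)


def test_marginal_free_energy_symmetry_and_recomposition():
    spec, obs = uniform_model(T=4, m=3)
    q = [np.full((4, 3), 1 / 3)]
    F_F, F_B, F_M = marginal_free_energies(spec, obs, q)
    np.testing.assert_allclose(F_F[1:-1], F_B[1:-1], atol=1e-12)
    # the mixture counts the likelihood and entropy once: F = (F_F + F_B)/2
    np.testing.assert_allclose(F_M, 0.5 * (F_F + F_B), atol=1e-12)


def test_recomposition_identity_generic(two_factor_model):
    spec, obs = two_factor_model
    rng = np.random.default_rng(3)
    q = random_q(spec, rng)
    F_F, F_B, F_M = marginal_free_energies(spec, obs, q)
    np.testing.assert_allclose(F_M, 0.5 * (F_F + F_B), atol=1e-10)


def test_mmp_fixed_point_is_stationary_for_marginal_free_energy():
    from scipy.special import softmax

    spec = random_model({"levels": (2,), "T": 4}, seed=4)
    obs = sample_trajectory(spec, 9)
    est = MarginalMessagePassing(spec, tol=1e-10).fit(obs)
    q = est.marginals_.singles[0]
    for t in range(spec.T):
        def local(qt):
            qq = [q.copy()]
            qq[0][t] = qt
            return marginal_free_energies(spec, obs, qq)[2][t]

        base = np.log(q[t])
        f0 = local(q[t])
        for i in range(2):
            v = base.copy()
            v[i] += 1e-7
            grad = (local(softmax(v)) - f0) / 1e-7
            assert abs(grad) < 1e-5


@pytest.mark.parametrize("seed", range(5))
def test_jensen_gap_nonnegative_for_random_q(seed):
    spec = random_model({"levels": (2, 2), "T": 3}, seed=seed)
    obs = sample_trajectory(spec, seed + 10)
    rng = np.random.default_rng(seed)
    for _ in range(10):
        assert jensen_gap(spec, obs, random_q(spec, rng)) >= -1e-9


def test_jensen_gap_equals_joint_kl():
    """F + ln P(o) equals D_KL[prod_t Q(s_t) || P(s_1..T | o)] directly."""
    import itertools

    spec = random_model({"levels": (2,), "T": 3}, seed=8)
    obs = sample_trajectory(spec, 3)
    rng = np.random.default_rng(1)
    q = random_q(spec, rng)
    gap = jensen_gap(spec, obs, q)

    # brute-force joint posterior and explicit sequence-level KL
    from mpdyn.exact import likelihood_messages

    lik = likelihood_messages(spec, obs)[0]
    fac = spec.factors[0]
    seqs = list(itertools.product(range(2), repeat=3))
    joint = np.array([
        fac.D[s[0]] * fac.B[s[1], s[0]] * fac.B[s[2], s[1]]
        * lik[0][s[0]] * lik[1][s[1]] * lik[2][s[2]] for s in seqs])
    post = joint / joint.sum()
    qs = np.array([np.prod([q.singles[0][t, s[t]] for t in range(3)])
                   for s in seqs])
    direct = float(np.sum(qs * (np.log(qs) - np.log(post))))
    assert gap == pytest.approx(direct, abs=1e-8)


def test_conjecture_slack_zero_on_deterministic():
    spec, obs = deterministic_chain(T=3)
    q = bp_marginals(spec, obs)
    np.testing.assert_allclose(conjecture_check(spec, obs, q), 0.0, atol=1e-9)


def test_conjecture_uniform_closed_form():
    # uniform model, uniform beliefs: interior slack reduces to ln O
    spec, obs = uniform_model(T=3, m=3, n_out=3)
    q = [np.full((3, 3), 1 / 3)]
    slack = conjecture_check(spec, obs, q)
    np.testing.assert_allclose(slack[:-1], math.log(3), atol=1e-9)


def test_conjecture_sweep_runs_and_reports():
    """The empirical sweep must run and report slack, whatever its sign."""
    mins = []
    for seed in range(20):
        spec = random_model({"levels": (2,), "T": 4}, seed=seed)
        obs = sample_trajectory(spec, seed + 1000)
        q = MarginalMessagePassing(spec).fit(obs).marginals_
        slack = conjecture_check(spec, obs, q)
        assert np.all(np.isfinite(slack))
        mins.append(slack.min())
    assert len(mins) == 20  # negative slack is reported, never clipped


def test_free_energy_report_bundle(two_factor_model):
    spec, obs = two_factor_model
    post = pairwise_marginals(spec, obs)
    rep = free_energy_report(spec, obs, post, with_conjecture=True)
    assert rep.F_bethe == pytest.approx(-rep.ln_evidence, abs=1e-9)
    assert rep.jensen_gap >= -1e-9
    assert rep.conjecture_slack.shape == (spec.T,)
    np.testing.assert_allclose(rep.F_marginal,
                               0.5 * (rep.F_forward + rep.F_backward),
                               atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_bethe_bound_tighter_than_mean_field(seed):
    """F_variational at the VMP attractor >= F_bethe at the exact posterior."""
    spec = random_model({"levels": (2, 3), "T": 4}, seed=seed)
    obs = sample_trajectory(spec, seed + 70)
    vmp = VariationalMessagePassing(spec).fit(obs).marginals_
    f_v = variational_free_energy(spec, obs, vmp)
    f_b = bethe_free_energy(spec, obs, pairwise_marginals(spec, obs))
    assert f_v >= f_b - 1e-9
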