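"""Li-Stephens HMM tests.

Oracles: a dense O(|H|^4)-transition forward-backward for the diploid
chain ([DERIVED] from the model definition) and exhaustive path
enumeration for sampled-path goodness of fit.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from hybridimpute import hmm
from hybridimpute.hmm import HMMParams
from hybridimpute.iodata import MISSING


def random_instance(rng, H, M):
    templates = rng.integers(0, 2, size=(H, M)).astype(np.int8)
    params = HMMParams(
        theta=rng.uniform(0.01, 0.4, size=M - 1),
        eps=rng.uniform(0.005, 0.2, size=M),
    )
    obs = rng.choice(np.array([0, 1, 2, MISSING], dtype=np.int8), size=M)
    return templates, params, obs


def dense_diploid_oracle(obs, templates, params):
    """Forward-backward over the H^2 pair states with the FULL transition
    matrix (cost O(M |H|^4)); the per-gamete transition factor is taken
    straight from the model definition. [DERIVED]"""
    H, M = templates.shape
    At = templates.T
    states = list(itertools.product(range(H), repeat=2))
    S = len(states)
    T = np.empty((M - 1, S, S))
    for t in range(M - 1):
        for a, (h1, k1) in enumerate(states):
            for b, (h2, k2) in enumerate(states):
                T[t, a, b] = hmm.transition_weight(
                    params.theta[t], h1 == h2, H
                ) * hmm.transition_weight(params.theta[t], k1 == k2, H)
    E = np.empty((M, S))
    for t in range(M):
        for a, (h, k) in enumerate(states):
            E[t, a] = hmm.emission_diploid(
                int(obs[t]), (int(At[t, h]), int(At[t, k])), params.eps[t]
            )
    f = E[0] / S
    loglik = 0.0
    F = np.empty((M, S))
    c = f.sum()
    loglik += np.log(c)
    F[0] = f / c
    for t in range(1, M):
        f = (F[t - 1] @ T[t - 1]) * E[t]
        c = f.sum()
        loglik += np.log(c)
        F[t] = f / c
    post = np.empty((M, S))
    b = np.ones(S)
    post[M - 1] = F[M - 1]
    for t in range(M - 2, -1, -1):
        b = T[t] @ (E[t + 1] * b)
        w = F[t] * b
        tot = w.sum()
        post[t] = w / tot
        b /= tot
    return post.reshape(M, H, H), loglik


@pytest.mark.parametrize("H,M", [(2, 2), (2, 3), (3, 3), (3, 4), (2, 4)])
@pytest.mark.parametrize("seed", range(4))
def test_factorised_diploid_matches_dense_oracle(H, M, seed):
    # [DERIVED] acceptance criterion 1: the factorised O(|H|^2)-per-step
    # recursion equals the dense O(|H|^4) transition oracle within 1e-10
    rng = np.random.default_rng(1000 * H + 10 * M + seed)
    templates, params, obs = random_instance(rng, H, M)
    post, loglik = hmm.forward_backward_diploid(obs, templates, params)
    post_o, loglik_o = dense_diploid_oracle(obs, templates, params)
    assert abs(loglik - loglik_o) < 1e-10
    np.testing.assert_allclose(post, post_o, atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_posteriors_normalise(seed):
    # [DERIVED] acceptance criterion 2 (normalisation part)
    rng = np.random.default_rng(seed)
    templates, params, obs = random_instance(rng, 4, 12)
    gam = rng.choice(np.array([0, 1, MISSING], dtype=np.int8), size=12)
    post_h, _ = hmm.forward_backward_haploid(gam, templates, params)
    np.testing.assert_allclose(post_h.sum(axis=1), 1.0, atol=1e-9)
    post_d, _ = hmm.forward_backward_diploid(obs, templates, params)
    np.testing.assert_allclose(post_d.sum(axis=(1, 2)), 1.0, atol=1e-9)


def test_sampled_paths_match_enumerated_posterior():
    # [PAPER] acceptance criterion 2 (goodness of fit): sampled haploid
    # path frequencies vs exhaustively enumerated posteriors on |H|=2,
    # M=2; chi-square alpha=0.001, 1e5 draws
    templates = np.array([[0, 1], [1, 0]], dtype=np.int8)
    params = HMMParams(theta=np.array([0.3]), eps=np.array([0.05, 0.1]))
    obs = np.array([0, 0], dtype=np.int8)
    H, M = templates.shape
    probs = {}
    for path in itertools.product(range(H), repeat=M):
        w = 1.0 / H
        for t in range(M):
            w *= hmm.emission_haploid(
                int(obs[t]), int(templates[path[t], t]), params.eps[t]
            )
            if t:
                w *= hmm.transition_weight(params.theta[t - 1], path[t - 1] == path[t], H)
        probs[path] = w
    tot = sum(probs.values())
    rng = np.random.default_rng(7)
    n = 100_000
    counts = dict.fromkeys(probs, 0)
    for _ in range(n):
        mos = hmm.sample_path_haploid(obs, templates, params, rng)
        counts[tuple(int(v) for v in mos.path)] += 1
    expected = np.array([n * probs[p] / tot for p in probs])
    observed = np.array([counts[p] for p in probs])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    crit = stats.chi2.ppf(1 - 0.001, df=len(probs) - 1)
    assert chi2 < crit


def test_transition_weight_normalises():
    # [TRIVIAL] one "same" plus H-1 "jump" weights sum to 1
    for theta, H in [(0.0, 2), (0.3, 5), (1.0, 3)]:
        total = hmm.transition_weight(theta, True, H) + (
            H - 1
        ) * hmm.transition_weight(theta, False, H)
        assert abs(total - 1.0) < 1e-12


def test_emission_diploid_values_and_normalisation():
    # [TRIVIAL] hand value: g=1 from (0,0) with eps -> 2 eps (1-eps)
    eps = 0.07
    assert abs(hmm.emission_diploid(1, (0, 0), eps) - 2 * eps * (1 - eps)) < 1e-12
    for pair in itertools.product((0, 1), repeat=2):
        tot = sum(hmm.emission_diploid(g, pair, eps) for g in (0, 1, 2))
        assert abs(tot - 1.0) < 1e-12
    assert hmm.emission_diploid(MISSING, (0, 1), eps) == 1.0


def test_haploid_update_posterior_matches_reference_fb():
    # [DERIVED] the numba kernel's allele posterior equals the reference
    # numpy forward-backward dotted with template alleles
    rng = np.random.default_rng(11)
    templates, params, _ = random_instance(rng, 5, 20)
    gam = rng.choice(np.array([0, 1, MISSING], dtype=np.int8), size=20)
    upd = hmm.haploid_update(gam, templates, params, rng)
    post, _ = hmm.forward_backward_haploid(gam, templates, params)
    expect = (post * templates.T).sum(axis=1)
    np.testing.assert_allclose(upd.post1, expect, atol=1e-9)


def test_diploid_update_mean_prob_matches_dense_posterior():
    # [DERIVED] Monte-Carlo: averaging diploid_update allele probabilities
    # over many draws approaches the dense pair-state posterior's allele-1
    # marginal (per gamete, summed in expectation)
    rng = np.random.default_rng(3)
    H, M = 3, 6
    templates = rng.integers(0, 2, size=(H, M)).astype(np.int8)
    params = HMMParams(
        theta=np.full(M - 1, 0.15), eps=np.full(M, 0.02)
    )
    obs = np.array([0, MISSING, 1, MISSING, 2, MISSING], dtype=np.int8)
    half = np.full((2, M), MISSING, dtype=np.int8)
    post, _ = hmm.forward_backward_diploid(obs, templates, params)
    At = templates.T
    # expected total dosage per marker under the pair-state posterior
    a = At[np.arange(M)][:, :, None] + At[np.arange(M)][:, None, :]
    dense_dosage = (post * a).sum(axis=(1, 2))
    acc = np.zeros(M)
    n = 3000
    for _ in range(n):
        upd = hmm.diploid_update(obs, half, templates, params, rng)
        acc += upd.prob.sum(axis=0)
    np.testing.assert_allclose(acc / n, dense_dosage, atol=0.06)


def test_diploid_update_output_shapes_and_ranges():
    rng = np.random.default_rng(5)
    templates, params, obs = random_instance(rng, 4, 15)
    half = np.full((2, 15), MISSING, dtype=np.int8)
    upd = hmm.diploid_update(obs, half, templates, params, rng)
    assert upd.prob.shape == (2, 15) and upd.pair.shape == (2, 15)
    assert upd.jumps.shape == (2, 14)
    assert np.all((upd.prob >= 0) & (upd.prob <= 1))
    assert set(np.unique(upd.pair)) <= {0, 1}


def test_param_update_laplace_formulas():
    # [PAPER] theta <- (jumps+1)/(transitions+2), eps <- (mism+1)/(comp+2)
    M = 4
    mos = hmm.SampledMosaic(
        path=np.array([0, 0, 1, 1]),
        jumps=np.array([0, 1, 0], dtype=np.int8),
        alleles=np.array([0, 1, 1, 0], dtype=np.int8),
    )
    obs = np.array([0, 1, 0, MISSING], dtype=np.int8)
    params = hmm.update_params([mos], [obs], hmm.init_params(M))
    # estimates clip at 0.5 to keep chains mixing
    np.testing.assert_allclose(
        params.theta, [(0 + 1) / 3, min((1 + 1) / 3, 0.5), (0 + 1) / 3]
    )
    # comparisons at markers 0..2 only; mismatch at marker 2
    np.testing.assert_allclose(
        params.eps, [(0 + 1) / 3, (0 + 1) / 3, min((1 + 1) / 3, 0.5), 1 / 2]
    )


def test_param_recovery_small():
    # [DERIVED] reduced-size analogue of acceptance criterion 4: eps
    # recovered within 50% on 400 gametes simulated from the model itself
    rng = np.random.default_rng(21)
    H, M, n = 30, 120, 400
    templates = rng.integers(0, 2, size=(H, M)).astype(np.int8)
    theta_true = np.full(M - 1, 0.05)
    eps_true = 0.02
    obs_list = []
    for _ in range(n):
        path = np.empty(M, dtype=np.int64)
        path[0] = rng.integers(H)
        for t in range(1, M):
            if rng.random() < theta_true[t - 1]:
                path[t] = rng.integers(H)
            else:
                path[t] = path[t - 1]
        alleles = templates[path, np.arange(M)]
        flip = rng.random(M) < eps_true
        obs_list.append((alleles ^ flip).astype(np.int8))
    params = hmm.init_params(M)
    for _ in range(8):
        counts = hmm.ParamCounts.zeros(M)
        for obs in obs_list:
            mos = hmm.sample_path_haploid(obs, templates, params, rng)
            counts.add_haploid(mos, obs)
        params = counts.to_params()
    assert abs(params.eps.mean() - eps_true) / eps_true < 0.5


def test_consensus_pair_majority_genotype_and_orientation():
    # [DERIVED] spec: per-locus majority genotype; inter-heterozygote
    # orientation by interval-wise majority
    a = np.array([[0, 1, 0, 1], [0, 0, 1, 0]], dtype=np.int8)  # orient keep
    b = np.array([[0, 1, 0, 1], [0, 0, 1, 0]], dtype=np.int8)
    c = np.array([[0, 1, 1, 0], [0, 0, 0, 1]], dtype=np.int8)  # one switch
    out = hmm.consensus_pair([a, b, c])
    np.testing.assert_array_equal(out.sum(axis=0), [0, 1, 1, 1])
    # majority relative orientation follows a/b at every interval
    o = out[0, 1:4]
    assert (o == [1, 0, 1]).all() or (o == [0, 1, 0]).all()


def test_consensus_pair_orders_gametes():
    pair = np.array([[1, 1], [0, 0]], dtype=np.int8)
    out = hmm.consensus_pair([pair])
    assert list(out[0]) <= list(out[1])


def test_initial_guess_respects_observations():
    rng = np.random.default_rng(0)
    obs = np.array([0, 1, 2, MISSING], dtype=np.int8)
    pair = hmm.initial_guess(obs, np.full(4, 0.5), rng)
    assert pair[:, 0].sum() == 0
    assert pair[:, 1].sum() == 1
    assert pair[:, 2].sum() == 2


def test_init_params_validation():
    with pytest.raises(ValueError):
        hmm.init_params(1)
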