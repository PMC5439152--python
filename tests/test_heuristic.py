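"""Single-locus heuristic tests.

The segregation analysis is checked against an exhaustive-enumeration
oracle on small pedigrees ([DERIVED]); the Mendelian rules against
hand-checkable forced-inheritance examples ([TRIVIAL]).
"""

import itertools

import numpy as np
import pytest

from hybridimpute import heuristic
from hybridimpute.iodata import MISSING, Pedigree


def trio():
    return Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("c", "s", "d")])


def test_allele_frequencies_ignores_missing():
    # [TRIVIAL]
    G = np.array([[0, 2, 9], [2, 2, 9]], dtype=np.int8)
    f = heuristic.allele_frequencies(G)
    # frequencies are clipped away from {0,1} to keep priors proper
    np.testing.assert_allclose(f[:2], [0.5, 1.0], atol=1e-5)


def test_mendelian_fill_opposing_homozygous_parents():
    # [TRIVIAL] sire=2, dam=0, offspring=9 -> genotype 1, phase (1,0)
    ped = trio()
    G = np.full((3, 1), MISSING, dtype=np.int8)
    G[ped.index["s"], 0] = 2
    G[ped.index["d"], 0] = 0
    G2, P = heuristic.mendelian_fill(G, ped)
    c = ped.index["c"]
    assert G2[c, 0] == 1
    assert P[2 * c, 0] == 1 and P[2 * c + 1, 0] == 0


def test_mendelian_fill_subtraction_rule():
    # [TRIVIAL] sire=0, offspring=1 -> offspring phase (0,1)
    ped = trio()
    G = np.full((3, 1), MISSING, dtype=np.int8)
    G[ped.index["s"], 0] = 0
    G[ped.index["c"], 0] = 1
    _, P = heuristic.mendelian_fill(G, ped)
    c = ped.index["c"]
    assert P[2 * c, 0] == 0 and P[2 * c + 1, 0] == 1


def test_mendelian_fill_conflict_sets_missing():
    # [TRIVIAL] sire=2, offspring=0 -> offspring locus reset to missing
    ped = trio()
    G = np.full((3, 1), MISSING, dtype=np.int8)
    G[ped.index["s"], 0] = 2
    G[ped.index["c"], 0] = 0
    G2, _ = heuristic.mendelian_fill(G, ped)
    assert G2[ped.index["c"], 0] == MISSING


def test_mendelian_fill_homozygote_phases_self():
    # [TRIVIAL] rule (a): genotype 2 -> both gametes 1
    ped = Pedigree.from_records([("a", "0", "0")])
    G = np.array([[2]], dtype=np.int8)
    _, P = heuristic.mendelian_fill(G, ped)
    assert P[0, 0] == 1 and P[1, 0] == 1


def test_mendelian_fill_never_alters_observed():
    # property: non-missing observed genotypes unchanged (no conflicts here)
    rng = np.random.default_rng(1)
    ped = trio()
    G = rng.integers(0, 3, size=(3, 20)).astype(np.int8)
    # resolve Mendelian conflicts in the random draw first
    G2, _ = heuristic.mendelian_fill(G.copy(), ped)
    obs = (G2 != MISSING) & (G == G2)
    G3, _ = heuristic.mendelian_fill(G2.copy(), ped)
    assert np.array_equal(G3[obs.nonzero()], G2[obs.nonzero()])


def test_mendelian_fill_monotone_idempotent():
    rng = np.random.default_rng(2)
    ped = trio()
    G = rng.choice(np.array([0, 1, 2, 9], dtype=np.int8), size=(3, 30))
    G1, P1 = heuristic.mendelian_fill(G.copy(), ped)
    G2, P2 = heuristic.mendelian_fill(G1.copy(), ped, P1.copy())
    np.testing.assert_array_equal(G1, G2)
    np.testing.assert_array_equal(P1, P2)


# --- segregation analysis -------------------------------------------------


def enumerate_posterior(ped: Pedigree, genotypes: np.ndarray, freq: float):
    """Exhaustive sum over all ordered-genotype configurations. [DERIVED]

    Joint = product of Hardy-Weinberg founder priors, per-child
    transmission probabilities (a parent transmits each of its two
    gamete alleles with probability 1/2) and exact-observation
    indicators.  Returns the (n, 4) ordered-pair posterior at one locus.
    """
    n = ped.n
    post = np.zeros((n, 4))
    total = 0.0
    pair_states = list(itertools.product((0, 1), repeat=2))  # (pat, mat)
    for config in itertools.product(range(4), repeat=n):
        w = 1.0
        for i in range(n):
            pa, ma = pair_states[config[i]]
            g = genotypes[i, 0]
            if g != MISSING and pa + ma != g:
                w = 0.0
                break
            si, di = ped.sire_idx[i], ped.dam_idx[i]
            if si < 0:
                w *= freq if pa == 1 else 1 - freq
            else:
                spa, sma = pair_states[config[si]]
                w *= 0.5 * ((spa == pa) + (sma == pa))
            if di < 0:
                w *= freq if ma == 1 else 1 - freq
            else:
                dpa, dma = pair_states[config[di]]
                w *= 0.5 * ((dpa == ma) + (dma == ma))
            if w == 0.0:
                break
        if w > 0.0:
            total += w
            for i in range(n):
                post[i, config[i]] += w
    return post / total


@pytest.mark.parametrize("seed", range(4))
def test_segregation_probs_matches_enumeration_all_observed(seed):
    # [DERIVED] spec property: with every genotype observed and no
    # conflicts, peeling marginals equal the exhaustive posterior on
    # pedigrees of <= 6 members
    ped = Pedigree.from_records(
        [
            ("s", "0", "0"),
            ("d1", "0", "0"),
            ("d2", "0", "0"),
            ("c1", "s", "d1"),
            ("c2", "s", "d2"),
            ("g1", "c1", "d2"),
        ]
    )
    rng = np.random.default_rng(seed)
    freq = 0.3
    # rejection-sample a conflict-free configuration by gene dropping
    pat = np.empty(ped.n, dtype=np.int8)
    mat = np.empty(ped.n, dtype=np.int8)
    for i in range(ped.n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        pat[i] = (
            rng.random() < freq
            if si < 0
            else (pat[si] if rng.random() < 0.5 else mat[si])
        )
        mat[i] = (
            rng.random() < freq
            if di < 0
            else (pat[di] if rng.random() < 0.5 else mat[di])
        )
    G = (pat + mat).astype(np.int8).reshape(-1, 1)
    phase = np.full((2 * ped.n, 1), MISSING, dtype=np.int8)
    Q = heuristic.segregation_probs(G, phase, ped, np.array([freq]))
    expected = enumerate_posterior(ped, G, freq)
    np.testing.assert_allclose(Q[:, 0, :], expected, atol=1e-9)


def test_segregation_probs_founder_prior():
    # [TRIVIAL] founder, genotype 9, freq 0.5 -> uniform
    ped = Pedigree.from_records([("a", "0", "0")])
    G = np.full((1, 1), MISSING, dtype=np.int8)
    phase = np.full((2, 1), MISSING, dtype=np.int8)
    Q = heuristic.segregation_probs(G, phase, ped, np.array([0.5]))
    np.testing.assert_allclose(Q[0, 0], [0.25] * 4)


def test_segregation_probs_observed_homozygote():
    # [TRIVIAL] founder, genotype 0 -> (1,0,0,0)
    ped = Pedigree.from_records([("a", "0", "0")])
    G = np.zeros((1, 1), dtype=np.int8)
    phase = np.full((2, 1), MISSING, dtype=np.int8)
    Q = heuristic.segregation_probs(G, phase, ped, np.array([0.5]))
    np.testing.assert_allclose(Q[0, 0], [1, 0, 0, 0])


def test_segregation_probs_trio_example():
    # [DERIVED] sire=0, dam missing (freq 0.5), child=1: the paternal
    # allele must be 0, so the child's mass concentrates on (0,1);
    # exact value via the enumeration oracle
    ped = trio()
    G = np.full((3, 1), MISSING, dtype=np.int8)
    G[ped.index["s"], 0] = 0
    G[ped.index["c"], 0] = 1
    phase = np.full((6, 1), MISSING, dtype=np.int8)
    Q = heuristic.segregation_probs(G, phase, ped, np.array([0.5]))
    expected = enumerate_posterior(ped, G, 0.5)
    c = ped.index["c"]
    np.testing.assert_allclose(Q[c, 0], expected[c], atol=1e-9)
    assert Q[c, 0, 1] > 0.99  # state (0,1)


def test_segregation_probs_normalised():
    rng = np.random.default_rng(3)
    ped = trio()
    G = rng.choice(np.array([0, 1, 2, 9], dtype=np.int8), size=(3, 16))
    G, P = heuristic.mendelian_fill(G, ped)
    Q = heuristic.segregation_probs(G, P, ped, np.full(16, 0.4))
    np.testing.assert_allclose(Q.sum(axis=-1), 1.0, atol=1e-9)
    assert np.all(Q >= 0)


def test_call_alleles_threshold():
    # [TRIVIAL] marginal 1.0 -> call; 0.6 @ 0.99 -> 9; 0.995 @ 0.99 -> call
    Q = np.zeros((1, 3, 4))
    Q[0, 0] = [0, 0, 0, 1.0]  # pat marginal 1.0
    Q[0, 1] = [0.4, 0, 0.6, 0]  # pat marginal 0.6
    Q[0, 2] = [0.005, 0, 0.995, 0]  # pat marginal 0.995
    phase = heuristic.call_alleles(Q, threshold=0.99)
    assert phase[0, 0] == 1
    assert phase[0, 1] == MISSING
    assert phase[0, 2] == 1


def test_call_alleles_threshold_validation():
    with pytest.raises(ValueError):
        heuristic.call_alleles(np.zeros((1, 1, 4)), threshold=0.5)
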