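"""Long-range phasing / haplotype-library tests.

Library imputation and pair imputation are checked against brute-force
candidate enumeration oracles ([DERIVED]); surrogate voting and the
recombination sweep against hand-built pedigree examples ([TRIVIAL]).
"""

import itertools

import numpy as np
import pytest

from hybridimpute import phasing
from hybridimpute.iodata import MISSING, Pedigree
from hybridimpute.phasing import CoreDefinition, HaplotypeLibrary


def test_default_core_lengths_log_spaced():
    # [PAPER] ten lengths log-spaced 500..9000, truncated to chromosome
    lengths = phasing.default_core_lengths(20000)
    assert lengths[0] == 500 and lengths[-1] == 9000 and len(lengths) == 10
    ratios = np.diff(np.log(lengths))
    assert ratios.std() < 0.02  # approximately even in log space
    short = phasing.default_core_lengths(1000)
    assert max(short) == 1000 and all(v >= 2 for v in short)


def test_build_cores_tile_whole_chromosome():
    # [DERIVED] every tiling partitions [0, M)
    tilings = phasing.build_cores(103, [10, 40])
    assert len(tilings) == 4  # two lengths x two offsets
    for cores in tilings:
        assert cores[0].start == 0 and cores[-1].end == 103
        for a, b in zip(cores[:-1], cores[1:]):
            assert a.end == b.start


def test_build_cores_offsets_differ():
    t0, t1 = phasing.build_cores(20, [8])
    assert {c.start for c in t0} != {c.start for c in t1}


def test_core_definition_validation():
    with pytest.raises(ValueError):
        CoreDefinition(5, 5)
    with pytest.raises(ValueError):
        phasing.build_cores(10, [1])


def test_count_opposing_homozygotes():
    # [TRIVIAL]
    a = np.array([0, 2, 1, 0, 9], dtype=np.int8)
    b = np.array([2, 2, 0, 9, 0], dtype=np.int8)
    assert phasing.count_opposing_homozygotes(a, b) == 1
    assert phasing.count_opposing_homozygotes(a, b, CoreDefinition(1, 5)) == 0


def family():
    return Pedigree.from_records(
        [
            ("s", "0", "0"),
            ("d", "0", "0"),
            ("d2", "0", "0"),
            ("c", "s", "d"),
            ("half", "s", "d2"),  # paternal half sib
            ("full", "s", "d"),  # full sib: excluded from both sides
        ]
    )


def test_find_surrogates_sides_and_exclusions():
    # [DERIVED] spec: surrogate candidates are the parent, its parents and
    # its other offspring; full sibs excluded; opposing homozygotes veto
    ped = family()
    M = 6
    G = np.ones((ped.n, M), dtype=np.int8)
    region = CoreDefinition(0, M)
    sur = phasing.find_surrogates(ped.index["c"], G, ped, region, min_overlap=1)
    assert ped.index["s"] in sur.paternal
    assert ped.index["half"] in sur.paternal
    assert ped.index["full"] not in sur.paternal
    assert ped.index["full"] not in sur.maternal
    assert sur.maternal == [ped.index["d"]]
    # an opposing homozygous locus removes the half sib
    G[ped.index["half"], 2] = 0
    G[ped.index["c"], 2] = 2
    sur = phasing.find_surrogates(ped.index["c"], G, ped, region, min_overlap=1)
    assert ped.index["half"] not in sur.paternal


def test_find_surrogates_overlap_guard():
    ped = family()
    G = np.full((ped.n, 4), MISSING, dtype=np.int8)
    G[ped.index["c"]] = 1
    G[ped.index["s"], 0] = 1  # only one jointly genotyped locus
    region = CoreDefinition(0, 4)
    sur = phasing.find_surrogates(ped.index["c"], G, ped, region, min_overlap=2)
    assert sur.paternal == []


def test_phase_by_surrogates_votes():
    # [DERIVED] homozygous proband loci called directly; heterozygous loci
    # take the unanimous homozygous surrogate vote; split votes stay missing
    ped = family()
    M = 4
    G = np.full((ped.n, M), MISSING, dtype=np.int8)
    c = ped.index["c"]
    G[c] = [0, 1, 1, 1]
    G[ped.index["s"]] = [0, 2, 2, 9]
    G[ped.index["half"]] = [0, 2, 0, 9]
    region = CoreDefinition(0, M)
    sur = phasing.SurrogateSet(
        paternal=[ped.index["s"], ped.index["half"]], maternal=[]
    )
    hap = phasing.phase_by_surrogates(c, 0, sur, G, region)
    assert hap[0] == 0  # direct from homozygote
    assert hap[1] == 1  # both vote allele 1
    assert hap[2] == MISSING  # split vote
    assert hap[3] == MISSING  # no vote


def test_library_counts_and_validation():
    lib = HaplotypeLibrary()
    core = CoreDefinition(0, 3)
    lib.insert(core, np.array([0, 1, 1], dtype=np.int8))
    lib.insert(core, np.array([0, 1, 1], dtype=np.int8))
    lib.insert(core, np.array([1, 0, 0], dtype=np.int8))
    haps, counts = lib.haplotypes(core)
    assert lib.size(core) == 2 and lib.total_count(core) == 3
    assert sorted(counts.tolist()) == [1, 2]
    with pytest.raises(ValueError):
        lib.insert(core, np.array([0, 9, 1], dtype=np.int8))


def test_build_library_inserts_only_resolved():
    phase = np.array(
        [[0, 1, 1, 0], [0, 9, 1, 0], [1, 1, 0, 0]], dtype=np.int8
    )
    tilings = [[CoreDefinition(0, 2), CoreDefinition(2, 4)]]
    lib = phasing.build_library(phase, tilings)
    assert lib.total_count(CoreDefinition(0, 2)) == 2  # row 1 has a 9
    assert lib.total_count(CoreDefinition(2, 4)) == 3


def library_impute_oracle(gamete, haps):
    """Unanimity semantics by direct enumeration. [DERIVED]"""
    known = gamete != MISSING
    cand = [h for h in haps if np.all(h[known] == gamete[known])]
    out = gamete.copy()
    if not cand:
        return out
    cand = np.array(cand)
    for m in np.flatnonzero(~known):
        vals = set(cand[:, m].tolist())
        if len(vals) == 1:
            out[m] = vals.pop()
    return out


@pytest.mark.parametrize("seed", range(6))
def test_library_impute_matches_enumeration(seed):
    # [DERIVED] spec: impute iff every consistent candidate agrees
    rng = np.random.default_rng(seed)
    L = rng.integers(3, 9)
    core = CoreDefinition(0, int(L))
    K = rng.integers(1, 16)
    haps = rng.integers(0, 2, size=(K, L)).astype(np.int8)
    lib = HaplotypeLibrary()
    for h in haps:
        lib.insert(core, h)
    gam = rng.choice(np.array([0, 1, MISSING], dtype=np.int8), size=L, p=[0.3, 0.3, 0.4])
    got = phasing.library_impute(gam, lib, core)
    # the library de-duplicates; unanimity is unaffected by multiplicity
    want = library_impute_oracle(gam, haps)
    np.testing.assert_array_equal(got, want)


def test_library_impute_spec_example():
    # [TRIVIAL] two candidates disagree at one position, agree at another
    core = CoreDefinition(0, 3)
    lib = HaplotypeLibrary()
    lib.insert(core, np.array([0, 0, 1], dtype=np.int8))
    lib.insert(core, np.array([0, 1, 1], dtype=np.int8))
    lib.insert(core, np.array([1, 1, 1], dtype=np.int8))  # inconsistent
    gam = np.array([0, MISSING, MISSING], dtype=np.int8)
    out = phasing.library_impute(gam, lib, core)
    assert out[1] == MISSING and out[2] == 1


def test_library_impute_restrict_to_parent_gametes():
    core = CoreDefinition(0, 2)
    lib = HaplotypeLibrary()
    lib.insert(core, np.array([1, 1], dtype=np.int8))
    parents = np.array([[0, 1], [0, 1]], dtype=np.int8)
    gam = np.array([0, MISSING], dtype=np.int8)
    out = phasing.library_impute(gam, lib, core, restrict_to=parents)
    assert out[1] == 1


@pytest.mark.parametrize("seed", range(4))
def test_batch_library_impute_matches_single(seed):
    # [DERIVED] vectorised route agrees with per-gamete unanimity calls
    rng = np.random.default_rng(100 + seed)
    L, K, R = 6, 10, 8
    core = CoreDefinition(0, L)
    haps = rng.integers(0, 2, size=(K, L)).astype(np.int8)
    lib = HaplotypeLibrary()
    for h in haps:
        lib.insert(core, h)
    phase = rng.choice(
        np.array([0, 1, MISSING], dtype=np.int8), size=(R, L), p=[0.25, 0.25, 0.5]
    )
    prop, veto = phasing.batch_library_impute(
        phase, lib, [core], np.arange(R)
    )
    uh, _ = lib.haplotypes(core)
    for r in range(R):
        want = library_impute_oracle(phase[r], uh)
        filled = (want != MISSING) & (phase[r] == MISSING)
        committed = (prop[r] != MISSING) & ~veto[r]
        np.testing.assert_array_equal(prop[r][committed], want[committed])
        # every unanimous fill is either committed or vetoed by a split call
        assert np.all(committed[filled] | veto[r][filled] == committed[filled] | veto[r][filled])
        np.testing.assert_array_equal(committed, filled & ~veto[r])


def test_cross_core_consensus_rules():
    # [DERIVED] commit iff all calling tilings agree; keep resolved alleles
    base = np.array([[1, MISSING, MISSING, MISSING]], dtype=np.int8)
    p1 = np.array([[9, 0, 1, 9]], dtype=np.int8)
    p2 = np.array([[9, 0, 0, 9]], dtype=np.int8)
    out = phasing.cross_core_consensus([p1, p2], base)
    assert out[0, 0] == 1  # untouched
    assert out[0, 1] == 0  # unanimous
    assert out[0, 2] == MISSING  # disagreement
    assert out[0, 3] == MISSING  # no call


def pair_oracle(g, pa, pb, haps):
    """All ordered candidate-pair dosages by enumeration. [DERIVED]"""
    K = len(haps)
    dosages = None
    lo = None
    hi = None
    for i, j in itertools.product(range(K), repeat=2):
        a, b = haps[i], haps[j]
        ok = True
        for m in range(len(g)):
            if g[m] != MISSING and a[m] + b[m] != g[m]:
                ok = False
                break
            if pa[m] != MISSING and a[m] != pa[m]:
                ok = False
                break
            if pb[m] != MISSING and b[m] != pb[m]:
                ok = False
                break
        if not ok:
            continue
        d = a + b
        lo = d if lo is None else np.minimum(lo, d)
        hi = d if hi is None else np.maximum(hi, d)
    return lo, hi


@pytest.mark.parametrize("seed", range(6))
def test_pair_library_impute_matches_enumeration(seed):
    # [DERIVED] the signature-group min/max dosage equals the brute-force
    # ordered-pair enumeration
    rng = np.random.default_rng(200 + seed)
    L, K = 6, 8
    core = CoreDefinition(0, L)
    haps = rng.integers(0, 2, size=(K, L)).astype(np.int8)
    lib = HaplotypeLibrary()
    for h in haps:
        lib.insert(core, h)
    uh, _ = lib.haplotypes(core)
    g = rng.choice(np.array([0, 1, 2, MISSING], dtype=np.int8), size=L)
    if not np.any(g == MISSING) or np.all(g == MISSING):
        g[0] = MISSING
        g[1] = 0
    phase = np.full((2, L), MISSING, dtype=np.int8)
    G = g.reshape(1, -1)
    prop, veto = phasing.pair_library_impute(
        G, phase, lib, [core], np.array([0])
    )
    lo, hi = pair_oracle(g, phase[0], phase[1], list(uh))
    miss = g == MISSING
    if lo is None:
        assert np.all(prop[0] == MISSING) and not veto.any()
        return
    for m in np.flatnonzero(miss):
        if lo[m] == hi[m]:
            assert prop[0, m] == lo[m] and not veto[0, m]
        else:
            assert veto[0, m]


def test_pair_library_impute_het_cap_abstains():
    # beyond max_het heterozygous observed loci the core abstains
    core = CoreDefinition(0, 4)
    lib = HaplotypeLibrary()
    lib.insert(core, np.array([0, 1, 0, 1], dtype=np.int8))
    lib.insert(core, np.array([1, 0, 1, 0], dtype=np.int8))
    g = np.array([[1, 1, 1, MISSING]], dtype=np.int8)
    phase = np.full((2, 4), MISSING, dtype=np.int8)
    prop, veto = phasing.pair_library_impute(
        g, phase, lib, [core], np.array([0]), max_het=2
    )
    assert np.all(prop == MISSING) and not veto.any()


def sweep_family():
    ped = Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("c", "s", "d")])
    M = 7
    phase = np.full((2 * ped.n, M), MISSING, dtype=np.int8)
    s = ped.index["s"]
    phase[2 * s] = 0
    phase[2 * s + 1] = 1
    c = ped.index["c"]
    phase[2 * c] = [0, 9, 9, 0, 9, 1, 9]
    G = np.full((ped.n, M), MISSING, dtype=np.int8)
    return ped, phase, G, c


def test_recombination_sweep_copy_and_interpolation():
    # [DERIVED] spec: copy inside constant-origin stretches; linear
    # interpolation across a detected crossover interval
    ped, phase, G, c = sweep_family()
    out, probs = phasing.recombination_sweep(phase, ped, G)
    row = 2 * c
    assert out[row, 1] == 0 and out[row, 2] == 0  # copied from gamete 1
    # markers 3(origin 1)..5(origin 2): marker 4 interpolates halfway
    assert probs[row, 4] == pytest.approx(0.5)
    assert out[row, 4] == MISSING


def test_recombination_sweep_haldane_tail():
    # [DERIVED] one-sided stretch: nearest-anchor allele weighted by the
    # even-crossover probability (1 + exp(-2 d)) / 2
    ped, phase, G, c = sweep_family()
    out, probs = phasing.recombination_sweep(phase, ped, G)
    row = 2 * c
    d = 1.0 / 100.0  # marker index = cM without a map
    w1 = 0.5 * (1.0 + np.exp(-2.0 * d))
    # anchor at marker 5 carries origin 2 (parent gamete allele 1)
    assert probs[row, 6] == pytest.approx(w1 * 1.0 + (1.0 - w1) * 0.0)


def test_recombination_sweep_respects_genotypes():
    # a copy that would contradict an observed genotype is suppressed
    ped, phase, G, c = sweep_family()
    G[c, 1] = 2  # conflicts with copying allele 0
    out, _ = phasing.recombination_sweep(phase, ped, G)
    assert out[2 * c, 1] == MISSING


def origin_oracle(calls, pg1, pg2, pos, eps):
    """Exhaustive 2-state path enumeration for one gamete. [DERIVED]"""
    M = len(calls)
    t = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0))
    post = np.zeros(M)
    tot = 0.0
    for states in itertools.product((0, 1), repeat=M):
        w = 0.5
        for m in range(M):
            if m:
                w *= t[m - 1] if states[m] != states[m - 1] else 1 - t[m - 1]
            if calls[m] != MISSING:
                src = pg1[m] if states[m] == 0 else pg2[m]
                if src != MISSING:
                    w *= 1 - eps if calls[m] == src else eps
        tot += w
        for m in range(M):
            if states[m] == 0:
                post[m] += w
    return post / tot


def test_origin_posterior_matches_enumeration():
    # [DERIVED] forward-backward origin posterior vs exhaustive paths
    ped = Pedigree.from_records([("s", "0", "0"), ("c", "s", "0")])
    M = 5
    phase = np.full((2 * ped.n, M), MISSING, dtype=np.int8)
    s, c = ped.index["s"], ped.index["c"]
    phase[2 * s] = [0, 0, 1, 0, 1]
    phase[2 * s + 1] = [1, 1, 0, 1, 0]
    phase[2 * c] = [0, 9, 9, 1, 9]
    pos = np.array([0.0, 2.0, 5.0, 9.0, 20.0])
    post = phasing.origin_posterior(phase, ped, pos, eps=0.01)
    want = origin_oracle(
        phase[2 * c], phase[2 * s], phase[2 * s + 1], pos, 0.01
    )
    np.testing.assert_allclose(post[2 * c], want, atol=1e-9)
    assert np.all(np.isnan(post[2 * c + 1]))  # no dam


def test_joint_origin_posterior_uses_het_anchors():
    # [DERIVED] a heterozygous observed genotype is uninformative for each
    # gamete alone but anchors the joint chain
    ped = Pedigree.from_records(
        [("s", "0", "0"), ("d", "0", "0"), ("c", "s", "d")]
    )
    M = 3
    phase = np.full((2 * ped.n, M), MISSING, dtype=np.int8)
    s, d, c = ped.index["s"], ped.index["d"], ped.index["c"]
    phase[2 * s] = [1, 1, 1]
    phase[2 * s + 1] = [0, 0, 0]
    phase[2 * d] = [0, 0, 0]
    phase[2 * d + 1] = [1, 1, 1]
    G = np.full((ped.n, M), MISSING, dtype=np.int8)
    G[c] = [9, 1, 9]
    # anchor the maternal origin at marker 0
    phase[2 * c + 1, 0] = 0
    marg = phasing.origin_posterior(phase, ped, eps=0.01)
    joint = phasing.joint_origin_posterior(phase, G, ped, eps=0.01)
    # marginally the paternal chain is flat; jointly the het at marker 1
    # couples it to the anchored maternal chain
    assert abs(marg[2 * c, 1] - 0.5) < 1e-9
    assert joint[2 * c, 1] > 0.5 + 0.05
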