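"""MaCH-style Li-Stephens haplotype HMM.

A gamete (haploid model) or an unphased genotype (diploid model) is
explained as a mosaic of template haplotypes H.  Hidden states are
template indices (haploid) or ordered pairs S_i = (h_i, k_i) (diploid,
|H|^2 states).  Transitions follow the classic Li-Stephens form: between
markers i and i+1 a gamete stays on its template or, with crossover
probability theta_i, jumps and lands uniformly on one of the |H|
templates.  Emissions flip each read allele independently with the
per-marker error probability eps_i.  Both parameter vectors start at 0.01
and are re-estimated each iteration from the sampled mosaics.

The factorised transition keeps a diploid forward step at O(|H|^2)
instead of O(|H|^4); runs of markers with no observation collapse
exactly into an effective stay probability, and closed-form "bridge"
formulas recover per-marker allele probabilities inside those runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iodata import MISSING
from ._kernels import diploid_obs_pass, haploid_pass

__all__ = [
    "HMMParams",
    "SampledMosaic",
    "ParamCounts",
    "init_params",
    "transition_weight",
    "emission_haploid",
    "emission_diploid",
    "genotype_emission_table",
    "forward_backward_haploid",
    "forward_backward_diploid",
    "sample_path_haploid",
    "initial_guess",
    "update_params",
    "consensus_pair",
    "HaploidUpdate",
    "DiploidUpdate",
    "haploid_update",
    "diploid_update",
]

PARAM_INIT = 0.01
PARAM_MIN = 1e-6
PARAM_MAX = 0.5


@dataclass
class HMMParams:
    """Crossover parameters theta (M-1) and error parameters eps (M)."""

    theta: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.clip(np.asarray(self.theta, dtype=float), 0.0, 1.0)
        self.eps = np.clip(np.asarray(self.eps, dtype=float), 0.0, 0.5)

    @property
    def M(self) -> int:
        return len(self.eps)


def init_params(M: int) -> HMMParams:
    """All crossover and error parameters start at 0.01."""
    if M < 2:
        raise ValueError("the HMM needs at least two markers")
    return HMMParams(np.full(M - 1, PARAM_INIT), np.full(M, PARAM_INIT))


def transition_weight(theta_i: float, same: bool, H_size: int) -> float:
    """Per-gamete transition probability between specific templates."""
    j = theta_i / H_size
    return (1.0 - theta_i) + j if same else j


def emission_haploid(observed_allele: int, template_allele: int, eps_i: float) -> float:
    if observed_allele == MISSING:
        return 1.0
    return 1.0 - eps_i if observed_allele == template_allele else eps_i


def emission_diploid(
    observed_genotype: int, template_alleles: tuple[int, int], eps_i: float
) -> float:
    """P(observed genotype | template pair), each read flipped independently."""
    if observed_genotype == MISSING:
        return 1.0
    a, b = template_alleles
    p = 0.0
    for fa in (0, 1):
        for fb in (0, 1):
            ra = a ^ fa
            rb = b ^ fb
            if ra + rb == observed_genotype:
                p += (eps_i if fa else 1 - eps_i) * (eps_i if fb else 1 - eps_i)
    return p


def genotype_emission_table(observed_genotype: int, eps_i: float) -> np.ndarray:
    """2x2 emission weights indexed by the two template alleles."""
    W = np.empty((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            W[a, b] = emission_diploid(observed_genotype, (a, b), eps_i)
    return W


def halfcall_emission_table(
    paternal_call: int, maternal_call: int, eps_i: float
) -> np.ndarray:
    """Emission weights when only per-gamete allele calls constrain a locus
    (9 = unconstrained side)."""
    wp = np.ones(2)
    wm = np.ones(2)
    if paternal_call != MISSING:
        wp = np.array(
            [emission_haploid(paternal_call, 0, eps_i), emission_haploid(paternal_call, 1, eps_i)]
        )
    if maternal_call != MISSING:
        wm = np.array(
            [emission_haploid(maternal_call, 0, eps_i), emission_haploid(maternal_call, 1, eps_i)]
        )
    return np.outer(wp, wm)


def forward_backward_haploid(
    obs: np.ndarray, templates: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Exact per-marker posteriors over templates and the log-likelihood.

    ``templates`` is (H, M); the prior is uniform over templates at the
    first marker.  Reference numpy implementation; the numba kernel used in
    production shares the identical recursion.
    """
    H, M = templates.shape
    if H < 2:
        raise ValueError("need at least two template haplotypes")
    At = templates.T
    E = np.where(
        (obs[:, None] == MISSING),
        1.0,
        np.where(At == obs[:, None], 1.0 - params.eps[:, None], params.eps[:, None]),
    )
    F = np.empty((M, H))
    loglik = 0.0
    F[0] = E[0] / H
    c = F[0].sum()
    if c <= 0:
        raise FloatingPointError("zero forward vector")
    loglik += np.log(c)
    F[0] /= c
    for t in range(1, M):
        s = 1.0 - params.theta[t - 1]
        j = params.theta[t - 1] / H
        F[t] = (s * F[t - 1] + j) * E[t]
        c = F[t].sum()
        if c <= 0:
            raise FloatingPointError("zero forward vector")
        loglik += np.log(c)
        F[t] /= c
    B = np.ones(H)
    post = np.empty((M, H))
    post[M - 1] = F[M - 1]
    for t in range(M - 2, -1, -1):
        s = 1.0 - params.theta[t]
        j = params.theta[t] / H
        eb = E[t + 1] * B
        B = s * eb + j * eb.sum()
        w = F[t] * B
        tot = w.sum()
        post[t] = w / tot
        B /= tot
    return post, loglik


def forward_backward_diploid(
    obs: np.ndarray, templates: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Pair-state posteriors (M, H, H) and log-likelihood for a genotype row.

    Uses the factorised transition so each step costs O(|H|^2); intended
    for moderate problem sizes (posterior storage is M |H|^2).
    """
    H, M = templates.shape
    At = templates.T
    F = np.empty((M, H, H))
    loglik = 0.0
    W0 = genotype_emission_table(int(obs[0]), params.eps[0])
    F[0] = W0[At[0][:, None], At[0][None, :]] / (H * H)
    c = F[0].sum()
    loglik += np.log(c)
    F[0] /= c
    for t in range(1, M):
        s = 1.0 - params.theta[t - 1]
        j = params.theta[t - 1] / H
        prev = F[t - 1]
        rs = prev.sum(axis=1)
        cs = prev.sum(axis=0)
        pred = s * s * prev + s * j * (rs[:, None] + cs[None, :]) + j * j
        W = genotype_emission_table(int(obs[t]), params.eps[t])
        F[t] = pred * W[At[t][:, None], At[t][None, :]]
        c = F[t].sum()
        loglik += np.log(c)
        F[t] /= c
    B = np.ones((H, H))
    post = np.empty((M, H, H))
    post[M - 1] = F[M - 1]
    for t in range(M - 2, -1, -1):
        s = 1.0 - params.theta[t]
        j = params.theta[t] / H
        W = genotype_emission_table(int(obs[t + 1]), params.eps[t + 1])
        eb = W[At[t + 1][:, None], At[t + 1][None, :]] * B
        rs = eb.sum(axis=1)
        cs = eb.sum(axis=0)
        B = s * s * eb + s * j * (rs[:, None] + cs[None, :]) + j * j * eb.sum()
        w = F[t] * B
        tot = w.sum()
        post[t] = w / tot
        B /= tot
    return post, loglik


@dataclass
class SampledMosaic:
    """A sampled template path with its crossover indicators and alleles."""

    path: np.ndarray  # (M,) template indices
    jumps: np.ndarray  # (M-1,) crossover indicators
    alleles: np.ndarray  # (M,) implied template alleles


def sample_path_haploid(
    obs: np.ndarray, templates: np.ndarray, params: HMMParams, rng: np.random.Generator
) -> SampledMosaic:
    """Sample a template path from its exact posterior (backward traceback)."""
    H, M = templates.shape
    At = np.ascontiguousarray(templates.T)
    _, path, jumps, _ = haploid_pass(
        At,
        obs.astype(np.int8),
        params.theta,
        params.eps,
        rng.random(M),
        rng.random(max(M - 1, 1)),
    )
    return SampledMosaic(path=path, jumps=jumps, alleles=At[np.arange(M), path])


def initial_guess(
    obs: np.ndarray, allele_freq: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Initial haplotype pair: homozygotes fixed, heterozygotes phased at
    random, missing markers drawn from the population allele frequency."""
    M = len(obs)
    pair = np.empty((2, M), dtype=np.int8)
    hom0 = obs == 0
    hom2 = obs == 2
    het = obs == 1
    miss = obs == MISSING
    pair[:, hom0] = 0
    pair[:, hom2] = 1
    flip = rng.random(M) < 0.5
    pair[0, het] = flip[het]
    pair[1, het] = 1 - pair[0, het]
    draws = rng.random((2, M)) < allele_freq[None, :]
    pair[:, miss] = draws[:, miss]
    return pair


@dataclass
class ParamCounts:
    """Sufficient statistics for one iteration's parameter update."""

    jumps: np.ndarray
    transitions: np.ndarray
    mismatches: np.ndarray
    comparisons: np.ndarray

    @classmethod
    def zeros(cls, M: int) -> "ParamCounts":
        return cls(
            np.zeros(M - 1), np.zeros(M - 1), np.zeros(M), np.zeros(M)
        )

    def add_haploid(self, mosaic: SampledMosaic, obs: np.ndarray) -> None:
        self.jumps += mosaic.jumps
        self.transitions += 1
        seen = obs != MISSING
        self.comparisons += seen
        self.mismatches += seen & (mosaic.alleles != obs)

    def to_params(self) -> HMMParams:
        theta = (self.jumps + 1.0) / (self.transitions + 2.0)
        eps = (self.mismatches + 1.0) / (self.comparisons + 2.0)
        return HMMParams(
            np.clip(theta, PARAM_MIN, PARAM_MAX), np.clip(eps, PARAM_MIN, PARAM_MAX)
        )


def update_params(
    mosaics: list[SampledMosaic], observations: list[np.ndarray], params: HMMParams
) -> HMMParams:
    """Re-estimate theta and eps from this iteration's sampled mosaics.

    theta_i <- (jumps in interval i + 1) / (gamete transitions + 2) and
    eps_i <- (observed-allele mismatches + 1) / (comparisons + 2); the
    Laplace smoothing keeps the estimates off absorbing bounds.
    """
    if not mosaics:
        raise ValueError("need at least one sampled mosaic")
    counts = ParamCounts.zeros(params.M)
    for mos, obs in zip(mosaics, observations):
        counts.add_haploid(mos, obs)
    return counts.to_params()


def consensus_pair(pairs: list[np.ndarray]) -> np.ndarray:
    """Consensus haplotype pair minimising total switch error.

    Per locus the consensus genotype is the majority of the sampled pair
    sums.  At consensus-heterozygous loci, the relative orientation between
    consecutive heterozygous sites is the majority across iterations (this
    interval-wise majority attains the exhaustive minimum of the summed
    switch disagreements because intervals are independent); the chain is
    anchored at the first heterozygous site by majority vote.  Gamete 1 of
    the result is the lexicographically smaller haplotype.
    """
    if not pairs:
        raise ValueError("need at least one sampled pair")
    P = np.stack(pairs)  # (R, 2, M)
    R, _, M = P.shape
    G = P.sum(axis=1)  # (R, M)
    counts = np.stack([(G == g).sum(axis=0) for g in (0, 1, 2)])
    gstar = counts.argmax(axis=0)
    out = np.empty((2, M), dtype=np.int8)
    hom = gstar != 1
    out[0, hom] = (gstar[hom] // 2).astype(np.int8)
    out[1, hom] = out[0, hom]
    het_sites = np.flatnonzero(gstar == 1)
    if het_sites.size:
        o = P[:, 0, het_sites]  # allele carried by gamete 1, per iteration
        valid = G[:, het_sites] == 1
        s0 = het_sites[0]
        v0 = valid[:, 0]
        anchor = 1 if (o[v0, 0].sum() * 2 >= v0.sum()) else 0
        orient = np.empty(het_sites.size, dtype=np.int8)
        orient[0] = anchor
        for k in range(1, het_sites.size):
            both = valid[:, k - 1] & valid[:, k]
            if both.any():
                flips = (o[both, k - 1] != o[both, k]).sum()
                d = 1 if flips * 2 > both.sum() else 0
            else:
                d = 0
            orient[k] = orient[k - 1] ^ d
        out[0, het_sites] = orient
        out[1, het_sites] = 1 - orient
    if list(out[1]) < list(out[0]):
        out = out[::-1].copy()
    return out


# ---------------------------------------------------------------------------
# production per-individual updates (condensed chains + closed-form bridges)
# ---------------------------------------------------------------------------


@dataclass
class HaploidUpdate:
    """Result of one haploid refinement of a gamete."""

    post1: np.ndarray  # (M,) posterior allele-1 probability
    mosaic: SampledMosaic
    loglik: float


def haploid_update(
    obs: np.ndarray,
    templates: np.ndarray,
    params: HMMParams,
    rng: np.random.Generator,
) -> HaploidUpdate:
    H, M = templates.shape
    At = np.ascontiguousarray(templates.T)
    post1, path, jumps, loglik = haploid_pass(
        At,
        obs.astype(np.int8),
        params.theta,
        params.eps,
        rng.random(M),
        rng.random(max(M - 1, 1)),
    )
    return HaploidUpdate(
        post1=post1,
        mosaic=SampledMosaic(path=path, jumps=jumps, alleles=At[np.arange(M), path]),
        loglik=loglik,
    )


@dataclass
class DiploidUpdate:
    """Result of one diploid refinement of an individual."""

    prob: np.ndarray  # (2, M) per-gamete allele-1 probabilities
    pair: np.ndarray  # (2, M) sampled hard haplotypes
    jumps: np.ndarray  # (2, M-1) sampled crossover indicators
    loglik: float


def _sample_gap_jumps(
    theta: np.ndarray, lo: int, hi: int, same_endpoint: bool, H: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample per-interval crossover indicators inside a gap [lo, hi) of
    intervals, conditional on the bridge endpoints.

    Conditioned on the endpoint pair, the jump pattern is a product of
    independent Bernoulli(theta_k) draws, conditioned on "no jump at all"
    when that is consistent (same endpoints) or on at least one jump
    (different endpoints); landings are uniform so intermediate states do
    not alter the pattern law.
    """
    th = theta[lo:hi]
    stay = np.prod(1.0 - th)
    out = np.zeros(hi - lo, dtype=np.int8)
    if same_endpoint:
        p_nojump = stay / (stay + (1.0 - stay) / H)
        if rng.random() < p_nojump:
            return out
    if stay >= 1.0:
        return out
    # sample the first jump position, then the rest unconditionally
    w = th * np.concatenate(([1.0], np.cumprod(1.0 - th[:-1])))
    tot = w.sum()
    if tot <= 0:
        return out
    first = rng.choice(len(th), p=w / tot)
    out[first] = 1
    rest = rng.random(len(th) - first - 1) < th[first + 1 :]
    out[first + 1 :] = rest
    return out


def diploid_update(
    genotype_row: np.ndarray,
    half_calls: np.ndarray,
    templates: np.ndarray,
    params: HMMParams,
    rng: np.random.Generator,
) -> DiploidUpdate:
    """One diploid refinement: condensed forward pass over informative
    markers, pair sampling, and closed-form bridge fill-in between them.

    ``half_calls`` is the (2, M) heuristic per-gamete call matrix (9 where
    uncalled); loci with a heuristic call but no usable genotype constrain
    the emission of the corresponding gamete only.
    """
    H, M = templates.shape
    At = np.ascontiguousarray(templates.T)
    abar = At.mean(axis=1)
    g = genotype_row
    has_geno = g != MISSING
    has_half = (half_calls[0] != MISSING) | (half_calls[1] != MISSING)
    informative = np.flatnonzero(has_geno | has_half)
    theta = params.theta
    cp = np.concatenate(([1.0], np.cumprod(1.0 - theta)))  # (M,) prefix stay

    if informative.size == 0:
        prob = np.vstack([abar, abar])
        pair = (rng.random((2, M)) < prob).astype(np.int8)
        jumps = (rng.random((2, M - 1)) < theta).astype(np.int8)
        return DiploidUpdate(prob=prob, pair=pair, jumps=jumps, loglik=0.0)

    T = informative.size
    W = np.empty((T, 2, 2))
    for t, m in enumerate(informative):
        if has_geno[m]:
            W[t] = genotype_emission_table(int(g[m]), params.eps[m])
            for side in (0, 1):
                c = half_calls[side, m]
                if c != MISSING:
                    wv = np.array(
                        [
                            emission_haploid(int(c), 0, params.eps[m]),
                            emission_haploid(int(c), 1, params.eps[m]),
                        ]
                    )
                    W[t] *= wv[:, None] if side == 0 else wv[None, :]
        else:
            W[t] = halfcall_emission_table(
                int(half_calls[0, m]), int(half_calls[1, m]), params.eps[m]
            )
    s_gap = cp[informative[1:]] / cp[informative[:-1]]
    A_obs = np.ascontiguousarray(At[informative])
    states, loglik = diploid_obs_pass(A_obs, W, s_gap, rng.random((T, 3)))

    prob = np.empty((2, M))
    pair = np.empty((2, M), dtype=np.int8)
    jumps = np.zeros((2, M - 1), dtype=np.int8)
    markers = np.arange(M)
    pos = np.searchsorted(informative, markers, side="left")
    at_obs = np.zeros(M, dtype=bool)
    at_obs[informative] = True
    for side in (0, 1):
        sh = states[:, side]
        p = np.empty(M)
        # at informative markers the sampled template allele is the estimate
        p[informative] = At[informative, sh]
        interior = ~at_obs & (pos > 0) & (pos < T)
        if np.any(interior):
            mi = markers[interior]
            li = informative[pos[interior] - 1]
            ri = informative[pos[interior]]
            ha = sh[pos[interior] - 1]
            hb = sh[pos[interior]]
            sL = cp[mi] / cp[li]
            sR = cp[ri] / cp[mi]
            jL = (1.0 - sL) / H
            jR = (1.0 - sR) / H
            same = (ha == hb).astype(float)
            aL = At[mi, ha]
            aR = At[mi, hb]
            num = (
                sL * sR * same * aL
                + sL * jR * aL
                + jL * sR * aR
                + jL * jR * H * abar[mi]
            )
            den = sL * sR * same + sL * jR + jL * sR + jL * jR * H
            p[interior] = num / den
        before = markers < informative[0]
        if np.any(before):
            mi = markers[before]
            sR = cp[informative[0]] / cp[mi]
            p[before] = sR * At[mi, sh[0]] + (1.0 - sR) * abar[mi]
        after = markers > informative[-1]
        if np.any(after):
            mi = markers[after]
            sL = cp[mi] / cp[informative[-1]]
            p[after] = sL * At[mi, sh[-1]] + (1.0 - sL) * abar[mi]
        prob[side] = p
        # exact path sample through each gap: the sampled jump pattern cuts
        # the gap into segments; the first segment keeps the left state, the
        # last carries the right state, and every segment in between lands
        # uniformly on a template
        state = np.empty(M, dtype=np.int64)
        state[informative] = sh
        for t in range(T - 1):
            lo, hi = int(informative[t]), int(informative[t + 1])
            patt = _sample_gap_jumps(theta, lo, hi, bool(sh[t] == sh[t + 1]), H, rng)
            jumps[side, lo:hi] = patt
            if hi - lo > 1:
                _fill_gap_states(
                    state, lo, hi, int(sh[t]), int(sh[t + 1]), patt, H, rng
                )
        if informative[0] > 0:
            hi = int(informative[0])
            patt = (rng.random(hi) < theta[:hi]).astype(np.int8)
            jumps[side, :hi] = patt
            _fill_edge_states(state, 0, hi, int(sh[0]), patt, H, rng, left_edge=True)
        if informative[-1] < M - 1:
            lo = int(informative[-1])
            patt = (rng.random(M - 1 - lo) < theta[lo:]).astype(np.int8)
            jumps[side, lo:] = patt
            _fill_edge_states(state, lo, M, int(sh[-1]), patt, H, rng, left_edge=False)
        pair[side] = At[markers, state]
    return DiploidUpdate(prob=prob, pair=pair, jumps=jumps, loglik=loglik)


def _fill_gap_states(
    state: np.ndarray,
    lo: int,
    hi: int,
    ha: int,
    hb: int,
    patt: np.ndarray,
    H: int,
    rng: np.random.Generator,
) -> None:
    """States at markers lo+1..hi-1 given endpoint states and the jump
    pattern over intervals lo..hi-1 (interval k sits between markers k and
    k+1)."""
    jpos = lo + np.flatnonzero(patt)
    if jpos.size == 0:
        state[lo + 1 : hi] = ha
        return
    cur = ha
    seg_start = lo + 1
    for k in jpos:
        state[seg_start : k + 1] = cur
        cur = int(rng.integers(H))
        seg_start = k + 1
    state[seg_start:hi] = hb  # the landing of the last jump is pinned


def _fill_edge_states(
    state: np.ndarray,
    lo: int,
    hi: int,
    anchor: int,
    patt: np.ndarray,
    H: int,
    rng: np.random.Generator,
    left_edge: bool,
) -> None:
    """States on a one-sided stretch; segments away from the anchor land
    uniformly."""
    if left_edge:
        # anchor at marker hi; walk left over intervals hi-1..lo
        jpos = lo + np.flatnonzero(patt)
        cur = anchor
        seg_end = hi  # exclusive
        for k in jpos[::-1]:
            state[k + 1 : seg_end] = cur
            cur = int(rng.integers(H))
            seg_end = k + 1
        state[lo:seg_end] = cur
    else:
        jpos = lo + np.flatnonzero(patt)
        cur = anchor
        seg_start = lo + 1
        for k in jpos:
            state[seg_start : k + 1] = cur
            cur = int(rng.integers(H))
            seg_start = k + 1
        state[seg_start:hi] = cur
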