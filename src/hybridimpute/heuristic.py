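"""Single-locus heuristic inference: Mendelian-inheritance rules and an
approximate single-locus segregation analysis (iterative peeling).

Both operate under the assumption that every locus is inherited
independently of its neighbours; linkage is exploited later by the
long-range phasing / haplotype-library stage and by the HMM.

Ordered genotype probabilities are 4-vectors over the ordered allele
pairs (0,0), (0,1), (1,0), (1,1), first element = paternal allele.
"""

from __future__ import annotations

import logging

import numpy as np

from .iodata import MISSING, Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "mendelian_fill",
    "segregation_probs",
    "call_alleles",
    "allele_frequencies",
    "DEFAULT_CALL_THRESHOLD",
]

DEFAULT_CALL_THRESHOLD = 0.99

# ordered pair layout: index = 2*paternal + maternal
_PAIR_PAT = np.array([0, 0, 1, 1])
_PAIR_MAT = np.array([0, 1, 0, 1])


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Frequency of allele 1 per marker from non-missing genotypes."""
    obs = genotypes != MISSING
    cnt = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, genotypes, 0).sum(axis=0) / np.maximum(2 * cnt, 1)
    freq[cnt == 0] = 0.5
    return np.clip(freq, 1e-6, 1 - 1e-6)


def _transmitted_from_hom(parent_geno: np.ndarray) -> np.ndarray:
    """Transmitted allele where the parent is homozygous, else 9."""
    out = np.full(parent_geno.shape, MISSING, dtype=np.int8)
    out[parent_geno == 0] = 0
    out[parent_geno == 2] = 1
    return out


def mendelian_fill(
    genotypes: np.ndarray, pedigree: Pedigree, phase: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Apply basic Mendelian-inheritance rules to a fixed point.

    Rules, applied iteratively in pedigree order:

    a. a homozygous individual has both gamete alleles equal to its allele;
    b. a homozygous parent fixes the transmitted allele of each offspring;
    c. a heterozygote with one gamete known gets the other by subtraction;
    d. a missing genotype with both gamete alleles known becomes their sum;
    e. (b)+(d) fill a missing genotype when both parents are homozygous.

    Mendelian conflicts (e.g. opposing homozygous parent/offspring) set the
    offending offspring genotype and gametes to missing and are logged, in
    line with routine quality-control practice; observed genotypes are never
    altered otherwise.
    """
    G = genotypes.astype(np.int8, copy=True)
    n, M = G.shape
    P = (
        phase.astype(np.int8, copy=True)
        if phase is not None
        else np.full((2 * n, M), MISSING, dtype=np.int8)
    )
    conflict_logged = np.zeros((n, M), dtype=bool)
    n_conflicts = 0

    for _sweep in range(64):
        changed = False
        for i in range(n):
            g = G[i]
            pat = P[2 * i]
            mat = P[2 * i + 1]
            before = (g != MISSING).sum() + (pat != MISSING).sum() + (mat != MISSING).sum()

            # (a) homozygotes fix both gametes
            hom0 = g == 0
            hom2 = g == 2
            pat[hom0] = 0
            mat[hom0] = 0
            pat[hom2] = 1
            mat[hom2] = 1

            # (b) homozygous parents fix transmitted alleles
            conflict = np.zeros(M, dtype=bool)
            for side, p_idx in ((0, pedigree.sire_idx[i]), (1, pedigree.dam_idx[i])):
                if p_idx < 0:
                    continue
                trans = _transmitted_from_hom(G[p_idx])
                gam = pat if side == 0 else mat
                known = trans != MISSING
                fill = known & (gam == MISSING)
                gam[fill] = trans[fill]
                conflict |= known & (gam != MISSING) & (gam != trans)

            # observed genotype contradicting the two resolved gametes (e.g.
            # a heterozygous child of two identical homozygous parents)
            conflict |= (
                (g != MISSING)
                & (pat != MISSING)
                & (mat != MISSING)
                & (pat + mat != g)
            )

            if np.any(conflict):
                new = conflict & ~conflict_logged[i]
                n_conflicts += int(new.sum())
                conflict_logged[i] |= conflict
                g[conflict] = MISSING
                pat[conflict] = MISSING
                mat[conflict] = MISSING
                changed = True
                continue  # re-derive this individual on the next sweep

            # (c) heterozygote with one gamete known
            het = g == 1
            fix_mat = het & (pat != MISSING) & (mat == MISSING)
            mat[fix_mat] = 1 - pat[fix_mat]
            fix_pat = het & (mat != MISSING) & (pat == MISSING)
            pat[fix_pat] = 1 - mat[fix_pat]

            # (d) missing genotype with both gametes known
            both = (g == MISSING) & (pat != MISSING) & (mat != MISSING)
            g[both] = pat[both] + mat[both]

            after = (g != MISSING).sum() + (pat != MISSING).sum() + (mat != MISSING).sum()
            if after != before:
                changed = True
        if not changed:
            break

    if n_conflicts:
        logger.info("mendelian_fill: %d conflicting genotypes set to missing", n_conflicts)
    return G, P


def _genotype_likelihood(genotypes: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """(n, M, 4) indicator likelihood of each ordered pair given the data."""
    n, M = genotypes.shape
    L = np.ones((n, M, 4), dtype=float)
    g = genotypes
    pat = phase[0::2]
    mat = phase[1::2]
    pair_g = _PAIR_PAT + _PAIR_MAT  # genotype implied by each ordered pair
    for k in range(4):
        ok = (g == MISSING) | (g == pair_g[k])
        ok &= (pat == MISSING) | (pat == _PAIR_PAT[k])
        ok &= (mat == MISSING) | (mat == _PAIR_MAT[k])
        L[:, :, k] = ok
    return L


def _transmit_prob(Q: np.ndarray) -> np.ndarray:
    """P(parent transmits allele 1) from its ordered-pair distribution."""
    pat1 = Q[:, 2] + Q[:, 3]
    mat1 = Q[:, 1] + Q[:, 3]
    return 0.5 * (pat1 + mat1)


def segregation_probs(
    genotypes: np.ndarray,
    phase: np.ndarray,
    pedigree: Pedigree,
    allele_freq: np.ndarray,
    n_sweeps: int = 2,
) -> np.ndarray:
    """Approximate single-locus iterative peeling.

    Each individual's ordered-pair distribution is the normalised product of
    its genotype/phase likelihood, transmission priors from each parent's
    current marginal gamete distribution (population frequency for unknown
    parents), and an aggregated one-generation offspring term.  The pedigree
    is swept down then up ``n_sweeps`` times; loops (inbreeding) make this
    approximate rather than exact.

    Returns an (n, M, 4) array of normalised distributions.
    """
    n, M = genotypes.shape
    L = _genotype_likelihood(genotypes, phase)
    f = allele_freq
    founder_prior = np.stack(
        [(1 - f) * (1 - f), (1 - f) * f, f * (1 - f), f * f], axis=-1
    )  # (M, 4)

    Q = L * founder_prior[None, :, :]
    _normalise(Q, L)

    offspring = pedigree.offspring_of()
    child_term = np.ones((n, M, 4), dtype=float)

    for _ in range(n_sweeps):
        # downward: parents -> offspring
        for i in range(n):
            si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
            ts = _transmit_prob(Q[si]) if si >= 0 else f
            td = _transmit_prob(Q[di]) if di >= 0 else f
            prior = np.stack(
                [(1 - ts) * (1 - td), (1 - ts) * td, ts * (1 - td), ts * td], axis=-1
            )
            Q[i] = L[i] * prior * child_term[i]
            _normalise(Q[i : i + 1], L[i : i + 1])

        # upward: offspring -> parents (one-generation likelihood messages)
        for i in range(n - 1, -1, -1):
            kids = offspring.get(i)
            if not kids:
                continue
            term = np.ones((M, 4), dtype=float)
            for c in kids:
                is_sire = pedigree.sire_idx[c] == i
                oi = pedigree.dam_idx[c] if is_sire else pedigree.sire_idx[c]
                to = _transmit_prob(Q[oi]) if oi >= 0 else f
                # lam[t] = P(child data | this parent transmits t); the child
                # contributes its own observation only (one-generation message)
                Lc = L[c]
                if is_sire:
                    lam0 = (1 - to) * Lc[:, 0] + to * Lc[:, 1]
                    lam1 = (1 - to) * Lc[:, 2] + to * Lc[:, 3]
                else:
                    lam0 = (1 - to) * Lc[:, 0] + to * Lc[:, 2]
                    lam1 = (1 - to) * Lc[:, 1] + to * Lc[:, 3]
                norm = lam0 + lam1
                ok = norm > 0
                lam0 = np.where(ok, lam0 / np.where(ok, norm, 1.0), 0.5)
                lam1 = np.where(ok, lam1 / np.where(ok, norm, 1.0), 0.5)
                # parent pair (a,b) transmits a or b with probability 1/2
                gam = 0.5 * np.stack(
                    [
                        lam0 + lam0,
                        lam0 + lam1,
                        lam1 + lam0,
                        lam1 + lam1,
                    ],
                    axis=-1,
                )
                term *= gam
                term /= np.maximum(term.sum(axis=-1, keepdims=True), 1e-300)
            child_term[i] = term
            si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
            ts = _transmit_prob(Q[si]) if si >= 0 else f
            td = _transmit_prob(Q[di]) if di >= 0 else f
            prior = np.stack(
                [(1 - ts) * (1 - td), (1 - ts) * td, ts * (1 - td), ts * td], axis=-1
            )
            Q[i] = L[i] * prior * child_term[i]
            _normalise(Q[i : i + 1], L[i : i + 1])

    return Q


def _normalise(Q: np.ndarray, L: np.ndarray) -> None:
    """Normalise in place; zero-normaliser cells fall back to the
    genotype-consistent uniform (and are logged)."""
    tot = Q.sum(axis=-1, keepdims=True)
    dead = tot[..., 0] <= 0
    if np.any(dead):
        logger.info("segregation: %d loci reset to genotype-consistent uniform", int(dead.sum()))
        Lsum = np.maximum(L.sum(axis=-1, keepdims=True), 1e-300)
        Q[dead] = (L / Lsum)[dead]
        tot = Q.sum(axis=-1, keepdims=True)
    Q /= np.maximum(tot, 1e-300)


def call_alleles(
    probs: np.ndarray, threshold: float = DEFAULT_CALL_THRESHOLD
) -> np.ndarray:
    """Hard-call gametes whose marginal allele probability reaches the
    threshold; everything else stays missing.

    ``probs`` is the (n, M, 4) ordered-pair array; returns a (2n, M) phase
    matrix.  Calls cannot contradict observed genotypes because the
    distributions are already genotype-consistent.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("call threshold must be in (0.5, 1]")
    n, M, _ = probs.shape
    pat1 = probs[:, :, 2] + probs[:, :, 3]
    mat1 = probs[:, :, 1] + probs[:, :, 3]
    phase = np.full((2 * n, M), MISSING, dtype=np.int8)
    for marg, rows in ((pat1, slice(0, None, 2)), (mat1, slice(1, None, 2))):
        out = phase[rows]
        out[marg >= threshold] = 1
        out[marg <= 1 - threshold] = 0
    return phase
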