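"""Orchestration of the hybrid imputation pipeline.

The hybrid method first runs the pedigree heuristics (Mendelian rules,
single-locus segregation analysis, long-range phasing, haplotype-library
imputation, recombination sweep), then hands whatever remains unresolved
to the Li-Stephens HMM.  Heuristically phased gametes populate the HMM's
template pool; thresholds decide, per run, how the HMM is trained and,
per individual, whether the haploid or the diploid model is used:

* training mode 1 - heuristics disabled: the HMM trains on genotypes
  (template pool = current haplotype estimates, re-sampled per iteration);
* training mode 2 - more than ``training_threshold`` of individuals are
  phased (>= ``phased_individual_fraction`` of markers on both gametes):
  templates come from the whole-chromosome resolved gametes;
* training mode 3 - otherwise: both sources, each individual entering
  once, haplotypes taking precedence.

Imputation mode is haploid for individuals whose gametes the heuristics
imputed beyond ``haploid_imputation_threshold``, else diploid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import heuristic, hmm, phasing
from .iodata import MISSING, ImputationResult, MarkerMap, Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "HybridConfig",
    "HeuristicResult",
    "ModeDecision",
    "count_phased_gametes",
    "select_training_mode",
    "select_imputation_mode",
    "build_training_set",
    "heuristic_stage",
    "run_hybrid",
]


@dataclass
class HybridConfig:
    """Run configuration; defaults follow the published parameter settings."""

    n_templates: int = 200
    n_iterations: int = 20
    burn_in: int = 5
    training_threshold: float = 0.50
    phased_individual_fraction: float = 0.99
    haploid_imputation_threshold: float = 0.90
    heuristics_enabled: bool = True
    hmm_enabled: bool = True
    seed: int = 0
    core_lengths: list[int] | None = None
    n_heuristic_iterations: int = 5
    min_surrogate_overlap: int = 50
    call_threshold: float = heuristic.DEFAULT_CALL_THRESHOLD
    impute_ids: list[str] | None = None
    n_reference_updates: int | None = 64
    max_halfcall_markers: int = 64

    def __post_init__(self) -> None:
        for name in (
            "training_threshold",
            "phased_individual_fraction",
            "haploid_imputation_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.hmm_enabled and not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")


@dataclass
class ModeDecision:
    training_mode: int
    imputation_mode: dict[int, int]  # individual row -> 1 (haploid) / 2 (diploid)


@dataclass
class HeuristicResult:
    """Output of the heuristic stage."""

    genotypes: np.ndarray  # heuristically completed genotypes (n x M)
    phase: np.ndarray  # per-gamete calls (2n x M)
    sweep_probs: np.ndarray  # recombination-interval allele probs (NaN elsewhere)
    seg_marginals: np.ndarray  # (2n x M) final segregation allele-1 marginals
    allele_freq: np.ndarray


def count_phased_gametes(
    phase: np.ndarray, fraction: float
) -> tuple[float, np.ndarray]:
    """Fraction of individuals phased (both gametes >= ``fraction``
    non-missing, inclusive) and the boolean per-individual indicator."""
    n = phase.shape[0] // 2
    res = (phase != MISSING).mean(axis=1)
    phased = (res[0::2] >= fraction) & (res[1::2] >= fraction)
    return float(phased.mean()) if n else 0.0, phased


def select_training_mode(config: HybridConfig, phased_fraction: float) -> int:
    if not config.heuristics_enabled:
        return 1
    return 2 if phased_fraction > config.training_threshold else 3


def select_imputation_mode(
    row: int, phase: np.ndarray, threshold: float
) -> int:
    """1 (haploid) when the heuristics imputed more than the threshold
    fraction of the individual's gamete alleles, else 2 (diploid)."""
    frac = (phase[2 * row : 2 * row + 2] != MISSING).mean()
    return 1 if frac > threshold else 2


@dataclass
class TrainingSet:
    """Template pool for the HMM: a (P x M) haplotype matrix plus the
    owning individual row of each pool haplotype (to exclude a proband's
    own gametes from its template draws)."""

    pool: np.ndarray
    owner: np.ndarray
    dynamic_rows: dict[int, tuple[int, int]] = field(default_factory=dict)
    # individual row -> (pool row of gamete 1, pool row of gamete 2) for
    # individuals whose estimates are refreshed each iteration (modes 1/3)


def build_training_set(
    mode: int,
    phase: np.ndarray,
    genotypes: np.ndarray,
    allele_freq: np.ndarray,
    rng: np.random.Generator,
) -> TrainingSet:
    """Assemble the template pool for the chosen training mode.

    Mode 1 uses every individual's current haplotype estimate (initialised
    from its genotypes).  Mode 2 uses whole-chromosome resolved gametes
    from the heuristic stage.  Mode 3 combines both with per-individual
    exclusivity, haplotypes taking precedence.
    """
    n, M = genotypes.shape
    resolved = ~np.any(phase == MISSING, axis=1)  # per gamete row
    pool_rows: list[np.ndarray] = []
    owners: list[int] = []
    dynamic: dict[int, tuple[int, int]] = {}

    def add_genotype_individuals(rows: np.ndarray) -> None:
        for r in rows:
            pair = hmm.initial_guess(genotypes[r], allele_freq, rng)
            dynamic[int(r)] = (len(pool_rows), len(pool_rows) + 1)
            pool_rows.append(pair[0])
            pool_rows.append(pair[1])
            owners.extend([int(r), int(r)])

    if mode == 1:
        add_genotype_individuals(np.arange(n))
    else:
        has_resolved = resolved[0::2] | resolved[1::2]
        for r in np.flatnonzero(has_resolved):
            for side in (0, 1):
                if resolved[2 * r + side]:
                    pool_rows.append(phase[2 * r + side])
                    owners.append(int(r))
        if mode == 3:
            add_genotype_individuals(np.flatnonzero(~has_resolved))
    if len(pool_rows) < 2:
        raise ValueError("template pool has fewer than 2 haplotypes")
    return TrainingSet(
        pool=np.ascontiguousarray(np.vstack(pool_rows), dtype=np.int8),
        owner=np.array(owners, dtype=np.int64),
        dynamic_rows=dynamic,
    )


def _long_range_phase(
    genotypes: np.ndarray,
    pedigree: Pedigree,
    phase: np.ndarray,
    tilings: list[list[phasing.CoreDefinition]],
    min_overlap: int,
    min_voters: int = 2,
) -> np.ndarray:
    """Surrogate-parent phasing proposals for every proband with unresolved
    loci, across all core tilings (consensus applied by the caller)."""
    n, M = genotypes.shape
    prop = np.full((2 * n, M), MISSING, dtype=np.int8)
    dense = (genotypes != MISSING).mean(axis=1) >= 0.5
    cores_flat = [core for cores in tilings for core in cores]
    for i in range(n):
        if not dense[i]:
            continue
        g_p = genotypes[i]
        # voting can only resolve unphased heterozygous loci; homozygous loci
        # are handled by the Mendelian rules
        hetmiss = np.flatnonzero(
            (g_p == 1)
            & ((phase[2 * i] == MISSING) | (phase[2 * i + 1] == MISSING))
        )
        if hetmiss.size == 0:
            continue
        pat_cand, mat_cand = phasing._pedigree_side_candidates(pedigree, i)
        if not pat_cand and not mat_cand:
            continue
        all_c = sorted(set(pat_cand) | set(mat_cand))
        Gc = genotypes[all_c]
        opp = ((g_p == 0) & (Gc == 2)) | ((g_p == 2) & (Gc == 0))
        oc = np.zeros((len(all_c), M + 1), dtype=np.int32)
        np.cumsum(opp, axis=1, out=oc[:, 1:])
        both = (g_p != MISSING) & (Gc != MISSING)
        bc = np.zeros((len(all_c), M + 1), dtype=np.int32)
        np.cumsum(both, axis=1, out=bc[:, 1:])
        V1 = (Gc[:, hetmiss] == 2)
        V0 = (Gc[:, hetmiss] == 0)
        side_rows = (
            np.array([all_c.index(c) for c in pat_cand], dtype=np.int64),
            np.array([all_c.index(c) for c in mat_cand], dtype=np.int64),
        )
        # voted[side][allele][candidate, het locus]: the candidate is
        # homozygous for the allele there and eligible in some spanning core
        voted = [
            [np.zeros((len(all_c), hetmiss.size), dtype=bool) for _ in range(2)]
            for _ in range(2)
        ]
        for core in cores_flat:
            k0, k1 = np.searchsorted(hetmiss, (core.start, core.end))
            if k0 == k1:
                continue
            conf = oc[:, core.end] - oc[:, core.start]
            overlap = bc[:, core.end] - bc[:, core.start]
            need = min(min_overlap, core.length)
            elig = (conf == 0) & (overlap >= need)
            for side in (0, 1):
                rows = side_rows[side]
                rows = rows[elig[rows]]
                if rows.size == 0:
                    continue
                voted[side][1][rows[:, None], np.arange(k0, k1)] |= V1[rows][:, k0:k1]
                voted[side][0][rows[:, None], np.arange(k0, k1)] |= V0[rows][:, k0:k1]
        for side in (0, 1):
            n1 = voted[side][1].sum(axis=0)
            n0 = voted[side][0].sum(axis=0)
            # an allele needs at least two independent voters: in a closely
            # related population a single surrogate's shared segment can
            # descend through the other parent
            call1 = (n1 >= min_voters) & (n0 == 0)
            call0 = (n0 >= min_voters) & (n1 == 0)
            row = prop[2 * i + side]
            row[hetmiss[call1]] = 1
            row[hetmiss[call0]] = 0
    return prop


def heuristic_stage(
    genotypes: np.ndarray,
    pedigree: Pedigree,
    config: HybridConfig,
    positions_cm: np.ndarray | None = None,
) -> HeuristicResult:
    """Run the iterated heuristic rules and return calls, sweep dosages and
    final segregation marginals."""
    n, M = genotypes.shape
    G = genotypes.astype(np.int8, copy=True)
    P = np.full((2 * n, M), MISSING, dtype=np.int8)
    tilings = phasing.build_cores(M, config.core_lengths)
    library = phasing.HaplotypeLibrary()
    sweep_probs = np.full((2 * n, M), np.nan)
    freq = heuristic.allele_frequencies(genotypes)
    gamete_rows = np.arange(2 * n)
    parent_rows = np.empty(2 * n, dtype=np.int64)
    parent_rows[0::2] = pedigree.sire_idx
    parent_rows[1::2] = pedigree.dam_idx

    for it in range(config.n_heuristic_iterations):
        G, P = heuristic.mendelian_fill(G, pedigree, P)
        Q = heuristic.segregation_probs(G, P, pedigree, freq)
        calls = heuristic.call_alleles(Q, config.call_threshold)
        fresh = (P == MISSING) & (calls != MISSING)
        P[fresh] = calls[fresh]
        G, P = heuristic.mendelian_fill(G, pedigree, P)

        lrp = _long_range_phase(G, pedigree, P, tilings, config.min_surrogate_overlap)
        P = phasing.cross_core_consensus([lrp], P)
        G, P = heuristic.mendelian_fill(G, pedigree, P)

        library = phasing.build_library(P, tilings, library)
        prop = np.full((2 * n, M), MISSING, dtype=np.int8)
        veto = np.zeros((2 * n, M), dtype=bool)
        for cores in tilings:
            phasing.batch_library_impute(
                P, library, cores, gamete_rows, prop=prop, veto=veto
            )
            phasing.batch_library_impute(
                P, library, cores, gamete_rows, parent_rows, P, prop=prop, veto=veto
            )
        prop[veto] = MISSING
        P_new = phasing.cross_core_consensus([prop], P)
        P = _guard_genotype_consistency(P_new, P, G)
        G, P = heuristic.mendelian_fill(G, pedigree, P)

        # genotype-level pair imputation for individuals the per-gamete
        # route cannot reach (their heterozygous observed loci constrain
        # candidate pairs rather than single haplotypes)
        sparse = np.flatnonzero((G == MISSING).any(axis=1))
        if sparse.size:
            gprop = np.full((n, M), MISSING, dtype=np.int8)
            gveto = np.zeros((n, M), dtype=bool)
            for cores in tilings:
                phasing.pair_library_impute(
                    G, P, library, cores, sparse, gprop, gveto
                )
            gprop[gveto] = MISSING
            ok = (G == MISSING) & (gprop != MISSING)
            G[ok] = gprop[ok]
            G, P = heuristic.mendelian_fill(G, pedigree, P)

        P, sw = heuristic_sweep(P, pedigree, G, positions_cm)
        keep = ~np.isnan(sw)
        sweep_probs[keep] = sw[keep]
        G, P = heuristic.mendelian_fill(G, pedigree, P)

    # final pass re-estimates allele frequencies from the completed matrix:
    # imputed individuals now contribute, so the residual-fill prior tracks
    # the whole population rather than only the initially genotyped subset
    freq = heuristic.allele_frequencies(G)
    Q = heuristic.segregation_probs(G, P, pedigree, freq)
    calls = heuristic.call_alleles(Q, config.call_threshold)
    fresh = (P == MISSING) & (calls != MISSING)
    P[fresh] = calls[fresh]
    G, P = heuristic.mendelian_fill(G, pedigree, P)
    marg = np.empty((2 * n, M))
    marg[0::2] = Q[:, :, 2] + Q[:, :, 3]
    marg[1::2] = Q[:, :, 1] + Q[:, :, 3]

    # final multi-locus refinement of the sweep dosages: the chromosome-wide
    # grand-parental-origin posterior pools every informative locus, so the
    # weighted parental average stays calibrated across long uncalled runs
    post = phasing.joint_origin_posterior(P, genotypes, pedigree, positions_cm)
    parent = np.empty(2 * n, dtype=np.int64)
    parent[0::2] = pedigree.sire_idx
    parent[1::2] = pedigree.dam_idx
    pv = np.clip(parent, 0, None)
    pg1, pg2 = P[2 * pv], P[2 * pv + 1]
    cells = (
        (parent >= 0)[:, None]
        & (P == MISSING)
        & (pg1 != MISSING)
        & (pg2 != MISSING)
        & ~np.isnan(post)
    )
    weighted = post * pg1 + (1.0 - post) * pg2
    sweep_probs[cells] = weighted[cells]
    return HeuristicResult(
        genotypes=G, phase=P, sweep_probs=sweep_probs, seg_marginals=marg,
        allele_freq=freq,
    )


def heuristic_sweep(
    phase: np.ndarray,
    pedigree: Pedigree,
    genotypes: np.ndarray,
    positions_cm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    return phasing.recombination_sweep(phase, pedigree, genotypes, positions_cm)


def _guard_genotype_consistency(
    P_new: np.ndarray, P_old: np.ndarray, G: np.ndarray
) -> np.ndarray:
    """Retract fresh calls that would contradict a non-missing genotype."""
    out = P_new.copy()
    pat = out[0::2]
    mat = out[1::2]
    known = (pat != MISSING) & (mat != MISSING) & (G != MISSING)
    bad = known & (pat + mat != G)
    if np.any(bad):
        fresh_p = (P_old[0::2] == MISSING) & bad
        fresh_m = (P_old[1::2] == MISSING) & bad
        pat[fresh_p] = MISSING
        mat[fresh_m] = MISSING
    return out


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *key]))


def run_hybrid(
    pedigree: Pedigree,
    genotypes: np.ndarray,
    marker_map: MarkerMap | None = None,
    config: HybridConfig | None = None,
    heuristic_result: HeuristicResult | None = None,
) -> ImputationResult:
    """Impute all markers for all individuals.

    Runs the heuristic stage (unless disabled), selects training and
    imputation modes, iterates the HMM with burn-in, and merges the
    results: observed and heuristic alleles are retained verbatim, the HMM
    fills only what the heuristics left uncalled, and every
    (individual, marker) cell ends with a dosage.  Deterministic given the
    inputs and the seed.  A precomputed ``heuristic_result`` for the same
    inputs may be injected to share the heuristic stage across HMM
    parameter sweeps.
    """
    config = config or HybridConfig()
    n, M = genotypes.shape
    if marker_map is None:
        marker_map = MarkerMap.default(M)
    if marker_map.M != M:
        raise ValueError("marker map and genotype matrix disagree on M")
    freq = heuristic.allele_frequencies(genotypes)

    if config.heuristics_enabled:
        heur = heuristic_result or heuristic_stage(
            genotypes, pedigree, config, marker_map.positions_cm
        )
    else:
        heur = HeuristicResult(
            genotypes=genotypes.astype(np.int8, copy=True),
            phase=np.full((2 * n, M), MISSING, dtype=np.int8),
            sweep_probs=np.full((2 * n, M), np.nan),
            seg_marginals=np.repeat(freq[None, :], 2 * n, axis=0),
            allele_freq=freq,
        )

    phased_fraction, _ = count_phased_gametes(
        heur.phase, config.phased_individual_fraction
    )
    training_mode = select_training_mode(config, phased_fraction)

    hmm_out = None
    mode_map: dict[int, int] = {}
    if config.hmm_enabled:
        targets = np.flatnonzero(np.any(genotypes == MISSING, axis=1))
        if config.impute_ids is not None:
            wanted = pedigree.subset_rows(config.impute_ids)
            targets = np.intersect1d(targets, wanted)
        for r in targets:
            mode_map[int(r)] = (
                select_imputation_mode(
                    int(r), heur.phase, config.haploid_imputation_threshold
                )
                if config.heuristics_enabled
                else 2
            )
        hmm_out = _hmm_stage(
            heur, genotypes, freq, targets, mode_map, training_mode, config
        )
    decision = ModeDecision(training_mode=training_mode, imputation_mode=mode_map)
    logger.info(
        "training mode %d (phased fraction %.3f); %d HMM targets",
        training_mode,
        phased_fraction,
        len(mode_map),
    )
    return _merge(pedigree, genotypes, heur, hmm_out, decision, config)


@dataclass
class _HMMOutput:
    prob: dict[int, np.ndarray]  # row -> (2, M) mean allele-1 probabilities
    phase: dict[int, np.ndarray]  # row -> (2, M) consensus/rounded haplotypes


def _hmm_stage(
    heur: HeuristicResult,
    genotypes: np.ndarray,
    freq: np.ndarray,
    targets: np.ndarray,
    mode_map: dict[int, int],
    training_mode: int,
    config: HybridConfig,
) -> _HMMOutput:
    n, M = genotypes.shape
    if M < 2:
        raise ValueError("the HMM needs at least two markers")
    rng_pool = _rng_for(config.seed, 1)
    train = build_training_set(
        training_mode,
        heur.phase,
        heur.genotypes,
        freq,
        rng_pool,
    )
    pool = train.pool
    n_pool = pool.shape[0]
    params = hmm.init_params(M)
    retained = config.n_iterations - config.burn_in

    prob_acc: dict[int, np.ndarray] = {}
    pair_store: dict[int, list[np.ndarray]] = {}
    align_ref: dict[int, np.ndarray] = {}
    target_rows = sorted(mode_map)

    # the update iterations run over the whole population: besides the
    # imputation targets, reference individuals also re-sample their
    # mosaics each iteration and contribute crossover/error counts (their
    # fully observed chains anchor the parameters at markers the target
    # chains barely cover), and genotype-trained pool members refresh
    # their haplotype estimates; a per-iteration cap with deterministic
    # rotation bounds the cost
    extra = (set(train.owner.tolist()) | set(train.dynamic_rows)) - set(
        target_rows
    )
    # genotype-trained pool members must refresh every iteration (their
    # estimates ARE the template pool); the cap rotates only the static
    # phased references, whose sole contribution is parameter counts
    dynamic_extra = sorted(r for r in extra if r in train.dynamic_rows)
    static_extra = np.array(
        sorted(r for r in extra if r not in train.dynamic_rows), dtype=np.int64
    )
    if len(static_extra):
        static_extra = static_extra[rng_pool.permutation(len(static_extra))]
    ref_cap = config.n_reference_updates

    def extra_slice(it: int) -> list[int]:
        if len(static_extra) == 0:
            picked = []
        elif ref_cap is None or ref_cap >= len(static_extra):
            picked = [int(r) for r in static_extra]
        else:
            k = (it * ref_cap) % len(static_extra)
            rot = np.concatenate([static_extra[k:], static_extra[:k]])[:ref_cap]
            picked = [int(r) for r in rot]
        return dynamic_extra + picked

    for it in range(config.n_iterations):
        counts = hmm.ParamCounts.zeros(M)
        new_pool = pool.copy() if train.dynamic_rows else pool
        for r in target_rows + extra_slice(it):
            rng = _rng_for(config.seed, 2, it, r)
            own = np.flatnonzero(train.owner == r)
            avail = np.setdiff1d(np.arange(n_pool), own, assume_unique=False)
            H = min(config.n_templates, len(avail))
            if H < 2:
                raise ValueError("fewer than 2 template haplotypes available")
            rows = avail[rng.choice(len(avail), size=H, replace=False)]
            templates = pool[rows]
            is_target = r in mode_map
            is_dynamic = r in train.dynamic_rows
            mode = mode_map.get(r, 2)
            if not is_target and not is_dynamic:
                # phased reference individual: haploid passes over its
                # resolved gametes, counts only
                for p in own:
                    obs = pool[p]
                    upd = hmm.haploid_update(obs, templates, params, rng)
                    counts.add_haploid(upd.mosaic, obs)
                continue
            if (
                is_dynamic
                and not is_target
                and not np.any(genotypes[r] == MISSING)
            ):
                # genotype-trained pool member with complete genotypes: its
                # only freedom is the phase at heterozygous loci.  Each
                # gamete's template path is sampled from the homozygous
                # anchors alone (conditioning on the current heterozygote
                # orientations would enslave the paths to their own errors
                # as eps shrinks), then every heterozygous orientation is
                # resampled from the two paths' emission weights — two
                # haploid passes instead of a dense diploid one
                g_row = genotypes[r]
                hom_obs = np.where(
                    g_row == 1, MISSING, g_row // 2
                ).astype(np.int8)
                al = []
                for _ in (0, 1):
                    upd = hmm.haploid_update(hom_obs, templates, params, rng)
                    counts.add_haploid(upd.mosaic, hom_obs)
                    al.append(upd.mosaic.alleles)
                eps = params.eps
                w1 = np.where(al[0] == 1, 1 - eps, eps) * np.where(
                    al[1] == 0, 1 - eps, eps
                )
                w0 = np.where(al[0] == 0, 1 - eps, eps) * np.where(
                    al[1] == 1, 1 - eps, eps
                )
                first = rng.random(M) < w1 / (w1 + w0)
                a = np.where(g_row == 1, first, g_row // 2).astype(np.int8)
                p0, p1 = train.dynamic_rows[r]
                new_pool[p0] = a
                new_pool[p1] = (g_row - a).astype(np.int8)
                continue
            if is_target and mode == 1:
                post = np.empty((2, M))
                hard = np.empty((2, M), dtype=np.int8)
                for side in (0, 1):
                    obs = heur.phase[2 * r + side]
                    upd = hmm.haploid_update(obs, templates, params, rng)
                    counts.add_haploid(upd.mosaic, obs)
                    post[side] = upd.post1
                    hard[side] = upd.mosaic.alleles
            else:
                g_row = genotypes[r]
                half = np.full((2, M), MISSING, dtype=np.int8)
                if config.heuristics_enabled:
                    # heuristic calls at unobserved loci constrain the
                    # emission per gamete; they are thinned to a budget
                    # because calls the whole library agrees on carry little
                    # extra information for the chain, and the full set is
                    # retained verbatim in the merge anyway
                    hc = heur.phase[2 * r : 2 * r + 2]
                    only_half = g_row == MISSING
                    half[:, only_half] = hc[:, only_half]
                    idx = np.flatnonzero(np.any(half != MISSING, axis=0))
                    budget = config.max_halfcall_markers
                    if idx.size > budget > 0:
                        keep = idx[
                            np.unique(
                                np.round(
                                    np.linspace(0, idx.size - 1, budget)
                                ).astype(int)
                            )
                        ]
                        mask = np.ones(M, dtype=bool)
                        mask[keep] = False
                        half[:, mask] = MISSING
                upd = hmm.diploid_update(g_row, half, templates, params, rng)
                _add_diploid_counts(counts, upd, g_row, half)
                post = upd.prob
                hard = upd.pair
            if is_dynamic:
                p0, p1 = train.dynamic_rows[r]
                new_pool[p0] = hard[0]
                new_pool[p1] = hard[1]
            if is_target and it >= config.burn_in:
                if r not in prob_acc:
                    prob_acc[r] = np.zeros((2, M))
                    pair_store[r] = []
                    align_ref[r] = hard.copy()
                if mode == 2:
                    same = int((hard != align_ref[r]).sum())
                    swap = int((hard[::-1] != align_ref[r]).sum())
                    if swap < same:
                        post = post[::-1]
                        hard = hard[::-1]
                prob_acc[r] += post
                pair_store[r].append(hard.copy())
        pool = new_pool
        if target_rows or len(extra_rows):
            params = counts.to_params()

    prob_out: dict[int, np.ndarray] = {}
    phase_out: dict[int, np.ndarray] = {}
    for r in mode_map:
        prob = prob_acc[r] / retained
        prob_out[r] = prob
        if mode_map[r] == 2:
            phase_out[r] = hmm.consensus_pair(pair_store[r])
        else:
            phase_out[r] = (prob >= 0.5).astype(np.int8)
    return _HMMOutput(prob=prob_out, phase=phase_out)


def _add_diploid_counts(
    counts: hmm.ParamCounts,
    upd: hmm.DiploidUpdate,
    g_row: np.ndarray,
    half: np.ndarray,
) -> None:
    counts.jumps += upd.jumps[0] + upd.jumps[1]
    counts.transitions += 2
    seen = g_row != MISSING
    counts.comparisons += 2 * seen
    gs = upd.pair.sum(axis=0)
    counts.mismatches += np.where(seen, np.abs(gs - g_row), 0)
    for side in (0, 1):
        hc = half[side] != MISSING
        counts.comparisons += hc
        counts.mismatches += hc & (upd.pair[side] != half[side])


def _merge(
    pedigree: Pedigree,
    observed: np.ndarray,
    heur: HeuristicResult,
    hmm_out: _HMMOutput | None,
    decision: ModeDecision,
    config: HybridConfig,
) -> ImputationResult:
    n, M = observed.shape
    prob = np.full((2 * n, M), np.nan)
    prov = np.full((2 * n, M), ImputationResult.PROV_HMM, dtype=np.int8)
    phase = heur.phase.copy()

    # heuristic calls (incl. those forced by observed homozygotes)
    called = heur.phase != MISSING
    prob[called] = heur.phase[called]
    obs_geno = np.repeat(observed, 2, axis=0)
    hom_obs = (obs_geno == 0) | (obs_geno == 2)
    prov[called & hom_obs] = ImputationResult.PROV_OBSERVED
    prov[called & ~hom_obs] = ImputationResult.PROV_HEURISTIC

    # recombination-sweep modelled dosages: direct parental evidence about
    # the uncalled stretch, preferred over panel-based HMM inference
    sweep = ~np.isnan(heur.sweep_probs) & np.isnan(prob)
    prob[sweep] = heur.sweep_probs[sweep]
    prov[sweep] = ImputationResult.PROV_HEURISTIC

    # HMM fill for whatever is left
    if hmm_out is not None:
        for r, pr in hmm_out.prob.items():
            for side in (0, 1):
                row = 2 * r + side
                fill = np.isnan(prob[row])
                prob[row, fill] = pr[side][fill]
                miss = phase[row] == MISSING
                phase[row, miss] = hmm_out.phase[r][side][miss]

    # residual: segregation marginals
    left = np.isnan(prob)
    prob[left] = heur.seg_marginals[left]
    prov[left] = ImputationResult.PROV_HEURISTIC

    # observed genotypes are authoritative: pin dosage (and probabilities at
    # unphased observed heterozygotes).  Heuristically called genotypes whose
    # phase is unresolved (candidate-pair heterozygote calls) pin the dosage
    # the same way.
    pat, mat = prob[0::2], prob[1::2]
    obs_mask = observed != MISSING
    known = np.where(obs_mask, observed, heur.genotypes)
    known_mask = known != MISSING
    hom = known_mask & (known != 1)
    pat[hom] = known[hom] / 2.0
    mat[hom] = known[hom] / 2.0
    het = known_mask & (known == 1)
    p = 0.5 * (pat[het] + (1.0 - mat[het]))
    pat[het] = p
    mat[het] = 1.0 - p

    dosages = pat + mat
    np.clip(dosages, 0.0, 2.0, out=dosages)
    dosages[known_mask] = known[known_mask]

    genos = known.astype(np.int8, copy=True)
    if hmm_out is not None or not config.heuristics_enabled:
        unobs = ~known_mask
        genos[unobs] = np.clip(np.rint(dosages[unobs]), 0, 2).astype(np.int8)
    else:
        # heuristic-only: a genotype is called only when both alleles are
        pat_c, mat_c = phase[0::2], phase[1::2]
        both = (pat_c != MISSING) & (mat_c != MISSING) & ~known_mask
        genos[both] = (pat_c + mat_c)[both]

    return ImputationResult(
        ids=list(pedigree.ids),
        genotypes=genos,
        phase=phase,
        dosages=dosages,
        allele_probs=np.clip(prob, 0.0, 1.0),
        provenance=prov,
    )
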