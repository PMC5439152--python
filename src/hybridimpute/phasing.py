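"""Long-range phasing and haplotype-library imputation over multi-length
cores, plus the recombination sweep that smooths imputation near detected
crossovers.

The chromosome is tiled into cores (contiguous marker blocks) at several
lengths and two offsets per length.  Within a core, gametes are resolved
by surrogate-parent voting (individuals that share a haplotype with the
proband, detected by the absence of opposing homozygous genotypes), and
fully resolved core haplotypes populate a library.  Partially known
gametes are then completed from library candidates that are consistent
with their known alleles, committing an allele only when every candidate
— and every core tiling spanning the marker — agrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iodata import MISSING, Pedigree

__all__ = [
    "CoreDefinition",
    "HaplotypeLibrary",
    "SurrogateSet",
    "default_core_lengths",
    "build_cores",
    "count_opposing_homozygotes",
    "find_surrogates",
    "phase_by_surrogates",
    "build_library",
    "library_impute",
    "cross_core_consensus",
    "recombination_sweep",
]

DEFAULT_MIN_SURROGATE_OVERLAP = 50


@dataclass(frozen=True)
class CoreDefinition:
    """Half-open marker-index interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid core [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class SurrogateSet:
    """Surrogate-parent rows per gamete side of one proband."""

    paternal: list[int] = field(default_factory=list)
    maternal: list[int] = field(default_factory=list)

    def side(self, which: int) -> list[int]:
        return self.paternal if which == 0 else self.maternal


class HaplotypeLibrary:
    """Per-core sets of distinct fully resolved haplotypes with counts."""

    def __init__(self) -> None:
        self._cores: dict[tuple[int, int], dict[bytes, int]] = {}

    def insert(self, core: CoreDefinition, hap: np.ndarray) -> None:
        if np.any(hap == MISSING):
            raise ValueError("library haplotypes must be fully resolved")
        key = (core.start, core.end)
        entry = self._cores.setdefault(key, {})
        b = hap.astype(np.int8).tobytes()
        entry[b] = entry.get(b, 0) + 1

    def haplotypes(self, core: CoreDefinition) -> tuple[np.ndarray, np.ndarray]:
        """(K x L) haplotype matrix and the K occurrence counts for a core."""
        entry = self._cores.get((core.start, core.end), {})
        if not entry:
            return (
                np.zeros((0, core.length), dtype=np.int8),
                np.zeros(0, dtype=np.int64),
            )
        haps = np.frombuffer(b"".join(entry.keys()), dtype=np.int8).reshape(
            len(entry), core.length
        )
        return haps.copy(), np.array(list(entry.values()), dtype=np.int64)

    def size(self, core: CoreDefinition) -> int:
        return len(self._cores.get((core.start, core.end), {}))

    def total_count(self, core: CoreDefinition) -> int:
        return sum(self._cores.get((core.start, core.end), {}).values())


def default_core_lengths(M: int, lo: int = 500, hi: int = 9000, k: int = 10) -> list[int]:
    """Ten core lengths evenly log-spaced between 500 and 9000 markers,
    truncated to the chromosome and de-duplicated."""
    lengths = np.unique(
        np.minimum(np.round(np.geomspace(lo, hi, k)).astype(int), M)
    )
    return [int(v) for v in lengths if v >= 2]


def build_cores(
    M: int, core_lengths: list[int] | None = None, offsets: bool = True
) -> list[list[CoreDefinition]]:
    """Tile [0, M) for each core length (and, optionally, a half-length
    offset per length, so each marker is phased as part of cores spanning
    different neighbourhoods).  Returns one tiling per (length, offset)."""
    if core_lengths is None:
        core_lengths = default_core_lengths(M)
    tilings: list[list[CoreDefinition]] = []
    for L in core_lengths:
        if L < 2:
            raise ValueError("core length must be >= 2")
        offs = [0, L // 2] if (offsets and 0 < L // 2 < M) else [0]
        for o in offs:
            bounds = [0] + list(range(o if o else L, M, L)) + [M]
            bounds = sorted(set(b for b in bounds if 0 <= b <= M))
            cores = [
                CoreDefinition(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
            ]
            tilings.append(cores)
    return tilings


def count_opposing_homozygotes(
    g1: np.ndarray, g2: np.ndarray, region: CoreDefinition | None = None
) -> int:
    """Loci in the region where one row is 0 and the other 2."""
    sl = region.slice() if region else slice(None)
    a, b = g1[sl], g2[sl]
    return int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))


def _pedigree_side_candidates(pedigree: Pedigree, proband: int) -> tuple[list[int], list[int]]:
    """Candidate surrogate rows on the sire and dam sides: the parent, the
    parent's parents, and the parent's other offspring.

    A surrogate's vote is attributed to the gamete of its side, which is
    only sound when the candidate is connected to the proband exclusively
    through that parent: full sibs (connected through both parents) and
    candidates reachable on both sides are excluded.
    """
    sire = pedigree.sire_idx[proband]
    dam = pedigree.dam_idx[proband]
    sides: list[set[int]] = []
    offspring = pedigree.offspring_of()
    for p, other in ((sire, dam), (dam, sire)):
        cand: set[int] = set()
        if p >= 0:
            cand.add(int(p))
            for gp in (pedigree.sire_idx[p], pedigree.dam_idx[p]):
                if gp >= 0:
                    cand.add(int(gp))
            for c in offspring.get(int(p), []):
                if c == proband:
                    continue
                # exclude full sibs: they may share the other parent's
                # haplotype instead
                if other >= 0 and (
                    pedigree.sire_idx[c] == other or pedigree.dam_idx[c] == other
                ):
                    continue
                cand.add(int(c))
        sides.append(cand)
    shared = sides[0] & sides[1]
    return sorted(sides[0] - shared), sorted(sides[1] - shared)


def find_surrogates(
    proband: int,
    genotypes: np.ndarray,
    pedigree: Pedigree,
    region: CoreDefinition,
    min_overlap: int = DEFAULT_MIN_SURROGATE_OVERLAP,
) -> SurrogateSet:
    """Surrogate parents of a proband within a region.

    A surrogate shares a haplotype with the proband, which requires zero
    opposing homozygous loci in the region; candidates are connected to the
    proband through the sire side (sire, sire's parents, sire's other
    offspring) or the dam side.  A minimum number of jointly genotyped loci
    (or the whole region, if shorter) guards against spurious matches on
    sparse rows.
    """
    need = min(min_overlap, region.length)
    g_p = genotypes[proband, region.slice()]
    out = SurrogateSet()
    pat_cand, mat_cand = _pedigree_side_candidates(pedigree, proband)
    for cand, store in ((pat_cand, out.paternal), (mat_cand, out.maternal)):
        for c in cand:
            g_c = genotypes[c, region.slice()]
            overlap = int(np.sum((g_p != MISSING) & (g_c != MISSING)))
            if overlap < need:
                continue
            if count_opposing_homozygotes(genotypes[proband], genotypes[c], region) == 0:
                store.append(c)
    return out


def phase_by_surrogates(
    proband: int,
    side: int,
    surrogates: SurrogateSet,
    genotypes: np.ndarray,
    region: CoreDefinition,
) -> np.ndarray:
    """Resolve one gamete of the proband within a region by surrogate votes.

    Homozygous proband loci are called directly.  At heterozygous loci each
    surrogate that is homozygous votes for its allele (its shared haplotype
    must carry it); the allele is called only if at least one vote exists
    and all votes agree.  Everything else stays missing.
    """
    sl = region.slice()
    g = genotypes[proband, sl]
    hap = np.full(region.length, MISSING, dtype=np.int8)
    hap[g == 0] = 0
    hap[g == 2] = 1
    rows = surrogates.side(side)
    if rows:
        gs = genotypes[rows][:, sl]
        votes1 = (gs == 2).sum(axis=0)
        votes0 = (gs == 0).sum(axis=0)
        het = g == 1
        hap[het & (votes1 > 0) & (votes0 == 0)] = 1
        hap[het & (votes0 > 0) & (votes1 == 0)] = 0
    return hap


def build_library(
    phase: np.ndarray,
    tilings: list[list[CoreDefinition]],
    library: HaplotypeLibrary | None = None,
    gamete_rows: np.ndarray | None = None,
) -> HaplotypeLibrary:
    """Insert every fully resolved core haplotype into the (possibly
    pre-existing) library; duplicates merge with a count increment."""
    lib = library if library is not None else HaplotypeLibrary()
    rows = range(phase.shape[0]) if gamete_rows is None else gamete_rows
    for cores in tilings:
        for core in cores:
            block = phase[:, core.slice()]
            for r in rows:
                hap = block[r]
                if not np.any(hap == MISSING):
                    lib.insert(core, hap)
    return lib


def library_impute(
    gamete: np.ndarray,
    library: HaplotypeLibrary,
    core: CoreDefinition,
    restrict_to: np.ndarray | None = None,
) -> np.ndarray:
    """Complete a partial core haplotype from consistent library candidates.

    Candidates are the library haplotypes (or, if ``restrict_to`` is given,
    those rows of it — e.g. the parental gametes) that match the gamete at
    every known position.  A missing position is imputed iff all candidates
    agree there; no candidates leaves the gamete unchanged.
    """
    if restrict_to is not None:
        haps = np.asarray(restrict_to, dtype=np.int8).reshape(-1, core.length)
        haps = haps[~np.any(haps == MISSING, axis=1)]
    else:
        haps, _ = library.haplotypes(core)
    out = gamete.copy()
    if haps.shape[0] == 0:
        return out
    known = gamete != MISSING
    consistent = ~np.any(haps[:, known] != gamete[known][None, :], axis=1)
    cand = haps[consistent]
    if cand.shape[0] == 0:
        return out
    agree1 = np.all(cand == 1, axis=0)
    agree0 = np.all(cand == 0, axis=0)
    out[(~known) & agree1] = 1
    out[(~known) & agree0] = 0
    return out


def batch_library_impute(
    phase: np.ndarray,
    library: HaplotypeLibrary,
    cores: list[CoreDefinition],
    gamete_rows: np.ndarray,
    parent_rows: np.ndarray | None = None,
    parent_phase: np.ndarray | None = None,
    prop: np.ndarray | None = None,
    veto: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised library imputation proposals for many gametes at once.

    Accumulates into (and returns) a (2n x M) proposal matrix ``prop``
    (9 = no call) and a boolean ``veto`` matrix.  An allele is only a
    valid call if every core spanning the marker agrees: a core whose
    consistent candidates are split between the alleles, or which
    proposes the opposite allele, vetoes the position.  Passing the same
    ``prop``/``veto`` across several tilings (and across the general and
    the parent-restricted route) therefore realises agreement across all
    spanning cores; callers must clear ``prop`` where ``veto`` is set
    before committing.

    When ``parent_rows`` maps each gamete row to the parent's individual
    row (or -1), candidates are restricted to the parent's two core
    haplotypes where these are fully resolved; otherwise the whole
    library is used.
    """
    n2, M = phase.shape
    if prop is None:
        prop = np.full((n2, M), MISSING, dtype=np.int8)
    if veto is None:
        veto = np.zeros((n2, M), dtype=bool)
    for core in cores:
        sl = core.slice()
        block = phase[gamete_rows][:, sl]
        needy = np.any(block == MISSING, axis=1)
        if not np.any(needy):
            continue
        rows = gamete_rows[needy]
        blk = block[needy].astype(np.int16)
        if parent_rows is not None and parent_phase is not None:
            pr = parent_rows[rows]
            has_p = pr >= 0
            if not np.any(has_p):
                continue
            rows = rows[has_p]
            blk = blk[has_p]
            pr = pr[has_p]
            pg1 = parent_phase[2 * pr][:, sl].astype(np.int16)
            pg2 = parent_phase[2 * pr + 1][:, sl].astype(np.int16)
            known = blk != MISSING
            miss = ~known
            ok1 = ~np.any(pg1 == MISSING, axis=1) & ~np.any(
                known & (blk != pg1), axis=1
            )
            ok2 = ~np.any(pg2 == MISSING, axis=1) & ~np.any(
                known & (blk != pg2), axis=1
            )
            call = np.full(blk.shape, MISSING, dtype=np.int8)
            both_ok = (ok1 & ok2)[:, None] & miss
            agree = both_ok & (pg1 == pg2)
            call[agree] = pg1[agree]
            split = both_ok & (pg1 != pg2)
            one = (ok1 & ~ok2)[:, None] & miss
            call[one] = pg1[one]
            two = (ok2 & ~ok1)[:, None] & miss
            call[two] = pg2[two]
        else:
            # a core where nothing is known about the gamete cannot filter
            # candidates: it carries no evidence, so it abstains entirely
            # rather than vetoing every polymorphic position
            informed = np.any(blk != MISSING, axis=1)
            if not np.any(informed):
                continue
            rows = rows[informed]
            blk = blk[informed]
            haps, _ = library.haplotypes(core)
            if haps.shape[0] == 0:
                continue
            A0 = (blk == 0).astype(np.float32)
            A1 = (blk == 1).astype(np.float32)
            H0 = (haps == 0).astype(np.float32)
            H1 = (haps == 1).astype(np.float32)
            mism = A0 @ H1.T + A1 @ H0.T  # (R, K)
            C = mism == 0
            ncand = C.sum(axis=1)
            S1 = C.astype(np.float32) @ H1  # candidate allele-1 sums, (R, L)
            all1 = S1 == ncand[:, None]
            all0 = S1 == 0
            missing = blk == MISSING
            call = np.full(blk.shape, MISSING, dtype=np.int8)
            ok = (ncand > 0)[:, None] & missing
            call[ok & all1] = 1
            call[ok & all0] = 0
            split = ok & ~all1 & ~all0
        cur = prop[rows, sl]
        fresh = (call != MISSING) & (cur == MISSING)
        clash = (call != MISSING) & (cur != MISSING) & (cur != call)
        cur[fresh] = call[fresh]
        prop[rows, sl] = cur
        veto[rows, sl] = veto[rows, sl] | clash | split
    return prop, veto


def _merge_proposal(current: np.ndarray, res: np.ndarray, orig: np.ndarray) -> np.ndarray:
    new_call = (res != MISSING) & (orig == MISSING)
    out = current.copy()
    fresh = new_call & (current == MISSING)
    out[fresh] = res[fresh]
    clash = new_call & (current != MISSING) & (current != res)
    out[clash] = MISSING
    return out


def cross_core_consensus(
    proposals: list[np.ndarray], base_phase: np.ndarray
) -> np.ndarray:
    """Commit an allele iff every tiling that called it agrees.

    ``proposals`` holds one (2n x M) call matrix per tiling (9 = no call);
    already-resolved alleles in ``base_phase`` are kept as-is.
    """
    out = base_phase.copy()
    votes0 = np.zeros(base_phase.shape, dtype=np.int16)
    votes1 = np.zeros(base_phase.shape, dtype=np.int16)
    for prop in proposals:
        votes0 += prop == 0
        votes1 += prop == 1
    unres = base_phase == MISSING
    out[unres & (votes1 > 0) & (votes0 == 0)] = 1
    out[unres & (votes0 > 0) & (votes1 == 0)] = 0
    return out


def pair_library_impute(
    genotypes: np.ndarray,
    phase: np.ndarray,
    library: HaplotypeLibrary,
    cores: list[CoreDefinition],
    indiv_rows: np.ndarray,
    prop: np.ndarray | None = None,
    veto: np.ndarray | None = None,
    max_het: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype imputation from candidate haplotype *pairs* per core.

    For an individual with observed genotypes in a core, the candidate
    ordered pairs are all library haplotype pairs consistent with the
    observed genotypes (homozygous loci filter each haplotype directly;
    heterozygous loci require the pair to carry complementary alleles)
    and with any per-gamete calls.  A missing genotype is proposed where
    every candidate pair implies the same allele dosage; a core whose
    candidate pairs disagree vetoes the position, and a core with no
    observed genotype for the individual abstains.

    Candidate pairs are never enumerated: haplotypes are grouped by their
    allele signature over the heterozygous loci (skipped beyond
    ``max_het`` of them), and the reachable dosage range per marker is
    the min/max over complementary signature-group pairs, which factorise
    over the two sides.

    Accumulates into (and returns) an (n x M) proposal matrix ``prop``
    (9 = no call) and a boolean ``veto``; callers clear vetoed proposals
    before committing, as with :func:`batch_library_impute`.
    """
    n, M = genotypes.shape
    if prop is None:
        prop = np.full((n, M), MISSING, dtype=np.int8)
    if veto is None:
        veto = np.zeros((n, M), dtype=bool)
    for core in cores:
        sl = core.slice()
        haps, _ = library.haplotypes(core)
        K = haps.shape[0]
        if K == 0:
            continue
        Hb = haps.astype(bool)
        for i in indiv_rows:
            g = genotypes[i, sl]
            miss = g == MISSING
            if not np.any(miss) or np.all(miss):
                continue
            het = np.flatnonzero(g == 1)
            if het.size > max_het:
                continue
            cons_a = np.ones(K, dtype=bool)
            hom0 = g == 0
            if np.any(hom0):
                cons_a &= ~Hb[:, hom0].any(axis=1)
            hom2 = g == 2
            if np.any(hom2):
                cons_a &= Hb[:, hom2].all(axis=1)
            cons_b = cons_a.copy()
            pa = phase[2 * i, sl]
            ca = pa != MISSING
            if np.any(ca):
                cons_a &= (haps[:, ca] == pa[ca]).all(axis=1)
            pb = phase[2 * i + 1, sl]
            cb = pb != MISSING
            if np.any(cb):
                cons_b &= (haps[:, cb] == pb[cb]).all(axis=1)
            A = np.flatnonzero(cons_a)
            B = np.flatnonzero(cons_b)
            if A.size == 0 or B.size == 0:
                continue
            if het.size == 0:
                pairs = [(A, B)]
            else:
                sig_a: dict[tuple, list[int]] = {}
                for a in A:
                    sig_a.setdefault(tuple(haps[a, het]), []).append(a)
                sig_b: dict[tuple, list[int]] = {}
                for b in B:
                    sig_b.setdefault(tuple(haps[b, het]), []).append(b)
                pairs = []
                for s1, ga in sig_a.items():
                    s2 = tuple(1 - x for x in s1)
                    gb = sig_b.get(s2)
                    if gb is not None:
                        pairs.append((np.asarray(ga), np.asarray(gb)))
                if not pairs:
                    continue
            L = haps.shape[1]
            lo_d = np.full(L, 3, dtype=np.int8)
            hi_d = np.full(L, -1, dtype=np.int8)
            for ga, gb in pairs:
                a_blk = Hb[ga]
                b_blk = Hb[gb]
                mins = a_blk.all(axis=0).astype(np.int8) + b_blk.all(
                    axis=0
                ).astype(np.int8)
                maxs = a_blk.any(axis=0).astype(np.int8) + b_blk.any(
                    axis=0
                ).astype(np.int8)
                np.minimum(lo_d, mins, out=lo_d)
                np.maximum(hi_d, maxs, out=hi_d)
            cur = prop[i, sl]
            v = veto[i, sl]
            agree = (lo_d == hi_d) & miss
            fresh = agree & (cur == MISSING)
            clash = agree & (cur != MISSING) & (cur != lo_d)
            cur[fresh] = lo_d[fresh]
            v |= clash | (miss & (lo_d != hi_d))
            prop[i, sl] = cur
            veto[i, sl] = v
    return prop, veto


def recombination_sweep(
    phase: np.ndarray,
    pedigree: Pedigree,
    genotypes: np.ndarray,
    positions_cm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect crossovers per offspring gamete and smooth nearby imputation.

    For each gamete, grand-parental origin is assigned at informative loci
    (both parental gametes resolved and different, offspring allele known).
    Between consecutive informative loci with different origins lies a
    recombination interval: there the allele probability is the linear (in
    marker index) interpolation between the parent's two gamete alleles.
    Within interior constant-origin stretches, unresolved offspring
    alleles are copied from the assigned parental gamete (never
    contradicting observed genotypes).  Beyond the outermost informative
    loci an undetected crossover could lie anywhere, so those stretches
    are modelled probabilistically: the allele probability is the average
    of the parent's two gamete alleles weighted by the probability that
    an even number of crossovers separates the marker from the nearest
    informative locus (Haldane: (1 + exp(-2 d)) / 2 at map distance d
    Morgan, taken from ``positions_cm``; marker index = cM when no map is
    given).

    Returns the updated phase and a (2n x M) allele-probability array with
    NaN where the sweep makes no statement.
    """
    n2, M = phase.shape
    out = phase.copy()
    probs = np.full((n2, M), np.nan)
    pos = np.arange(M, dtype=float) if positions_cm is None else np.asarray(
        positions_cm, dtype=float
    )
    n = n2 // 2
    for i in range(n):
        for side, p_idx in ((0, pedigree.sire_idx[i]), (1, pedigree.dam_idx[i])):
            if p_idx < 0:
                continue
            row = 2 * i + side
            gam = out[row]
            pg1 = phase[2 * p_idx]
            pg2 = phase[2 * p_idx + 1]
            informative = (
                (gam != MISSING)
                & (pg1 != MISSING)
                & (pg2 != MISSING)
                & (pg1 != pg2)
            )
            idx = np.flatnonzero(informative)
            if idx.size == 0:
                continue
            origin = np.where(gam[idx] == pg1[idx], 1, 2).astype(np.int8)

            markers = np.arange(M)
            ri_pos = np.searchsorted(idx, markers, side="left")
            li_pos = ri_pos - 1
            has_l = li_pos >= 0
            has_r = ri_pos < idx.size
            org_l = np.where(has_l, origin[np.clip(li_pos, 0, idx.size - 1)], 0)
            org_r = np.where(has_r, origin[np.clip(ri_pos, 0, idx.size - 1)], 0)

            # copy only between two anchors of equal origin; beyond the
            # outermost anchors an undetected crossover could lie anywhere,
            # so those stretches are left for the segregation analysis
            const = has_l & has_r & (org_l == org_r)
            src = np.where(org_l == 1, pg1, pg2)
            g = genotypes[i]
            other = out[2 * i + (1 - side)]
            ok = (
                const
                & (gam == MISSING)
                & (src != MISSING)
                & ~((g == 0) & (src != 0))
                & ~((g == 2) & (src != 1))
                & ~((g == 1) & (other != MISSING) & (other != 1 - src))
            )
            gam[ok] = src[ok]

            # recombination intervals: linear interpolation in marker index
            rec = (
                has_l
                & has_r
                & (org_l != org_r)
                & (gam == MISSING)
                & (pg1 != MISSING)
                & (pg2 != MISSING)
            )
            if np.any(rec):
                a = idx[np.clip(li_pos, 0, idx.size - 1)]
                b = idx[np.clip(ri_pos, 0, idx.size - 1)]
                w = (b - markers) / np.maximum(b - a, 1)
                left = np.where(org_l == 1, pg1, pg2)
                right = np.where(org_r == 1, pg1, pg2)
                probs[row, rec] = (w * left + (1 - w) * right)[rec]

            # one-sided stretches: weight the nearest anchor's gamete by the
            # probability that no odd number of crossovers lies in between
            one_sided = has_l ^ has_r
            open_cells = (
                one_sided
                & (gam == MISSING)
                & (pg1 != MISSING)
                & (pg2 != MISSING)
            )
            if np.any(open_cells):
                anchor = np.where(
                    has_l, idx[np.clip(li_pos, 0, idx.size - 1)],
                    idx[np.clip(ri_pos, 0, idx.size - 1)],
                )
                org_n = np.where(has_l, org_l, org_r)
                d_morgan = np.abs(pos - pos[anchor]) / 100.0
                w1 = 0.5 * (1.0 + np.exp(-2.0 * d_morgan))
                near = np.where(org_n == 1, pg1, pg2)
                far = np.where(org_n == 1, pg2, pg1)
                probs[row, open_cells] = (w1 * near + (1 - w1) * far)[open_cells]
    return out, probs


def origin_posterior(
    phase: np.ndarray,
    pedigree: Pedigree,
    positions_cm: np.ndarray | None = None,
    eps: float = 0.01,
) -> np.ndarray:
    """Posterior probability that each gamete cell descends from the
    parent's first gamete.

    A two-state Markov chain per offspring gamete: states are the parent's
    two gametes, the switch probability between adjacent markers follows
    Haldane's map function on ``positions_cm`` (marker index = cM when no
    map is given), and emissions compare the offspring's called alleles
    against the parental gamete alleles with error rate ``eps``.  The
    forward-backward posterior combines every informative locus on the
    chromosome, so evidence propagates across arbitrarily long uncalled
    stretches with correctly decaying confidence.

    Returns a (2n x M) float array; rows of parentless gametes are NaN.
    """
    n2, M = phase.shape
    pos = np.arange(M, dtype=float) if positions_cm is None else np.asarray(
        positions_cm, dtype=float
    )
    parent = np.empty(n2, dtype=np.int64)
    parent[0::2] = pedigree.sire_idx
    parent[1::2] = pedigree.dam_idx
    valid = parent >= 0
    pv = np.clip(parent, 0, None)
    pg1 = phase[2 * pv]
    pg2 = phase[2 * pv + 1]
    known = (
        valid[:, None]
        & (phase != MISSING)
        & (pg1 != MISSING)
        & (pg2 != MISSING)
    )
    lik1 = np.ones((n2, M), dtype=np.float64)
    lik2 = np.ones((n2, M), dtype=np.float64)
    lik1[known] = np.where(phase[known] == pg1[known], 1.0 - eps, eps)
    lik2[known] = np.where(phase[known] == pg2[known], 1.0 - eps, eps)

    t = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0))
    fwd = np.empty((M, n2, 2), dtype=np.float64)
    f1, f2 = lik1[:, 0].copy(), lik2[:, 0].copy()
    s = f1 + f2
    f1 /= s
    f2 /= s
    fwd[0, :, 0], fwd[0, :, 1] = f1, f2
    for m in range(1, M):
        tp = t[m - 1]
        g1 = f1 * (1.0 - tp) + f2 * tp
        g2 = f1 * tp + f2 * (1.0 - tp)
        f1 = g1 * lik1[:, m]
        f2 = g2 * lik2[:, m]
        s = f1 + f2
        f1 /= s
        f2 /= s
        fwd[m, :, 0], fwd[m, :, 1] = f1, f2

    post = np.empty((n2, M), dtype=np.float64)
    b1 = np.ones(n2)
    b2 = np.ones(n2)
    post[:, M - 1] = fwd[M - 1, :, 0]
    for m in range(M - 2, -1, -1):
        tp = t[m]
        e1 = lik1[:, m + 1] * b1
        e2 = lik2[:, m + 1] * b2
        b1 = e1 * (1.0 - tp) + e2 * tp
        b2 = e1 * tp + e2 * (1.0 - tp)
        s = b1 + b2
        b1 /= s
        b2 /= s
        num = fwd[m, :, 0] * b1
        post[:, m] = num / (num + fwd[m, :, 1] * b2)
    post[~valid] = np.nan
    return post


def joint_origin_posterior(
    phase: np.ndarray,
    genotypes: np.ndarray,
    pedigree: Pedigree,
    positions_cm: np.ndarray | None = None,
    eps: float = 0.01,
) -> np.ndarray:
    """Grand-parental-origin posteriors from a joint chain over both gametes.

    Like :func:`origin_posterior`, but for individuals with both parents
    the two origin chains are tracked jointly (four states: paternal origin
    x maternal origin) and the individual's observed genotypes enter the
    emission.  A heterozygous observed marker says nothing about either
    gamete alone, yet constrains the two origins jointly (the transmitted
    parental alleles must sum to one); the joint chain turns every such
    marker into an origin anchor.

    Returns a (2n x M) array: row 2i = P(paternal gamete of i descends
    from the sire's first gamete), row 2i+1 likewise for the dam.  Rows of
    gametes without the needed parent are NaN.
    """
    n2, M = phase.shape
    n = n2 // 2
    pos = np.arange(M, dtype=float) if positions_cm is None else np.asarray(
        positions_cm, dtype=float
    )
    post = origin_posterior(phase, pedigree, positions_cm, eps)
    both = (pedigree.sire_idx >= 0) & (pedigree.dam_idx >= 0)
    rows = np.flatnonzero(both)
    if rows.size == 0:
        return post
    nb = rows.size
    si = pedigree.sire_idx[rows]
    di = pedigree.dam_idx[rows]

    def side(call, g1, g2):
        lik = np.ones((nb, M, 2))
        p1 = np.empty((nb, M, 2))
        for k, gk in enumerate((g1, g2)):
            kb = (call != MISSING) & (gk != MISSING)
            lk = lik[:, :, k]
            lk[kb] = np.where(call[kb] == gk[kb], 1.0 - eps, eps)
            a = np.where(call != MISSING, call, gk).astype(np.float64)
            p1[:, :, k] = np.where(a == MISSING, 0.5, a)
        return lik, p1

    lik_p, pp = side(phase[2 * rows], phase[2 * si], phase[2 * si + 1])
    lik_m, pm = side(phase[2 * rows + 1], phase[2 * di], phase[2 * di + 1])

    # emission over the four states: call-match factors times the genotype
    # likelihood under the implied transmitted-allele probabilities
    a1 = pp[:, :, :, None]
    a2 = pm[:, :, None, :]
    g = genotypes[rows][:, :, None, None]
    pg = np.where(
        g == 0, (1 - a1) * (1 - a2),
        np.where(
            g == 1, a1 * (1 - a2) + (1 - a1) * a2,
            np.where(g == 2, a1 * a2, 1.0),
        ),
    )
    E = lik_p[:, :, :, None] * lik_m[:, :, None, :] * np.clip(pg, eps, None)
    E = E.reshape(nb, M, 4)

    t = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0))

    def mix(f, tp):
        # independent Haldane switching on each side of the (2 x 2) state
        f = f.reshape(nb, 2, 2)
        f = (1.0 - tp) * f + tp * f[:, ::-1, :]
        f = (1.0 - tp) * f + tp * f[:, :, ::-1]
        return f.reshape(nb, 4)

    fwd = np.empty((M, nb, 4))
    f = E[:, 0, :].copy()
    f /= f.sum(axis=1, keepdims=True)
    fwd[0] = f
    for m in range(1, M):
        f = mix(f, t[m - 1]) * E[:, m, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[m] = f

    b = np.ones((nb, 4))
    out = np.empty((nb, M, 4))
    out[:, M - 1] = fwd[M - 1]
    for m in range(M - 2, -1, -1):
        b = mix(E[:, m + 1, :] * b, t[m])
        b /= b.sum(axis=1, keepdims=True)
        q = fwd[m] * b
        out[:, m] = q / q.sum(axis=1, keepdims=True)

    q4 = out.reshape(nb, M, 2, 2)
    post[2 * rows] = q4.sum(axis=3)[:, :, 0]
    post[2 * rows + 1] = q4.sum(axis=2)[:, :, 0]
    return post
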