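"""Synthetic data generation: coalescent base haplotypes, pedigree gene
dropping, marker panels and low-density masking.

The demography emulates estimates for the Holstein cattle population:
effective population size 100 at present, 1256 at 1,000 generations ago,
4,350 at 10,000 and 43,500 at 100,000, with linear changes in between
(one generation per year).  Base haplotypes carry biallelic segregating
sites produced under a per-site mutation rate of 2.5e-8 and a per-site
recombination rate of 1.0e-8 (so 1e8 bp corresponds to 100 cM).

Genotypes are then "gene dropped" through a sire/dam pedigree: founders
draw base haplotypes, and every meiosis recombines the parental gametes
with crossovers occurring with 1% probability per cM, uniformly placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iodata import MISSING, MarkerMap, Pedigree, UNKNOWN_PARENT

__all__ = [
    "DemographyProfile",
    "SimPedigreeSpec",
    "PanelSpec",
    "TruthSet",
    "simulate_base_haplotypes",
    "make_pedigree",
    "found_and_drop",
    "make_panels",
    "mask_and_split",
    "drop_pedigree_links",
    "simulate_dataset",
]


@dataclass
class DemographyProfile:
    """Piecewise-linear Ne history plus sequence parameters."""

    sizes: tuple[float, ...] = (100.0, 1256.0, 4350.0, 43500.0)
    times: tuple[float, ...] = (0.0, 1000.0, 10_000.0, 100_000.0)
    mutation_rate: float = 2.5e-8
    recombination_rate: float = 1.0e-8
    sequence_length: float = 1.0e6
    generations_per_year: float = 1.0
    steps_per_epoch: int = 8

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")
        if list(self.times) != sorted(self.times):
            raise ValueError("demography breakpoints must be ordered")

    def size_at(self, t: float) -> float:
        """Linear interpolation of Ne at time t generations ago."""
        return float(np.interp(t, self.times, self.sizes))

    def to_msprime_demography(self):
        """Approximate the linear ramps by a fine piecewise-constant grid."""
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=self.sizes[0])
        for e in range(len(self.times) - 1):
            t0, t1 = self.times[e], self.times[e + 1]
            grid = np.linspace(t0, t1, self.steps_per_epoch + 1)[1:]
            for t in grid:
                dem.add_population_parameters_change(
                    time=t * self.generations_per_year,
                    initial_size=self.size_at(t),
                    population="pop",
                )
        return dem


@dataclass
class SimPedigreeSpec:
    """Mating design: each generation mates sires x dams to produce progeny."""

    n_sires: int = 25
    n_dams: int = 500
    n_progeny: int = 1000
    n_generations: int = 5

    def __post_init__(self) -> None:
        if min(self.n_sires, self.n_dams, self.n_progeny, self.n_generations) <= 0:
            raise ValueError("pedigree counts must be positive")
        if self.n_dams < self.n_sires:
            raise ValueError("need at least as many dams as sires")


@dataclass
class PanelSpec:
    """High-density marker count and low-density subset sizes."""

    n_hd: int = 2000
    n_ld: tuple[int, ...] = (15, 30, 300, 600, 2000)
    maf_min: float = 0.05  # chip-style ascertainment of common variants

    def __post_init__(self) -> None:
        if any(l > self.n_hd for l in self.n_ld):
            raise ValueError("low-density panels must be subsets of the HD panel")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")


@dataclass
class TruthSet:
    """Complete truth plus the masked observation matrix."""

    pedigree: Pedigree
    marker_map: MarkerMap
    true_phase: np.ndarray  # 2n x M
    true_genotypes: np.ndarray  # n x M
    masked_genotypes: np.ndarray  # n x M with 9s at masked cells
    test_ids: list[str] = field(default_factory=list)
    panel_markers: np.ndarray | None = None  # LD marker indices kept for tests


def simulate_base_haplotypes(
    profile: DemographyProfile, n_haplotypes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coalescent base haplotypes under the piecewise-linear demography.

    Returns ``(haplotypes, positions_cm)`` where haplotypes is an
    (n_haplotypes x S) 0/1 matrix over segregating sites and positions are
    genetic positions in cM (1e-8 per-site recombination = 1e-6 cM per bp).
    """
    import msprime

    if n_haplotypes < 2:
        raise ValueError("need at least two base haplotypes")
    # Ne values follow the diploid convention (pairwise coalescence rate
    # 1/(2Ne)), so sample n/2 diploids rather than n haploids.
    ts = msprime.sim_ancestry(
        samples=(n_haplotypes + 1) // 2,
        ploidy=2,
        demography=profile.to_msprime_demography(),
        sequence_length=profile.sequence_length,
        recombination_rate=profile.recombination_rate,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=profile.mutation_rate,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        model=msprime.BinaryMutationModel(),
    )
    S = mts.num_sites
    haps = np.empty((n_haplotypes, S), dtype=np.int8)
    for j, var in enumerate(mts.variants()):
        haps[:, j] = np.minimum(var.genotypes[:n_haplotypes], 1)
    positions = np.array([s.position for s in mts.sites()])
    # collapse duplicate positions are already distinct in msprime sites
    pos_cm = positions * profile.recombination_rate * 100.0
    # keep only sites still segregating in the pool
    freq = haps.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    return haps[:, keep], pos_cm[keep]


def make_pedigree(
    spec: SimPedigreeSpec,
) -> tuple[list[str], list[str], list[str], list[list[str]]]:
    """Lay out the multi-generation id structure of the sire/dam pedigree.

    Generation 0 holds the founder sires and dams; each later generation g
    holds ``n_progeny`` individuals.  Parent tokens are assigned during gene
    dropping (it owns the rng).  Returns (ids, sires, dams, per-generation
    id lists) with all parents still unknown.
    """
    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    gen_ids: list[list[str]] = []
    founders = [f"S{i + 1}" for i in range(spec.n_sires)] + [
        f"D{i + 1}" for i in range(spec.n_dams)
    ]
    for f in founders:
        ids.append(f)
        sires.append(UNKNOWN_PARENT)
        dams.append(UNKNOWN_PARENT)
    gen_ids.append(founders)
    for g in range(1, spec.n_generations + 1):
        gen_ids.append([f"G{g}_{k + 1}" for k in range(spec.n_progeny)])
        ids.extend(gen_ids[g])
    return ids, sires, dams, gen_ids


def found_and_drop(
    pool: np.ndarray,
    spec: SimPedigreeSpec,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> tuple[Pedigree, np.ndarray]:
    """Found a pedigree from base haplotypes and gene-drop genotypes.

    Each meiosis draws its crossover count as Bernoulli(0.01) per whole-cM
    interval with positions uniform along the chromosome, and recombines the
    parent's two gametes accordingly.  Returns the pedigree (topologically
    ordered) and the 2n x M truth phase matrix (rows 2i, 2i+1 = paternal,
    maternal gamete of individual i).
    """
    if pool.shape[0] < 2:
        raise ValueError("base haplotype pool is empty or too small")
    M = pool.shape[1]
    pos = marker_map.positions_cm
    length_cm = float(pos[-1] - pos[0]) if M else 0.0

    ids, sires, dams, gen_ids = make_pedigree(spec)
    index = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    phase = np.empty((2 * n, M), dtype=np.int8)
    sire_tok = [UNKNOWN_PARENT] * n
    dam_tok = [UNKNOWN_PARENT] * n

    # founders draw two pool haplotypes each, without replacement within an
    # individual (with replacement across individuals if the pool is small)
    n_founders = len(gen_ids[0])
    for i in range(n_founders):
        a, b = rng.choice(pool.shape[0], size=2, replace=False)
        phase[2 * i] = pool[a]
        phase[2 * i + 1] = pool[b]

    def meiosis(parent_row: int) -> np.ndarray:
        g1 = phase[2 * parent_row]
        g2 = phase[2 * parent_row + 1]
        n_int = max(int(round(length_cm)), 0)
        ncross = int(rng.binomial(n_int, 0.01)) if n_int else 0
        start = int(rng.integers(0, 2))
        if ncross == 0:
            return g1.copy() if start == 0 else g2.copy()
        xpos = np.sort(rng.uniform(pos[0], pos[-1], size=ncross))
        seg = start + np.searchsorted(xpos, pos, side="right")
        take2 = (seg % 2).astype(bool)
        out = np.where(take2, g2, g1)
        return out.astype(np.int8)

    for g in range(1, spec.n_generations + 1):
        prev = gen_ids[g - 1]
        if g == 1:
            sire_pool = [index[s] for s in prev[: spec.n_sires]]
            dam_pool = [index[d] for d in prev[spec.n_sires : spec.n_sires + spec.n_dams]]
        else:
            rows = [index[p] for p in prev]
            picked = rng.choice(len(rows), size=spec.n_sires + spec.n_dams, replace=False)
            sire_pool = [rows[k] for k in picked[: spec.n_sires]]
            dam_pool = [rows[k] for k in picked[spec.n_sires :]]
        # each dam produces n_progeny / n_dams offspring, sires drawn at random
        dam_assign = np.resize(np.array(dam_pool), len(gen_ids[g]))
        sire_assign = rng.choice(sire_pool, size=len(gen_ids[g]))
        for child, (s_row, d_row) in zip(gen_ids[g], zip(sire_assign, dam_assign)):
            c = index[child]
            sire_tok[c] = ids[int(s_row)]
            dam_tok[c] = ids[int(d_row)]
            phase[2 * c] = meiosis(int(s_row))
            phase[2 * c + 1] = meiosis(int(d_row))

    ped = Pedigree(ids=ids, sires=sire_tok, dams=dam_tok)
    return ped, phase


def make_panels(
    base_freqs: np.ndarray, spec: PanelSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """SNP-chip-style marker panels from the segregating sites.

    ``base_freqs`` are per-site allele frequencies in the founder
    haplotype pool.  Commercial genotyping arrays are ascertained for
    common variants, so the HD panel is a random draw from sites with
    minor allele frequency at least ``spec.maf_min``.  Low-density chips
    additionally aim for even genome coverage; each LD panel takes the
    highest-MAF HD marker within each of ``size`` equal windows of the HD
    panel.

    Returns ``(hd_sites, {ld_size: hd_panel_indices})`` where the LD values
    index into the HD panel (so every LD marker is an HD marker).
    """
    base_freqs = np.asarray(base_freqs, dtype=float)
    maf = np.minimum(base_freqs, 1.0 - base_freqs)
    eligible = np.flatnonzero(maf >= spec.maf_min)
    if eligible.size < spec.n_hd:
        raise ValueError(
            f"only {eligible.size} sites with MAF >= {spec.maf_min} "
            f"for an HD panel of {spec.n_hd}"
        )
    hd = np.sort(rng.choice(eligible, size=spec.n_hd, replace=False))
    hd_maf = maf[hd]
    ld = {}
    for size in spec.n_ld:
        bounds = np.linspace(0, spec.n_hd, size + 1).astype(int)
        picks = [
            lo + int(np.argmax(hd_maf[lo:hi]))
            for lo, hi in zip(bounds[:-1], bounds[1:])
            if hi > lo
        ]
        ld[size] = np.array(sorted(set(picks)), dtype=int)
    return hd, ld


def mask_and_split(
    pedigree: Pedigree,
    marker_map: MarkerMap,
    true_phase: np.ndarray,
    panel_keep: np.ndarray,
    test_ids: list[str],
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Mask test individuals down to the low-density panel.

    Training individuals keep the complete HD genotypes; test individuals
    keep only the ``panel_keep`` marker columns (the rest set to missing).
    """
    geno = (true_phase[0::2] + true_phase[1::2]).astype(np.int8)
    masked = geno.copy()
    rows = pedigree.subset_rows(test_ids)
    mask = np.ones(geno.shape[1], dtype=bool)
    mask[panel_keep] = False
    for r in rows:
        masked[r, mask] = MISSING
    return TruthSet(
        pedigree=pedigree,
        marker_map=marker_map,
        true_phase=true_phase,
        true_genotypes=geno,
        masked_genotypes=masked,
        test_ids=list(test_ids),
        panel_markers=np.asarray(panel_keep),
    )


def drop_pedigree_links(
    pedigree: Pedigree, n_remove: int, candidates: list[str], rng: np.random.Generator
) -> tuple[Pedigree, list[str]]:
    """Remove sire and dam links for ``n_remove`` of the candidate ids.

    The selected individuals become founder-coded records (treated as
    unrelated); everything else is unchanged.  Returns the new pedigree and
    the list of ids whose links were removed.
    """
    if n_remove > len(candidates):
        raise ValueError("cannot remove more links than candidates")
    chosen = set(
        rng.choice(np.array(candidates, dtype=object), size=n_remove, replace=False)
    )
    # removing links cannot break topological order, so the row order (and
    # with it the alignment of any matrices built on it) is preserved
    out = Pedigree(
        ids=list(pedigree.ids),
        sires=[
            UNKNOWN_PARENT if i in chosen else s
            for i, s in zip(pedigree.ids, pedigree.sires)
        ],
        dams=[
            UNKNOWN_PARENT if i in chosen else d
            for i, d in zip(pedigree.ids, pedigree.dams)
        ],
    )
    return out, sorted(chosen)


def simulate_dataset(
    seed: int,
    profile: DemographyProfile | None = None,
    ped_spec: SimPedigreeSpec | None = None,
    panel_spec: PanelSpec | None = None,
    n_base_haplotypes: int = 1000,
) -> tuple[TruthSet, dict[int, np.ndarray], list[str]]:
    """End-to-end simulation of one chromosome.

    Returns a TruthSet built on the HD panel (unmasked yet; use
    :func:`mask_and_split` per LD panel), the LD panel index sets, and the
    last-generation (test) ids.
    """
    profile = profile or DemographyProfile()
    ped_spec = ped_spec or SimPedigreeSpec()
    panel_spec = panel_spec or PanelSpec()
    rng = np.random.default_rng(seed)
    pool, pos_cm = simulate_base_haplotypes(profile, n_base_haplotypes, rng)
    hd, ld = make_panels(pool.mean(axis=0), panel_spec, rng)
    pool_hd = pool[:, hd]
    mm = MarkerMap(
        marker_ids=[f"m{i + 1}" for i in range(len(hd))],
        positions_cm=pos_cm[hd],
    )
    ped, phase = found_and_drop(pool_hd, ped_spec, mm, rng)
    test_ids = [
        i for i in ped.ids if i.startswith(f"G{ped_spec.n_generations}_")
    ]
    geno = (phase[0::2] + phase[1::2]).astype(np.int8)
    truth = TruthSet(
        pedigree=ped,
        marker_map=mm,
        true_phase=phase,
        true_genotypes=geno,
        masked_genotypes=geno.copy(),
        test_ids=test_ids,
        panel_markers=None,
    )
    return truth, ld, test_ids
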