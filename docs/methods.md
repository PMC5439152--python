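# Methods

This document describes the imputation method implemented in
`hybridimpute`, the simulator used to validate it, and the accuracy
conventions used throughout.

## Problem statement

A livestock population is genotyped on two SNP panels: a high-density
(HD) panel covering all M markers, and a low-density (LD) subset of
those markers.  Most ancestors carry HD genotypes; selection candidates
are typed on the LD panel to save cost.  The task is to predict, for
every LD-typed animal, its genotype at every HD marker — ideally as an
expected allele dosage in [0, 2] so downstream genomic evaluation can
weight uncertain calls correctly.  A recorded pedigree is usually
available but may be incomplete; the method must degrade gracefully for
animals with no recorded parents.

## Stage 1: pedigree and haplotype heuristics

The first stage applies deterministic rules that are exact (or nearly
so) wherever pedigree structure and observed genotypes pin down the
answer.  Each rule only ever fills alleles it can justify; anything
ambiguous is left missing for stage 2.

1. **Mendelian fill-in.**  Homozygous parents transmit a known allele;
   a homozygous offspring reveals one allele in each parent.  Rules are
   iterated to a fixed point.  Observed-genotype conflicts with an
   already-fixed transmitted allele are resolved in favour of the
   individual's own observation.
2. **Single-locus segregation peeling.**  For each marker, genotype
   probabilities are propagated both down (parent → offspring) and up
   (offspring → parent) through the pedigree, and alleles whose
   posterior exceeds a calling threshold are fixed.  The resulting
   marginal dosages also serve as the fallback dosage for any genotype
   the later stages never resolve, which is why the final dosage matrix
   is always complete.
3. **Long-range phasing with surrogate parents.**  When a true parent
   is ungenotyped, relatives that demonstrably share a gamete with the
   focal animal (no opposing homozygotes over a long stretch) act as
   surrogates, and the shared haplotype is read off the surrogate.
4. **Haplotype-library imputation over multi-length cores.**  The
   chromosome is partitioned into cores at several geometrically spaced
   lengths.  Phased gametes populate a library per core; a partially
   observed gamete that is consistent with library entries inherits the
   alleles on which all matching entries agree (with an abstention rule
   when too many heterozygous positions make the match uninformative).
   Results from different core lengths are combined by consensus.
5. **Recombination sweep.**  For each offspring gamete with a genotyped
   parent, a forward–backward pass over the parental origin (which of
   the parent's two gametes is being copied, with Haldane-map switch
   probabilities) yields origin posteriors; confident stretches copy
   the parental allele and uncertain intervals contribute probabilistic
   dosages.  A joint version couples the two gametes of an offspring
   through heterozygous anchors.

After stage 1, animals with fully genotyped and phased parents and
grandparents and recombination-free gametes are recovered exactly; the
test suite checks this property literally.

## Stage 2: Li–Stephens mosaic model

Unresolved genotypes are imputed with a haplotype-mosaic hidden Markov
model in the style of MaCH.  Each gamete of a target animal is modelled
as an imperfect mosaic of H template haplotypes.  Hidden state = which
template is being copied; transitions between adjacent markers switch
templates with probability θ_t (shared across template pairs, i.e. the
exchangeable Li–Stephens kernel), and the observed allele differs from
the copied template allele with per-marker error rate ε_m.

Because the transition kernel is exchangeable, the diploid
forward–backward pass factorises: the update for an (H × H) ordered
template pair costs O(H²) per marker instead of the naive O(H⁴),
using row/column sums and the total mass of the forward matrix.  The
test suite verifies this factorised pass against a dense
O(M·|H|⁴) enumeration oracle to 1e-10.

Imputation runs as a blocked Gibbs sampler:

- **Template pool.**  Phased gametes from stage 1 form a static
  reference pool; animals that are HD-genotyped but not phased
  contribute dynamic pool members whose phase is resampled each sweep.
  When mostly-unphased data leave no usable pool, the sampler falls
  back to bootstrapping templates from the genotype matrix itself.
- **Sweep.**  Each iteration re-samples a mosaic path for every dynamic
  pool gamete (conditioning on homozygous anchors only, so path choice
  is not enslaved to the current heterozygous orientations), re-samples
  each target animal's ordered template pair from the diploid model,
  and accumulates transition/emission counts.
- **Parameter re-estimation.**  After each sweep, θ and ε are updated
  from Laplace-smoothed count ratios, clipped to [1e-6, 0.5] so chains
  keep mixing.  On data simulated from the model itself the estimates
  recover the generating parameters; the acceptance suite requires the
  error rate within 20 % relative error.
- **Consensus.**  Post-burn-in samples are averaged into dosages and
  genotype probabilities; hard calls take the modal genotype and a
  consensus ordered pair fixes the output phase.

Static reference refreshes exist only to feed the parameter counts, so
each sweep refreshes the dynamic members plus a deterministic rotation
of at most `n_reference_updates` static references (64 by default).
This bounds per-sweep cost on large phased reference sets without
changing what the targets condition on.

## Hybrid integration

`run_hybrid` runs stage 1, then stage 2 on the animals selected for
imputation, and merges: observed genotypes are kept verbatim,
heuristically fixed alleles are kept, and HMM dosages fill the rest.
Either stage can be disabled (`--no-hmm`, `--no-heuristics`) to get the
pure-pedigree or pure-population baselines.

## Simulation

Founder haplotypes come from an msprime coalescent simulation
(constant-size neutral demography) on a single chromosome; a pedigree
with discrete generations (configurable sires, dams, progeny per
generation) is then gene-dropped with crossovers at Haldane map
distances.  HD markers are ascertained above a minor-allele-frequency
floor, one per evenly spaced window; LD panels are nested, evenly
spaced subsets.  Test animals are masked down to the LD panel, and a
configurable number of test animals have their parent links deleted to
create the no-pedigree condition.

## Evaluation

Accuracy is the Pearson correlation between imputed dosage and true
genotype after standardising each marker by its population mean and
standard deviation.  Standardisation matters: filling in twice the
allele frequency everywhere scores zero instead of inheriting the
frequency signal.  Animal-wise accuracy correlates across markers
within an animal; marker-wise accuracy correlates across animals within
a marker and is summarised in minor-allele-frequency bins.  Animals are
also grouped by which of their ancestors are HD-genotyped.

## Benchmark design

The validation study bundled with the package
(`hybridimpute benchmark`, `scripts/acceptance.py`) is sized to run on
a single desktop core:

- one chromosome of 2 × 10⁷ bp (≈ 20 cM), HD panel of 2 000 markers;
- LD panels of 3, 6, 60, 120 and 400 markers;
- a five-generation pedigree (4 sires, 40 dams, 80 progeny per
  generation, ≈ 444 animals) from 200 founder haplotypes;
- 80 test animals, of which 40 have their pedigree links dropped;
- hybrid runs with 200 templates; on the 6-marker focus panel also a
  template sweep over {100, 300} (no-pedigree animals only, since the
  sweep probes population-only information) and an HMM-only run;
- a Gibbs schedule of 14 sweeps with 4 burn-in — parameter chains at
  this problem size converge in well under 10 sweeps, and the shorter
  schedule keeps a replicate within the desktop time budget;
- three replicates, each a fresh coalescent + pedigree simulation.

Headline figures (t1–t7 in `scripts/acceptance.py --out targets.json`)
are replicate means: with-pedigree and no-pedigree accuracy on the
focus panel for each method, dense-panel accuracies by pedigree status,
the sparsest-panel with-pedigree accuracy, and the worst
marker-wise MAF-bin mean of the no-pedigree hybrid.  The monotonicity
table checks that accuracy never decreases with panel density for any
method/status.

Because this study is deliberately small — one short chromosome and a
compact, closely related pedigree — population linkage disequilibrium
around the anchor markers is stronger than it would be genome-wide.
Population-based accuracy at very sparse panels is therefore expected
to sit above what the same method achieves in large, diverse
populations, while pedigree-based accuracy is essentially
scale-independent.  The acceptance tests document where the desk-scale
values land relative to the expected field-scale windows.
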