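# Methods

`bsamap` implements bulked-segregant SNP-index mapping (the MutMap / QTL-seq
family of methods) for a single recessive, EMS-induced mutation segregating
in an F2 population, together with a simulator that generates complete
in-silico experiments with known ground truth, a codon-level variant-effect
annotator, and the two supporting screens such a study uses (Mendelian
segregation test; fold-change / rank-sum differential screens).

## The mapping model

Cross the mutant to its progenitor, self the F1, and sequence two pooled DNA
samples from the F2: a bulk of plants showing the mutant phenotype and a bulk
of plants that do not.  At every biallelic SNP the **SNP index** of a bulk is

    SNP index = alt reads / (ref reads + alt reads)

and the mapping statistic is

    Δ(SNP index) = SNP index(mutant bulk) − SNP index(wild bulk).

For a recessive mutation, every plant in the mutant bulk is homozygous for
the causal allele, so the mutant bulk's index at the causal site is 1 under
error-free sequencing.  The phenotypically wild bulk is a selected mixture of
1 AA : 2 Aa genotypes, so its expected causal-site index is **1/3** — not 0,
as is sometimes loosely stated for MutMap-style designs (that figure applies
when the reference bulk is the parent, not a phenotype-selected F2 pool).
The expected peak Δ is therefore 2/3, decaying toward 0 with genetic distance
from the causal locus; far from it both indices centre on 1/2 and Δ on 0.

### Filters

Three removal rules guard against sequencing/alignment artefacts, OR-combined:

1. a bulk with zero depth at the site (site "deleted" in one pool);
2. SNP index below `min_index` (default 0.3) in **both** bulks;
3. alt-supporting reads below `min_support` (default 7) in **both** bulks.

`min_support` counts alt-supporting reads; counting total depth or SNPs per
window are alternative readings of the convention and the parameter is
configurable.

### Windows and the simulated null band

Window means of Δ are computed over sliding windows (defaults 2 Mb window,
50 kb step, ≥ 3 SNPs per window; windows with fewer SNPs are reported as
missing and never imputed).  Significance comes from a replicate simulation:
for each of `n_rep` (default 1000) replicates, each bulk is re-drawn as a
random Mendelian sample with no linkage to phenotype — the bulk's mutant
allele count over 2n gametes is Binomial(2n, 1/2), which is exactly n
genotypes drawn from 1/4 : 1/2 : 1/4 — and alt reads are re-drawn as
Binomial(observed depth, bulk frequency) at every site.  Window means are
recomputed per replicate and the per-window (2.5%, 97.5%) quantiles form the
95% band.  Drawing the bulk composition per replicate (rather than fixing
the allele frequency at 1/2) puts bulk-size sampling variance into the null.
The band is two-sided, but candidate intervals use only the upper bound,
because the mutant bulk is defined as the one carrying the mutant allele.
Maximal runs of consecutive windows above the upper bound are merged into
candidate intervals; each interval reports its peak window.

The null draws sites independently.  Real (and simulated) bulk data are
*correlated* across linked sites, because all sites on a chromosome share the
bulk's genotype composition; the band is therefore a per-window envelope,
not a genome-wide error rate.  Consequently the 5%-coverage property of the
band can only be observed on data for which the independent-site null is the
true generative model: the calibration test uses phenotype-blind bulks over
markers made effectively unlinked (genetic map stretched until the
adjacent-SNP recombination fraction is ~1/2) and a large F2 population
(n = 2000) so that without-replacement bulk sampling is effectively binomial.
On the default linked genome the same check would measure window correlation,
not calibration.

## The simulator

* **Genome**: a desk-scale stand-in — 2 chromosomes × 30 Mb, 100 cM each —
  small enough for minutes-scale runs, large enough that the Δ peak and its
  decay are visible.  The bp→cM map is linear per chromosome.
* **Parental variants**: background SNP counts are Poisson(rate × Mb) with a
  default of 10 SNPs/Mb; each ref→alt pair is a G:C→A:T transition with
  probability 0.9 (EMS is strongly transition-biased; the genome-wide
  spectrum is a modelling choice, so it is configurable), otherwise uniform
  over the remaining pairs.  The causal G→A site is always included.
* **Meiosis**: crossover counts Poisson(map length/100), positions uniform,
  no interference.  This is simulated in its exactly equivalent Markov form:
  at the ordered variant positions, a gamete starts from a fair coin and
  flips parental origin between consecutive loci with the Haldane
  recombination fraction r = (1 − e^(−2d/100))/2.  The marginal law at the
  observed loci is identical to the crossover-process formulation and it
  vectorises over individuals.
* **Phenotype**: mutant iff homozygous for the causal allele; an optional
  misclassification rate (default 0) models bulking errors.
* **Bulks**: 20 mutant-phenotype and 20 wild-phenotype plants sampled without
  replacement (the standard design size for this experiment family); the
  default F2 population of 200 gives an expected 50 mutant-phenotype plants,
  comfortably above the bulk size.
* **Reads**: per site and bulk, depth ~ Poisson(mean 30); alt reads ~
  Binomial(depth, p(1−e) + (1−p)e) with p the bulk's true allele frequency
  and e a symmetric base-error rate (default 0).  Zero-depth sites are kept
  and handled downstream as missing.

All randomness flows from explicit integer seeds; stage seeds derive from a
master seed via `numpy.random.SeedSequence`, and every parameter and seed is
echoed into the run manifest.  Identical configs produce byte-identical
datasets and tables.

What the simulator does **not** emulate: read-level errors that correlate
across sites (alignment artefacts, paralogy), depth heterogeneity beyond
Poisson, EMS dosage/chimera effects, segregation distortion, multi-locus or
quantitative traits, and phenotyping structure beyond iid misclassification.
Passing tests therefore demonstrate correctness of the statistics under the
stated generative model, not robustness to every failure mode of real
bulk-sequencing data.

## Variant-effect annotation

Gene models are single-transcript ordered CDS exon lists on either strand.
For an exonic SNP the codon is rebuilt on the coding strand, both alleles are
translated with the standard nuclear code, and the change is classed as
stop_gain, stop_loss, nonsynonymous or synonymous.  The two intronic bases
flanking each internal exon boundary are splice_site (the ANNOVAR
convention); other in-gene positions are intronic, everything else
intergenic.  Candidate ranking prefers truncating changes (stop loss/gain),
then nonsynonymous, then splice-site, then the rest, with ties broken by
coordinate.  The canonical positive case — G→A at the third base of a TGG
(Trp) codon creating a TGA stop — is both a unit fixture and the gene
fixture used by the end-to-end run.  CDS translation drops the terminal stop
(a 2433-nt CDS encodes 810 residues) and reports an internal stop as a
premature-termination error carrying the codon index, which is the mutant
signature.  Indels, MNVs, isoforms and regulatory annotation are out of
scope.

## Supporting statistics

* **Segregation**: χ² goodness-of-fit of wild/mutant counts to 3:1 with 1 df;
  consistency means χ² below the upper-α critical value (3.84 at α = 0.05).
* **Metabolite screen**: fold change = mean(mutant)/mean(wild); calls are
  'up' at fold change ≥ 2 and 'down' at ≤ 0.5.  A two-sided Wilcoxon
  rank-sum p-value is reported alongside but does not gate the call by
  default, since the selection rule is the fold-change thresholds; a p gate
  is available.  The p-value is exact by full enumeration over rank
  assignments for group sizes ≤ 10 (midranks make ties exact too); larger
  groups use the normal approximation without continuity correction.  A zero
  wild-type mean with nonzero mutant signal is 'up' with missing fold change
  (the direction is unambiguous; the ratio is not finite).  No
  multiple-testing correction is applied.  Replicate fixtures default to
  3 vs 3, mirroring the triplicate designs typical of these assays.
* **Expression ratio**: per gene, log2((FPKM_mut + c)/(FPKM_wt + c)) with a
  shared pseudocount c (default 0.01) so silenced genes report large finite
  negative values; results are sorted ascending with ties by gene id.

## Numerical and design notes

* Coordinates are 1-based inclusive everywhere; windows tile from position 1
  at the step size, with a final clipped-start window so the chromosome end
  is covered; a chromosome shorter than the window is a single window.
* Window means use per-chromosome prefix sums; they agree with direct
  summation to float summation order (~1e-15), which is what the oracle
  tests assert.
* Quantiles are `numpy` linear-interpolation quantiles.
* Missing values (zero-depth indices, under-populated windows) propagate as
  NaN and are excluded from calling, never imputed.
* The VCF dialect is VCF v4.2 with FORMAT `AD` and samples `bulk_mut`,
  `bulk_wt`; parsing goes through pysam after a light structural check that
  reports malformed rows by line number.

## Problem sizes used by the test suite

The acceptance-style checks run at desk scale: segregation on 100,000
simulated F2 individuals; parameter recovery on 20 seeded replicates of the
default fixture (2 × 30 Mb, 10 SNPs/Mb, depth 30, 20/20 bulks,
1000-replicate null); null calibration on ~240 non-overlapping 250-kb
windows at 40 SNPs/Mb.  The full suite completes in well under a minute on
one CPU.

## Known limitations

* Single recessive causal locus only; no G-statistic/Euclidean-distance BSA
  variants, no multi-QTL models.
* The null band is per-window; no genome-wide multiplicity control.
* Parental sequencing tracks are not simulated; the reference allele plays
  the role of the wild-type parent.
* The simulator's error model is iid per read; systematic artefacts that the
  index/support filters exist to catch in real data are not generated, so
  those filters are exercised by constructed fixtures rather than by the
  generative model.
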