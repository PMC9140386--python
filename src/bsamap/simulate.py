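"""In-silico bulked-segregant mapping experiments with known ground truth.

This module builds complete synthetic MutMap-style experiments: an
EMS-mutagenised parent carrying one recessive causal mutation plus background
SNPs, an F2 population produced by selfing the F1 of a mutant x wild-type
cross, phenotype-based bulks, and short-read allele counts per bulk.  Every
stage is seeded, so a dataset is a pure function of its parameters.

The meiosis model is the standard no-interference one: crossover counts are
Poisson with mean ``map_length_cM / 100`` and positions are uniform, which at
any set of observed loci is equivalent to a Markov walk along the chromosome
whose flip probability between consecutive loci is the Haldane recombination
fraction ``r = (1 - exp(-2d/100)) / 2``.  The walk form is what is simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChromSpec",
    "GenomeSpec",
    "CausalLocus",
    "MutationModel",
    "BulkDesign",
    "DepthModel",
    "F2Population",
    "Bulk",
    "SimulatedDataset",
    "haldane_r",
    "simulate_parental_variants",
    "simulate_f2_population",
    "assign_phenotypes",
    "form_bulks",
    "form_random_bulks",
    "simulate_read_counts",
    "simulate_experiment",
    "write_dataset",
]

_NUCLEOTIDES = ("A", "C", "G", "T")
#: EMS predominantly alkylates guanine: G:C -> A:T transitions.
_TRANSITIONS = (("G", "A"), ("C", "T"))
_OTHER_PAIRS = tuple(
    (r, a)
    for r in _NUCLEOTIDES
    for a in _NUCLEOTIDES
    if r != a and (r, a) not in _TRANSITIONS
)

#: Canonical column order for a table of per-site, per-bulk read counts.
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "mut_ref",
    "mut_alt",
    "wt_ref",
    "wt_alt",
]


@dataclass(frozen=True)
class ChromSpec:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    map_length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length_bp must be >= 1")
        if not self.map_length_cM > 0:
            raise ValueError(f"chromosome {self.name}: map_length_cM must be > 0")


@dataclass(frozen=True)
class GenomeSpec:
    """A desk-scale stand-in for a reference genome.

    The physical->genetic map is linear per chromosome (uniform cM/Mb).
    """

    chromosomes: tuple[ChromSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if not names:
            raise ValueError("genome must have at least one chromosome")

    @classmethod
    def default(cls) -> "GenomeSpec":
        """Two 30-Mb chromosomes of 100 cM each: small enough for minutes-scale
        runs, large enough to show the decay of the mapping signal."""
        return cls(
            chromosomes=(
                ChromSpec("chr1", 30_000_000, 100.0),
                ChromSpec("chr2", 30_000_000, 100.0),
            )
        )

    def chrom(self, name: str) -> ChromSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    def genetic_pos(self, chrom: str, pos: np.ndarray | int) -> np.ndarray:
        """Linear interpolation bp -> cM."""
        c = self.chrom(chrom)
        return np.asarray(pos, dtype=float) / c.length_bp * c.map_length_cM


@dataclass(frozen=True)
class CausalLocus:
    """The single recessive causal mutation; default an EMS G->A transition."""

    chrom: str
    pos: int
    ref: str = "G"
    alt: str = "A"
    inheritance: str = "recessive"

    def __post_init__(self) -> None:
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError("alleles must be single nucleotides")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class MutationModel:
    """EMS-style background SNP model.

    ``transition_fraction`` is the share of G:C -> A:T changes; EMS is heavily
    transition-biased, so the default is 0.9.
    """

    snp_rate_per_Mb: float = 10.0
    transition_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snp_rate_per_Mb < 0 or not np.isfinite(self.snp_rate_per_Mb):
            raise ValueError("snp_rate_per_Mb must be finite and >= 0")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValueError("transition_fraction must be in [0, 1]")


@dataclass(frozen=True)
class BulkDesign:
    """Bulk sizes; default 20 mutant-phenotype and 20 wild-phenotype plants."""

    n_mutant_bulk: int = 20
    n_wild_bulk: int = 20

    def __post_init__(self) -> None:
        if self.n_mutant_bulk < 1 or self.n_wild_bulk < 1:
            raise ValueError("bulk sizes must be positive")


@dataclass(frozen=True)
class DepthModel:
    """Sequencing summary: per-site depth ~ Poisson(mean_depth), base error
    rate applied symmetrically to both alleles."""

    mean_depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class F2Population:
    """An F2 population over a set of variant sites.

    ``genotypes`` is an (n_individuals, n_variants) array counting copies of
    the mutant (alt) allele; ``phenotypes`` is a boolean array, True = mutant
    phenotype (set by :func:`assign_phenotypes`).
    """

    variants: pd.DataFrame  # columns chrom, pos, ref, alt
    genotypes: np.ndarray
    phenotypes: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def causal_index(self, causal: CausalLocus) -> int:
        m = (self.variants["chrom"] == causal.chrom) & (
            self.variants["pos"] == causal.pos
        )
        idx = np.flatnonzero(m.to_numpy())
        if idx.size != 1:
            raise ValueError("causal locus not present exactly once among variants")
        return int(idx[0])


@dataclass
class Bulk:
    """Indices of bulked individuals plus their mutant-allele frequency per site."""

    members: np.ndarray
    allele_freq: np.ndarray


@dataclass
class SimulatedDataset:
    """A complete simulated experiment: per-site counts for both bulks, the
    ground-truth causal locus, and the phenotype tally of the population."""

    sites: pd.DataFrame  # SITE_COLUMNS
    truth: CausalLocus
    n_mutant_pheno: int
    n_wild_pheno: int
    manifest: dict = field(default_factory=dict)


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_parental_variants(
    genome: GenomeSpec,
    model: MutationModel,
    causal: CausalLocus,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw the mutant parent's SNPs relative to the reference.

    The causal locus is always included.  Background SNP counts per chromosome
    are Poisson(rate x Mb); positions are uniform without replacement; each
    ref->alt pair is a G:C->A:T transition with probability
    ``transition_fraction``, otherwise uniform over the remaining pairs.

    Returns a DataFrame with columns chrom, pos, ref, alt sorted by
    (chrom order in the genome, pos), positions unique per chromosome.
    """
    causal_chrom = genome.chrom(causal.chrom)  # KeyError if absent
    if causal.pos > causal_chrom.length_bp:
        raise ValueError(
            f"causal position {causal.pos} outside {causal.chrom} "
            f"(length {causal_chrom.length_bp})"
        )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rows: list[pd.DataFrame] = []
    for c in genome.chromosomes:
        n_bg = rng.poisson(model.snp_rate_per_Mb * c.length_bp / 1e6)
        n_bg = min(n_bg, c.length_bp - 1)  # cannot exceed available positions
        taken = {causal.pos} if c.name == causal.chrom else set()
        pos: list[int] = []
        while len(pos) < n_bg:
            cand = rng.integers(1, c.length_bp + 1, size=n_bg - len(pos))
            for p in cand:
                p = int(p)
                if p not in taken:
                    taken.add(p)
                    pos.append(p)
        is_ts = rng.random(len(pos)) < model.transition_fraction
        ts_pick = rng.integers(0, len(_TRANSITIONS), size=len(pos))
        other_pick = rng.integers(0, len(_OTHER_PAIRS), size=len(pos))
        refs = [
            (_TRANSITIONS[t] if ts else _OTHER_PAIRS[o])[0]
            for ts, t, o in zip(is_ts, ts_pick, other_pick)
        ]
        alts = [
            (_TRANSITIONS[t] if ts else _OTHER_PAIRS[o])[1]
            for ts, t, o in zip(is_ts, ts_pick, other_pick)
        ]
        df = pd.DataFrame({"chrom": c.name, "pos": pos, "ref": refs, "alt": alts})
        if c.name == causal.chrom:
            df = pd.concat(
                [
                    df,
                    pd.DataFrame(
                        {
                            "chrom": [causal.chrom],
                            "pos": [causal.pos],
                            "ref": [causal.ref],
                            "alt": [causal.alt],
                        }
                    ),
                ],
                ignore_index=True,
            )
        rows.append(df.sort_values("pos", kind="stable"))
    out = pd.concat(rows, ignore_index=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out


def _simulate_gametes(
    cM: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Haplotypes (0 = wild, 1 = mutant parent) for one chromosome.

    Markov walk along sorted loci: start Bernoulli(1/2), flip between
    consecutive loci with the Haldane recombination fraction.  Equivalent to
    Poisson crossovers with no interference.
    """
    order = np.argsort(cM, kind="stable")
    m = len(cM)
    steps = np.empty((n_gametes, m), dtype=np.int8)
    steps[:, 0] = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    if m > 1:
        r = haldane_r(np.diff(cM[order]))
        steps[:, 1:] = rng.random((n_gametes, m - 1)) < r
    hap_sorted = (np.cumsum(steps, axis=1, dtype=np.int64) % 2).astype(np.int8)
    hap = np.empty_like(hap_sorted)
    hap[:, order] = hap_sorted
    return hap


def simulate_f2_population(
    variants: pd.DataFrame,
    genome: GenomeSpec,
    n: int,
    seed: int = 0,
) -> F2Population:
    """Self the (fully heterozygous) F1: each F2 individual is the union of
    two independent gametes; genotypes count mutant-allele copies.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    genotypes = np.zeros((n, len(variants)), dtype=np.int8)
    for c in genome.chromosomes:
        mask = (variants["chrom"] == c.name).to_numpy()
        if not mask.any():
            continue
        pos = variants.loc[mask, "pos"].to_numpy()
        if (pos < 1).any() or (pos > c.length_bp).any():
            raise ValueError(f"variant position outside chromosome {c.name}")
        cM = genome.genetic_pos(c.name, pos)
        g1 = _simulate_gametes(cM, n, rng)
        g2 = _simulate_gametes(cM, n, rng)
        genotypes[:, mask] = g1 + g2
    extra = set(variants["chrom"]) - {c.name for c in genome.chromosomes}
    if extra:
        raise ValueError(f"variants on chromosomes absent from the genome: {extra}")
    return F2Population(variants=variants.reset_index(drop=True), genotypes=genotypes)


def assign_phenotypes(
    pop: F2Population,
    causal: CausalLocus,
    misclassification_rate: float = 0.0,
    seed: int = 0,
) -> F2Population:
    """Recessive phenotype: mutant iff homozygous for the causal allele.

    ``misclassification_rate`` flips each phenotype call independently with the
    given probability (default 0: error-free phenotyping).
    """
    j = pop.causal_index(causal)
    pheno = pop.genotypes[:, j] == 2
    if misclassification_rate > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(pop.n) < misclassification_rate
        pheno = pheno ^ flip
    pop.phenotypes = pheno
    return pop


def _bulk_from_members(pop: F2Population, members: np.ndarray) -> Bulk:
    freq = pop.genotypes[members].mean(axis=0) / 2.0
    return Bulk(members=members, allele_freq=freq)


def form_bulks(
    pop: F2Population, design: BulkDesign, seed: int = 0
) -> tuple[Bulk, Bulk]:
    """Sample the mutant- and wild-phenotype bulks without replacement."""
    if pop.phenotypes is None:
        raise ValueError("phenotypes not assigned; call assign_phenotypes first")
    rng = np.random.default_rng(seed)
    mut_pool = np.flatnonzero(pop.phenotypes)
    wt_pool = np.flatnonzero(~pop.phenotypes)
    if len(mut_pool) < design.n_mutant_bulk:
        raise ValueError(
            f"need {design.n_mutant_bulk} mutant-phenotype individuals, "
            f"only {len(mut_pool)} available (short {design.n_mutant_bulk - len(mut_pool)})"
        )
    if len(wt_pool) < design.n_wild_bulk:
        raise ValueError(
            f"need {design.n_wild_bulk} wild-phenotype individuals, "
            f"only {len(wt_pool)} available (short {design.n_wild_bulk - len(wt_pool)})"
        )
    mut_members = rng.choice(mut_pool, size=design.n_mutant_bulk, replace=False)
    wt_members = rng.choice(wt_pool, size=design.n_wild_bulk, replace=False)
    return _bulk_from_members(pop, mut_members), _bulk_from_members(pop, wt_members)


def form_random_bulks(
    pop: F2Population, design: BulkDesign, seed: int = 0
) -> tuple[Bulk, Bulk]:
    """Bulks drawn at random, ignoring phenotype — the no-causal-conditioning
    control used for null-calibration runs."""
    total = design.n_mutant_bulk + design.n_wild_bulk
    if pop.n < total:
        raise ValueError(f"need {total} individuals, only {pop.n} available")
    rng = np.random.default_rng(seed)
    picks = rng.choice(pop.n, size=total, replace=False)
    return (
        _bulk_from_members(pop, picks[: design.n_mutant_bulk]),
        _bulk_from_members(pop, picks[design.n_mutant_bulk :]),
    )


def simulate_read_counts(
    bulks: tuple[Bulk, Bulk],
    variants: pd.DataFrame,
    depth: DepthModel,
    truth: CausalLocus,
    pheno_counts: tuple[int, int] = (0, 0),
    seed: int | None = None,
) -> SimulatedDataset:
    """Draw per-site read counts for both bulks.

    Per site and bulk: total depth ~ Poisson(mean_depth); alt reads ~
    Binomial(depth, p(1-e) + (1-p)e) where p is the bulk's true mutant-allele
    frequency and e the base error rate.  Depth 0 yields a missing-capable
    site (both counts 0).
    """
    rng = np.random.default_rng(depth.seed if seed is None else seed)
    mut_bulk, wt_bulk = bulks
    m = len(variants)
    out = {"chrom": variants["chrom"], "pos": variants["pos"],
           "ref": variants["ref"], "alt": variants["alt"]}
    for label, bulk in (("mut", mut_bulk), ("wt", wt_bulk)):
        total = rng.poisson(depth.mean_depth, size=m)
        p_read = bulk.allele_freq * (1 - depth.error_rate) + (
            1 - bulk.allele_freq
        ) * depth.error_rate
        alt = rng.binomial(total, p_read)
        out[f"{label}_ref"] = total - alt
        out[f"{label}_alt"] = alt
    sites = pd.DataFrame(out)[SITE_COLUMNS].reset_index(drop=True)
    return SimulatedDataset(
        sites=sites,
        truth=truth,
        n_mutant_pheno=pheno_counts[0],
        n_wild_pheno=pheno_counts[1],
    )


def simulate_experiment(
    genome: GenomeSpec | None = None,
    causal: CausalLocus | None = None,
    mutation: MutationModel | None = None,
    design: BulkDesign | None = None,
    depth: DepthModel | None = None,
    n_f2: int = 200,
    seed: int = 0,
    causal_conditioning: bool = True,
) -> SimulatedDataset:
    """One full experiment: parent SNPs -> F2 -> phenotypes -> bulks -> reads.

    All stage seeds derive from ``seed`` via ``numpy.random.SeedSequence``.
    With ``causal_conditioning=False`` the bulks are random samples of the
    population (the null control).
    """
    genome = genome or GenomeSpec.default()
    causal = causal or CausalLocus(
        chrom=genome.chromosomes[-1].name,
        pos=genome.chromosomes[-1].length_bp // 2,
    )
    mutation = mutation or MutationModel()
    design = design or BulkDesign()
    depth = depth or DepthModel()
    ss = np.random.SeedSequence(seed)
    s_var, s_pop, s_bulk, s_reads = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    variants = simulate_parental_variants(genome, mutation, causal, seed=s_var)
    pop = simulate_f2_population(variants, genome, n=n_f2, seed=s_pop)
    pop = assign_phenotypes(pop, causal)
    if causal_conditioning:
        bulks = form_bulks(pop, design, seed=s_bulk)
    else:
        bulks = form_random_bulks(pop, design, seed=s_bulk)
    n_mut = int(pop.phenotypes.sum())
    ds = simulate_read_counts(
        bulks, variants, depth, truth=causal,
        pheno_counts=(n_mut, pop.n - n_mut), seed=s_reads,
    )
    ds.manifest = {
        "seed": seed,
        "n_f2": n_f2,
        "causal_conditioning": causal_conditioning,
        "genome": [dataclasses.asdict(c) for c in genome.chromosomes],
        "causal": dataclasses.asdict(causal),
        "mutation_model": dataclasses.asdict(mutation),
        "bulk_design": dataclasses.asdict(design),
        "depth_model": dataclasses.asdict(depth),
        "n_mutant_pheno": ds.n_mutant_pheno,
        "n_wild_pheno": ds.n_wild_pheno,
    }
    return ds


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the VCF, the truth TSV and the run manifest; returns the paths."""
    from . import vcfio  # local import: vcfio depends on SITE_COLUMNS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "bulks.vcf",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.yaml",
    }
    genome = (
        GenomeSpec(tuple(ChromSpec(**c) for c in dataset.manifest["genome"]))
        if dataset.manifest.get("genome")
        else None
    )
    vcfio.write_vcf(dataset.sites, paths["vcf"], genome=genome)
    pd.DataFrame(
        {
            "chrom": [dataset.truth.chrom],
            "pos": [dataset.truth.pos],
            "ref": [dataset.truth.ref],
            "alt": [dataset.truth.alt],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(dataset.manifest, fh, sort_keys=True)
    if genome is not None:
        paths["genome"] = vcfio.write_genome_tsv(genome, out / "genome.tsv")
    return paths
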