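"""The umbrella run: simulate -> map -> annotate -> report.

A run is a pure function of its :class:`RunConfig`: identical configs (and
seeds) produce identical tables.  The config round-trips losslessly through
YAML and rejects unknown keys, so a run directory's echoed config fully
documents the run.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import mapping, vcfio
from .annotate import GeneModel, annotate as annotate_snp, prioritize
from .simulate import (
    BulkDesign,
    CausalLocus,
    ChromSpec,
    DepthModel,
    GenomeSpec,
    MutationModel,
    simulate_experiment,
    write_dataset,
)

__all__ = ["RunConfig", "RunResult", "run_all", "build_gene_fixture",
           "synthesize_genome_sequence"]

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChromConfig(_Strict):
    name: str
    length_bp: int
    map_length_cM: float


class CausalConfig(_Strict):
    chrom: str
    pos: int
    ref: str = "G"
    alt: str = "A"


class MutationConfig(_Strict):
    snp_rate_per_Mb: float = 10.0
    transition_fraction: float = 0.9


class BulkConfig(_Strict):
    n_mutant_bulk: int = 20
    n_wild_bulk: int = 20


class DepthConfig(_Strict):
    mean_depth: float = 30.0
    error_rate: float = 0.0


class FilterConfigModel(_Strict):
    min_index: float = 0.3
    min_support: int = 7
    drop_if_missing_one_bulk: bool = True


class WindowConfigModel(_Strict):
    window_bp: int = 2_000_000
    step_bp: int = 50_000
    min_snps_per_window: int = 3


class ThresholdConfigModel(_Strict):
    n_rep: int = 1000
    confidence: float = 0.95


class RunConfig(_Strict):
    """Every stage parameter plus the master seed; YAML round-trippable."""

    genome: list[ChromConfig] = Field(
        default_factory=lambda: [
            ChromConfig(name="chr1", length_bp=30_000_000, map_length_cM=100.0),
            ChromConfig(name="chr2", length_bp=30_000_000, map_length_cM=100.0),
        ]
    )
    causal: CausalConfig | None = None  # default: middle of the last chromosome
    mutation: MutationConfig = Field(default_factory=MutationConfig)
    bulks: BulkConfig = Field(default_factory=BulkConfig)
    depth: DepthConfig = Field(default_factory=DepthConfig)
    filters: FilterConfigModel = Field(default_factory=FilterConfigModel)
    windows: WindowConfigModel = Field(default_factory=WindowConfigModel)
    thresholds: ThresholdConfigModel = Field(default_factory=ThresholdConfigModel)
    n_f2: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(
            tuple(ChromSpec(c.name, c.length_bp, c.map_length_cM) for c in self.genome)
        )

    def causal_locus(self) -> CausalLocus:
        if self.causal is not None:
            return CausalLocus(
                self.causal.chrom, self.causal.pos, self.causal.ref, self.causal.alt
            )
        last = self.genome[-1]
        return CausalLocus(last.name, last.length_bp // 2)


class RunResult(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    out_dir: Path
    truth_recovered: bool
    causal_effect: str
    n_candidates: int
    funnel: dict


def synthesize_genome_sequence(
    genome: GenomeSpec, seed: int = 0
) -> dict[str, bytearray]:
    """Deterministic random nucleotide sequence per chromosome (mutable, so
    variant ref alleles and gene codons can be patched in)."""
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for c in genome.chromosomes:
        codes = rng.integers(0, 4, size=c.length_bp, dtype=np.uint8)
        out[c.name] = bytearray(lut[codes].tobytes())
    return out


#: Stop-free codons used to pad the synthetic gene body.
_PAD_CODONS = ("GCT", "AAG", "CTG", "GAC", "TTC", "GGA", "CAC", "ATC")


def build_gene_fixture(
    causal: CausalLocus,
    seq: Mapping[str, bytearray],
    gene_id: str = "GENE_causal",
    n_codons: int = 100,
) -> GeneModel:
    """Write a single-exon CDS around the causal locus into the sequence.

    The causal position lands on the third base of an internal codon built as
    'TG' + ref, so the canonical G->A change turns TGG (Trp) into the TGA
    stop — a stop gain.  The CDS starts ATG, ends TAA, and is padded with
    stop-free codons.
    """
    codon_of_causal = n_codons // 2
    start = causal.pos - (3 * codon_of_causal + 2)
    if start < 1:
        raise ValueError("causal locus too close to the chromosome start")
    chrom_seq = seq[causal.chrom]
    if start + 3 * n_codons - 1 > len(chrom_seq):
        raise ValueError("causal locus too close to the chromosome end")
    codons = ["ATG"]
    for i in range(1, n_codons - 1):
        if i == codon_of_causal:
            codons.append("TG" + causal.ref)
        else:
            codons.append(_PAD_CODONS[i % len(_PAD_CODONS)])
    codons.append("TAA")
    cds = "".join(codons).encode()
    chrom_seq[start - 1 : start - 1 + len(cds)] = cds
    return GeneModel(
        gene_id=gene_id,
        chrom=causal.chrom,
        strand="+",
        cds_exons=((start, start + len(cds) - 1),),
    )


def run_all(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute the full pipeline into a run directory.

    Stages: simulate the experiment, write the dataset, map it, build the
    synthetic gene fixture around the causal locus, annotate the SNPs inside
    the top candidate interval, and write a report stating whether the truth
    locus sits inside the top interval and what its codon-level effect is.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("bsamap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_all_inner(config, out)
    except Exception:
        logger.exception("run aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all_inner(config: RunConfig, out: Path) -> RunResult:
    config.to_yaml(out / "config.yaml")
    genome = config.genome_spec()
    causal = config.causal_locus()
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_map, s_seq = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    logger.info("stage simulate: n_f2=%d seed=%d", config.n_f2, s_sim)
    ds = simulate_experiment(
        genome=genome,
        causal=causal,
        mutation=MutationModel(**config.mutation.model_dump()),
        design=BulkDesign(**config.bulks.model_dump()),
        depth=DepthModel(**config.depth.model_dump()),
        n_f2=config.n_f2,
        seed=s_sim,
    )
    paths = write_dataset(ds, out / "dataset")
    logger.info(
        "stage simulate: %d sites, %d/%d mutant/wild phenotypes",
        len(ds.sites), ds.n_mutant_pheno, ds.n_wild_pheno,
    )

    window_cfg = mapping.WindowConfig(**config.windows.model_dump())
    if window_cfg.window_bp >= min(c.length_bp for c in genome.chromosomes):
        logger.warning(
            "window (%d bp) is not smaller than a chromosome; "
            "that chromosome forms a single whole-chromosome window",
            window_cfg.window_bp,
        )
    report = mapping.map_dataset(
        paths["vcf"],
        genome,
        filter_cfg=mapping.FilterConfig(**config.filters.model_dump()),
        window_cfg=window_cfg,
        bulk_design=BulkDesign(**config.bulks.model_dump()),
        n_rep=config.thresholds.n_rep,
        confidence=config.thresholds.confidence,
        seed=s_map,
        out_dir=out / "mapping",
    )
    logger.info("stage map: funnel %s", report.funnel)

    seq = synthesize_genome_sequence(genome, seed=s_seq)
    gene = build_gene_fixture(causal, seq)
    # patch every simulated ref allele into the sequence so annotation's
    # reference check holds (the causal ref equals the fixture codon base)
    for row in ds.sites.itertuples(index=False):
        seq[row.chrom][row.pos - 1] = ord(row.ref)
    genome_str = {k: bytes(v).decode() for k, v in seq.items()}

    top = max(report.candidates, key=lambda c: c.peak_delta, default=None)
    truth_recovered = bool(
        top is not None
        and top.chrom == causal.chrom
        and top.start <= causal.pos <= top.end
    )
    effects = []
    if top is not None:
        in_top = ds.sites[
            (ds.sites["chrom"] == top.chrom)
            & (ds.sites["pos"] >= top.start)
            & (ds.sites["pos"] <= top.end)
        ]
        for row in in_top.itertuples(index=False):
            effects.extend(
                annotate_snp(row.chrom, int(row.pos), row.ref, row.alt,
                             [gene], genome_str)
            )
    effects = prioritize(effects)
    pd.DataFrame([vars(e) for e in effects]).to_csv(
        out / "candidate_effects.tsv", sep="\t", index=False
    )
    causal_effect = next(
        (e.category for e in effects
         if e.chrom == causal.chrom and e.pos == causal.pos),
        "not_in_top_interval",
    )
    logger.info(
        "stage annotate: %d effects in top interval; causal effect %s",
        len(effects), causal_effect,
    )
    summary = {
        "truth_recovered": truth_recovered,
        "causal_effect": causal_effect,
        "n_candidates": len(report.candidates),
        "funnel": report.funnel,
        "truth": {"chrom": causal.chrom, "pos": causal.pos},
        "top_interval": None if top is None else vars(top),
    }
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return RunResult(
        out_dir=out,
        truth_recovered=truth_recovered,
        causal_effect=causal_effect,
        n_candidates=len(report.candidates),
        funnel=report.funnel,
    )
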