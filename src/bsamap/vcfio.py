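"""Reading and writing the pipeline's plain-text formats.

The variant interchange format is a minimal VCF v4.2 dialect: biallelic SNPs
with FORMAT ``AD`` (ref,alt allele depths) for exactly two samples,
``bulk_mut`` and ``bulk_wt``.  Reading goes through :mod:`pysam`; a light
pre-validation pass supplies line numbers for malformed rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .simulate import CausalLocus, ChromSpec, GenomeSpec, SITE_COLUMNS

__all__ = [
    "VcfFormatError",
    "write_vcf",
    "read_vcf",
    "read_truth",
    "read_manifest",
    "read_genome_tsv",
    "write_genome_tsv",
]

logger = logging.getLogger(__name__)

MUT_SAMPLE = "bulk_mut"
WT_SAMPLE = "bulk_wt"

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=AD,Number=R,Type=Integer,'
    'Description="Allelic depths for the ref and alt alleles">',
]


class VcfFormatError(ValueError):
    """A malformed VCF record, reported with its 1-based line number."""


def write_vcf(
    sites: pd.DataFrame, path: str | Path, genome: GenomeSpec | None = None
) -> Path:
    """Write a site-count table as the two-sample AD-only VCF dialect."""
    path = Path(path)
    lines = list(_HEADER_LINES)
    if genome is not None:
        for c in genome.chromosomes:
            lines.append(f"##contig=<ID={c.name},length={c.length_bp}>")
    else:
        for chrom in pd.unique(sites["chrom"]):
            lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{MUT_SAMPLE}\t{WT_SAMPLE}"
    )
    for row in sites.itertuples(index=False):
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tAD\t"
            f"{row.mut_ref},{row.mut_alt}\t{row.wt_ref},{row.wt_alt}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _prevalidate(path: Path) -> None:
    """Cheap structural check so malformed rows are reported by line number."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise VcfFormatError(
                        f"{path}:{lineno}: header lacks FORMAT/sample columns"
                    )
                n_cols = len(fields)
                continue
            if n_cols is None:
                raise VcfFormatError(f"{path}:{lineno}: record before #CHROM header")
            if len(fields) != n_cols:
                raise VcfFormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            if not fields[1].isdigit() or int(fields[1]) < 1:
                raise VcfFormatError(
                    f"{path}:{lineno}: POS must be a positive integer, got {fields[1]!r}"
                )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Parse the dialect into a site-count table (SITE_COLUMNS).

    Samples other than ``bulk_mut``/``bulk_wt`` are ignored with a warning;
    their absence is an error.  Positions stay 1-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate(path)
    rows: list[tuple] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for s in (MUT_SAMPLE, WT_SAMPLE):
            if s not in samples:
                raise VcfFormatError(f"{path}: required sample column {s!r} missing")
        extra = [s for s in samples if s not in (MUT_SAMPLE, WT_SAMPLE)]
        if extra:
            logger.warning("%s: ignoring extra sample columns %s", path, extra)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfFormatError(
                    f"{path}: {rec.chrom}:{rec.pos} is not biallelic"
                )
            ad_mut = rec.samples[MUT_SAMPLE].get("AD")
            ad_wt = rec.samples[WT_SAMPLE].get("AD")
            if ad_mut is None or ad_wt is None or None in ad_mut or None in ad_wt:
                ad_mut = tuple(0 if v is None else v for v in (ad_mut or (0, 0)))
                ad_wt = tuple(0 if v is None else v for v in (ad_wt or (0, 0)))
            rows.append(
                (
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0],
                    int(ad_mut[0]),
                    int(ad_mut[1]),
                    int(ad_wt[0]),
                    int(ad_wt[1]),
                )
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def read_truth(path: str | Path) -> CausalLocus:
    df = pd.read_csv(path, sep="\t")
    row = df.iloc[0]
    return CausalLocus(
        chrom=str(row["chrom"]), pos=int(row["pos"]),
        ref=str(row["ref"]), alt=str(row["alt"]),
    )


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_genome_tsv(path: str | Path) -> GenomeSpec:
    """Read a genome spec TSV: ``name  length_bp  map_length_cM``."""
    df = pd.read_csv(path, sep="\t")
    return GenomeSpec(
        tuple(
            ChromSpec(str(r["name"]), int(r["length_bp"]), float(r["map_length_cM"]))
            for _, r in df.iterrows()
        )
    )


def write_genome_tsv(genome: GenomeSpec, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "name": [c.name for c in genome.chromosomes],
            "length_bp": [c.length_bp for c in genome.chromosomes],
            "map_length_cM": [c.map_length_cM for c in genome.chromosomes],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
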