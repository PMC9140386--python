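"""Codon-level consequence annotation of candidate SNPs.

Classifies each SNP against single-transcript CDS gene models into
stop_gain, stop_loss, nonsynonymous, synonymous, splice_site, intronic or
intergenic, using the standard nuclear genetic code.  The canonical positive
case for a recessive EMS screen is a G->A change at the third base of a TGG
(Trp) codon producing the TGA stop — a stop gain that truncates the protein.

Splice convention: the two intronic bases flanking each internal exon
boundary are splice_site (the categorisation ANNOVAR-style annotators use).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "VariantEffect",
    "PrematureStopError",
    "RefMismatchError",
    "CATEGORY_RANK",
    "translate_cds",
    "annotate",
    "annotate_table",
    "prioritize",
    "load_gene_models_tsv",
    "load_gene_models_gff3",
    "read_fasta",
]

#: Candidate preference: truncations first, then missense, then splice
#: disruption, then everything else.
CATEGORY_RANK = {
    "stop_loss": 1,
    "stop_gain": 1,
    "nonsynonymous": 2,
    "splice_site": 3,
    "synonymous": 4,
    "intronic": 4,
    "intergenic": 4,
}

_SPLICE_FLANK = 2


class PrematureStopError(ValueError):
    """An internal stop codon in a CDS; ``codon_index`` is 1-based."""

    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"premature stop codon at codon {codon_index}")


class RefMismatchError(ValueError):
    """The variant's ref allele disagrees with the genome sequence."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene: ordered CDS exons.

    Intervals are 1-based inclusive on the reference; ``strand`` is '+' or
    '-'.  The exon list is stored in genomic order regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = self.cds_exons
        if not exons:
            raise ValueError("gene model needs at least one CDS exon")
        for (s, e) in exons:
            if s > e or s < 1:
                raise ValueError(f"bad exon interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError("exons must be sorted and non-overlapping")
        if self.cds_length % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Coding-strand CDS sequence assembled from the genome."""
        seq = genome[self.chrom]
        parts = [seq[s - 1 : e] for s, e in self.cds_exons]
        cds = "".join(parts).upper()
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the coding sequence,
        or None if the position is not exonic."""
        running = 0
        if self.strand == "+":
            for s, e in self.cds_exons:
                if s <= pos <= e:
                    return running + (pos - s)
                running += e - s + 1
        else:
            for s, e in reversed(self.cds_exons):
                if s <= pos <= e:
                    return running + (e - pos)
                running += e - s + 1
        return None


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    category: str
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    protein_pos: int | None = None  # 1-based codon index

    @property
    def rank(self) -> int:
        return CATEGORY_RANK[self.category]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, dropping the terminal stop.

    Raises :class:`PrematureStopError` on an internal stop codon — the mutant
    signature of a stop-gain allele.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    protein = str(Seq(cds).translate())
    stop_at = protein.find("*")
    if 0 <= stop_at < len(protein) - 1:
        raise PrematureStopError(stop_at + 1)
    return protein[:-1] if protein.endswith("*") else protein


def _classify_exonic(
    gene: GeneModel, genome: Mapping[str, str], pos: int, ref: str, alt: str,
    offset: int,
) -> VariantEffect:
    cds = gene.cds_sequence(genome)
    if gene.strand == "-":
        ref_c = str(Seq(ref).reverse_complement())
        alt_c = str(Seq(alt).reverse_complement())
    else:
        ref_c, alt_c = ref, alt
    if cds[offset] != ref_c:
        raise RefMismatchError(
            f"{gene.gene_id}: CDS base {cds[offset]!r} at {gene.chrom}:{pos} "
            f"does not match ref allele {ref!r}"
        )
    codon_i = offset // 3
    within = offset % 3
    codon_ref = cds[codon_i * 3 : codon_i * 3 + 3]
    codon_alt = codon_ref[:within] + alt_c + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref == aa_alt:
        category = "synonymous"
    elif aa_alt == "*":
        category = "stop_gain"
    elif aa_ref == "*":
        category = "stop_loss"
    else:
        category = "nonsynonymous"
    return VariantEffect(
        chrom=gene.chrom, pos=pos, ref=ref, alt=alt, gene_id=gene.gene_id,
        category=category, codon_ref=codon_ref, codon_alt=codon_alt,
        aa_ref=aa_ref, aa_alt=aa_alt, protein_pos=codon_i + 1,
    )


def annotate(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[VariantEffect]:
    """Annotate one SNP against every overlapping gene model.

    Returns one effect per overlapping gene (all of them when genes overlap),
    or a single intergenic effect when none does.  The ref allele must match
    the genome sequence at ``pos`` (error otherwise).
    """
    if chrom not in genome:
        raise KeyError(f"no sequence for chromosome {chrom!r}")
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
    genome_base = seq[pos - 1].upper()
    if genome_base != ref.upper():
        raise RefMismatchError(
            f"genome has {genome_base!r} at {chrom}:{pos}, variant ref is {ref!r}"
        )
    effects: list[VariantEffect] = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        lo, hi = gene.span
        if not (lo - _SPLICE_FLANK) <= pos <= (hi + _SPLICE_FLANK):
            continue
        offset = gene.cds_offset(pos)
        if offset is not None:
            effects.append(_classify_exonic(gene, genome, pos, ref, alt, offset))
            continue
        if not lo <= pos <= hi:
            continue  # just outside the CDS span: not this gene's variant
        category = "intronic"
        for (_, e0), (s1, _) in zip(gene.cds_exons, gene.cds_exons[1:]):
            if e0 < pos < s1 and (pos - e0 <= _SPLICE_FLANK or s1 - pos <= _SPLICE_FLANK):
                category = "splice_site"
                break
        effects.append(
            VariantEffect(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene_id=gene.gene_id, category=category,
            )
        )
    if not effects:
        effects.append(
            VariantEffect(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene_id=None, category="intergenic",
            )
        )
    return effects


def prioritize(effects: Iterable[VariantEffect]) -> list[VariantEffect]:
    """Order candidates: truncating first, then missense, then splice, then
    the rest; ties broken by (chrom, pos); stable within ties."""
    return sorted(effects, key=lambda e: (e.rank, e.chrom, e.pos))


def annotate_table(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> pd.DataFrame:
    """Annotate every row of a site table; one output row per effect."""
    rows = []
    for row in sites.itertuples(index=False):
        for eff in annotate(row.chrom, int(row.pos), row.ref, row.alt, genes, genome):
            rows.append(vars(eff) | {k: getattr(row, k) for k in sites.columns
                                     if k not in ("chrom", "pos", "ref", "alt")})
    return pd.DataFrame(rows)


def load_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    """Read the minimal gene-model TSV:
    ``gene_id  chrom  strand  exon_start  exon_end`` (one row per CDS exon)."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for (gid, chrom, strand), grp in df.groupby(
        ["gene_id", "chrom", "strand"], sort=False
    ):
        exons = tuple(
            sorted((int(s), int(e)) for s, e in zip(grp["exon_start"], grp["exon_end"]))
        )
        genes.append(GeneModel(str(gid), str(chrom), str(strand), exons))
    return genes


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def load_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read the CDS-feature subset of a GFF3 file into gene models.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``ID``); other feature types are ignored.
    """
    by_parent: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "CDS":
                continue
            attrs = dict(_GFF_ATTR.findall(fields[8]))
            parent = attrs.get("Parent", attrs.get("ID"))
            if parent is None:
                raise ValueError(f"CDS feature without Parent/ID: {line.rstrip()}")
            key = (parent, fields[0], fields[6])
            by_parent.setdefault(key, []).append((int(fields[3]), int(fields[4])))
    return [
        GeneModel(gid, chrom, strand, tuple(sorted(exons)))
        for (gid, chrom, strand), exons in by_parent.items()
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
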