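"""Recessive-pattern trio filtering and simplified consequence classes.

The trio design has three fixed roles drawn from the mapped risk region:
an affected dog homozygous for the risk haplotype, its carrier parent
(heterozygous), and an unrelated control homozygous for the non-risk
haplotype.  A candidate variant is retained only when its genotypes track
that pattern exactly: affected hom-alt, parent het, control hom-ref.

Consequence classification is deliberately interval-based: a variant is
intergenic outside every gene, UTR when inside an annotated UTR, missense
when a substitution inside an annotated CDS changes the encoded amino acid
(standard codon table), splice-site when within 2 bp of an exon boundary,
and "gene-coding other" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import ConfigError, InputError
from .formats import VariantRecord

logger = logging.getLogger(__name__)

GENOTYPES = ("hom-ref", "het", "hom-alt", "missing")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class TrioGenotypes:
    """Genotypes of the sequencing trio at one variant."""

    affected: str
    carrier_parent: str
    control: str

    def __post_init__(self) -> None:
        for role, g in (
            ("affected", self.affected),
            ("carrier_parent", self.carrier_parent),
            ("control", self.control),
        ):
            if g not in GENOTYPES:
                raise InputError(f"{role} genotype {g!r} not one of {GENOTYPES}")

    @property
    def complete(self) -> bool:
        return "missing" not in (self.affected, self.carrier_parent, self.control)

    @property
    def recessive_pattern(self) -> bool:
        return (
            self.affected == "hom-alt"
            and self.carrier_parent == "het"
            and self.control == "hom-ref"
        )


def recessive_filter(
    variants: list[tuple[VariantRecord, TrioGenotypes]],
    allow_carrier_homalt: bool = False,
) -> tuple[list[VariantRecord], int]:
    """Keep variants whose trio genotypes follow the strict recessive rule.

    Returns (retained records, number dropped for a missing genotype).
    ``allow_carrier_homalt`` relaxes the parent to het OR hom-alt (an
    incomplete-penetrance allowance); off by default.
    """
    retained = []
    n_missing = 0
    for rec, trio in variants:
        if not trio.complete:
            n_missing += 1
            continue
        ok = trio.recessive_pattern
        if allow_carrier_homalt:
            ok = ok or (
                trio.affected == "hom-alt"
                and trio.carrier_parent in ("het", "hom-alt")
                and trio.control == "hom-ref"
            )
        if ok:
            retained.append(rec)
    return retained, n_missing


def region_filter(
    variants: list[VariantRecord],
    chromosome: str,
    start_bp: int,
    end_bp: int,
) -> list[VariantRecord]:
    """Variants on ``chromosome`` with start <= pos <= end (1-based, inclusive)."""
    if start_bp > end_bp:
        raise InputError(f"empty region: start {start_bp} > end {end_bp}")
    return [
        v
        for v in variants
        if str(v.chromosome) == str(chromosome) and start_bp <= v.position_bp <= end_bp
    ]


SPLICE_MARGIN_BP = 2


def classify_consequence(variant: VariantRecord, annotation: pd.DataFrame) -> str:
    """Interval-based consequence class for one variant.

    ``annotation`` rows carry chrom, start, end (1-based inclusive),
    feature in {gene, exon, CDS, UTR5, UTR3}, gene, extra (for a CDS row the
    in-frame reference nucleotide sequence of that CDS).  Classes:
    ``intergenic``, ``5 prime UTR``, ``3 prime UTR``, ``splice site``,
    ``missense``, ``synonymous``, ``gene-coding other``.
    """
    pos = variant.position_bp
    rows = annotation[
        (annotation["chrom"].astype(str) == str(variant.chromosome))
        & (annotation["start"] <= pos)
        & (annotation["end"] >= pos)
    ]
    genes = rows[rows["feature"] == "gene"]
    if genes.empty:
        return "intergenic"

    utr5 = rows[rows["feature"] == "UTR5"]
    utr3 = rows[rows["feature"] == "UTR3"]
    if not utr5.empty:
        return "5 prime UTR"
    if not utr3.empty:
        return "3 prime UTR"

    # splice site: within 2 bp of an exon boundary but outside the exon
    gene_names = set(genes["gene"])
    exons = annotation[
        (annotation["feature"] == "exon") & annotation["gene"].isin(gene_names)
    ]
    in_exon = ((exons["start"] <= pos) & (exons["end"] >= pos)).any()
    near_boundary = (
        ((exons["start"] - SPLICE_MARGIN_BP <= pos) & (pos < exons["start"]))
        | ((exons["end"] < pos) & (pos <= exons["end"] + SPLICE_MARGIN_BP))
    ).any()
    if near_boundary and not in_exon:
        return "splice site"

    cds = rows[rows["feature"] == "CDS"]
    if cds.empty:
        return "gene-coding other"
    if not variant.is_snp:
        return "gene-coding other"
    row = cds.iloc[0]
    seq = row.get("extra")
    if not isinstance(seq, str) or not seq:
        logger.warning(
            "variant at %s:%d lies in CDS of %s without frame/sequence annotation",
            variant.chromosome, pos, row["gene"],
        )
        return "gene-coding other"
    offset = pos - int(row["start"])
    if offset >= len(seq):
        raise InputError(
            f"CDS sequence for {row['gene']} shorter than variant offset {offset}"
        )
    if seq[offset].upper() != variant.ref_allele.upper():
        logger.warning(
            "CDS sequence mismatch at %s:%d (annotation %s, variant ref %s)",
            variant.chromosome, pos, seq[offset], variant.ref_allele,
        )
    codon_start = (offset // 3) * 3
    ref_codon = seq[codon_start : codon_start + 3].upper()
    if len(ref_codon) < 3:
        return "gene-coding other"
    alt_codon = list(ref_codon)
    alt_codon[offset % 3] = variant.alt_allele.upper()
    alt_codon = "".join(alt_codon)
    aa_ref = CODON_TABLE.get(ref_codon)
    aa_alt = CODON_TABLE.get(alt_codon)
    if aa_ref is None or aa_alt is None:
        return "gene-coding other"
    return "missense" if aa_ref != aa_alt else "synonymous"


def classify_all(variants: list[VariantRecord], annotation: pd.DataFrame) -> list[VariantRecord]:
    """Classify every record, returning copies with consequence filled in."""
    out = []
    for v in variants:
        cls = classify_consequence(v, annotation)
        out.append(
            VariantRecord(
                chromosome=v.chromosome,
                position_bp=v.position_bp,
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                var_type=v.var_type,
                gene=v.gene if cls != "intergenic" else "",
                exon=v.exon,
                consequence=cls,
                aa_change=v.aa_change,
            )
        )
    return out
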