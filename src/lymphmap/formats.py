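"""Readers and writers for the on-disk text formats.

Supported dialects (all plain text, all coordinates 1-based inclusive):

* PLINK-style PED/MAP — six leading PED columns (family, id, sire, dam,
  sex, phenotype 1/2) then two allele columns per SNP; ``0 0`` is missing.
* A phased-haplotype sidecar (two allele rows per sample).
* A minimal VCF-like TSV (CHROM, POS, REF, ALT, then 0/0-style genotypes).
* BED-like gene/exon/UTR interval annotation (converted from half-open to
  1-based inclusive on read).
* The published variant table (Location, Type, Ref, Allele, Gene, Exon
  Number, Consequence, A.A.Change) where an insertion location ``a^b``
  means "between positions a and b" and is parsed to position a with an
  insertion flag.

Readers reject malformed input (naming the offending line) rather than
silently coercing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, InputError, make_phenotype_table

logger = logging.getLogger(__name__)

VALID_ALLELES = set("ACGT12")


@dataclass
class VariantRecord:
    """One row of the variant table (Table-1-shaped)."""

    chromosome: str
    position_bp: int
    ref_allele: str  # "-" for an insertion
    alt_allele: str
    var_type: str  # SNP, SNV (synonym of SNP) or Ins
    gene: str = ""
    exon: str = ""
    consequence: str = ""
    aa_change: str = "-"

    def __post_init__(self) -> None:
        if (self.var_type == "Ins") != (self.ref_allele == "-"):
            raise InputError(
                f"variant at {self.position_bp}: type Ins iff ref allele is '-'"
            )

    @property
    def is_snp(self) -> bool:
        return self.var_type in ("SNP", "SNV")


# ---------------------------------------------------------------------------
# PED / MAP

def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PED+MAP; doses count the MAP-declared/first-seen minor allele."""
    snps = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise InputError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            snps.append((parts[0], parts[1], int(parts[3])))
    m = len(snps)

    sample_ids, statuses, rows = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise InputError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns for {m} MAP SNPs, got {len(parts)}"
                )
            sid = parts[1]
            if sid in sample_ids:
                raise InputError(f"{ped_path}:{ln}: duplicated sample id {sid!r}")
            sample_ids.append(sid)
            statuses.append({"1": "control", "2": "case"}.get(parts[5], "control"))
            alleles = parts[6:]
            for a in alleles:
                if a != "0" and a not in VALID_ALLELES:
                    raise InputError(f"{ped_path}:{ln}: invalid allele code {a!r}")
            rows.append(alleles)

    n = len(sample_ids)
    allele_a = [""] * m
    allele_b = [""] * m
    doses = np.full((n, m), MISSING, dtype=np.int64)
    for j in range(m):
        # first pass: collect observed alleles and counts
        counts: dict[str, int] = {}
        for i in range(n):
            a1, a2 = rows[i][2 * j], rows[i][2 * j + 1]
            if (a1 == "0") != (a2 == "0"):
                raise InputError(f"{ped_path}: sample {sample_ids[i]} SNP {j + 1}: half-missing genotype")
            if a1 == "0":
                continue
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
        if len(counts) > 2:
            raise InputError(f"{ped_path}: SNP {j + 1}: more than two alleles {sorted(counts)}")
        if not counts:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        # counted (dose) allele = minor allele; ties and monomorphic SNPs
        # resolve to the first-seen allele
        ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        minor = ordered[0][0]
        if len(ordered) == 1:
            # monomorphic: the only observed allele is the counted allele
            allele_a[j], allele_b[j] = "0", minor
            doses[:, j] = [2 if rows[i][2 * j] != "0" else MISSING for i in range(n)]
            continue
        major = ordered[-1][0]
        allele_a[j], allele_b[j] = major, minor
        for i in range(n):
            a1, a2 = rows[i][2 * j], rows[i][2 * j + 1]
            if a1 == "0":
                continue
            doses[i, j] = (a1 == minor) + (a2 == minor)

    snp_table = pd.DataFrame(
        {
            "chrom": [s[0] for s in snps],
            "pos": [s[2] for s in snps],
            "snp_id": [s[1] for s in snps],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    gm = GenotypeMatrix(sample_ids=sample_ids, snp_table=snp_table, doses=doses)
    phen = make_phenotype_table(sample_ids, statuses, np.nan)
    return gm, phen


def write_ped_map(ped_path, map_path, genotypes: GenotypeMatrix,
                  phenotypes: pd.DataFrame | None = None,
                  pedigree=None) -> None:
    """Write PED/MAP text files; doses decode to allele pairs."""
    st = genotypes.snp_table
    with open(map_path, "w") as fh:
        for _, r in st.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{r['pos']}\n")

    status = {}
    if phenotypes is not None:
        status = dict(zip(phenotypes["sample_id"], phenotypes["status"]))
    sire = dam = None
    if pedigree is not None:
        sire = dict(zip(pedigree.ids, pedigree.sire))
        dam = dict(zip(pedigree.ids, pedigree.dam))
    aa = st["allele_a"].to_numpy()
    ab = st["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            phe = {"case": "2", "control": "1"}.get(status.get(sid, ""), "0")
            s = (sire or {}).get(sid) or "0"
            d = (dam or {}).get(sid) or "0"
            fields = ["FAM", sid, s, d, "0", phe]
            row = genotypes.doses[i]
            for j, dose in enumerate(row):
                if dose == MISSING:
                    fields += ["0", "0"]
                elif dose == 0:
                    fields += [aa[j], aa[j]]
                elif dose == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


def write_haplotypes(path, genotypes: GenotypeMatrix) -> None:
    """Phased sidecar: two rows per sample of 0/1 alleles (counted allele)."""
    if not genotypes.phased:
        raise InputError("genotype matrix is not phased")
    h1, h2 = genotypes.haplotypes
    with open(path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            fh.write(sid + "_1 " + " ".join(map(str, h1[i])) + "\n")
            fh.write(sid + "_2 " + " ".join(map(str, h2[i])) + "\n")


def read_haplotypes(path, genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Attach a phased sidecar back onto a dose matrix."""
    rows = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            rows[parts[0]] = np.array(parts[1:], dtype=np.uint8)
    n, m = genotypes.doses.shape
    h1 = np.empty((n, m), dtype=np.uint8)
    h2 = np.empty((n, m), dtype=np.uint8)
    for i, sid in enumerate(genotypes.sample_ids):
        try:
            h1[i] = rows[sid + "_1"]
            h2[i] = rows[sid + "_2"]
        except KeyError as exc:
            raise InputError(f"{path}: missing haplotypes for sample {sid!r}") from exc
    # reconcile the sidecar's allele orientation with the dose matrix: a
    # reader may have recoded a SNP's counted allele, flipping its doses
    hapsum = h1.astype(np.int64) + h2
    known = genotypes.doses != MISSING
    for j in range(m):
        k = known[:, j]
        if np.array_equal(hapsum[k, j], genotypes.doses[k, j]):
            continue
        if np.array_equal(2 - hapsum[k, j], genotypes.doses[k, j]):
            h1[:, j] = 1 - h1[:, j]
            h2[:, j] = 1 - h2[:, j]
        else:
            raise InputError(f"{path}: haplotypes inconsistent with doses at SNP {j + 1}")
    return GenotypeMatrix(
        sample_ids=list(genotypes.sample_ids),
        snp_table=genotypes.snp_table.copy(),
        doses=genotypes.doses.copy(),
        haplotypes=(h1, h2),
        sample_meta=genotypes.sample_meta,
    )


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return make_phenotype_table(df["sample_id"], df["status"], df["age_years"])


# ---------------------------------------------------------------------------
# Variant table (Table-1 dialect)

VARIANT_COLUMNS = [
    "Location", "Type", "Ref", "Allele", "Gene", "Exon Number", "Consequence", "A.A.Change",
]


def _parse_location(loc: str, line_no: int, path) -> tuple[int, bool]:
    loc = str(loc).strip()
    if "^" in loc:
        a, _, b = loc.partition("^")
        try:
            a_i, b_i = int(a), int(b)
        except ValueError as exc:
            raise InputError(f"{path}:{line_no}: unparseable insertion location {loc!r}") from exc
        if b_i != a_i + 1:
            raise InputError(f"{path}:{line_no}: insertion location {loc!r} not between adjacent positions")
        return a_i, True
    try:
        return int(loc), False
    except ValueError as exc:
        raise InputError(f"{path}:{line_no}: unparseable location {loc!r}") from exc


def read_variant_table(path, chromosome: str = "13") -> list[VariantRecord]:
    """Read a Table-1-shaped TSV into variant records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing variant-table columns {sorted(missing)}")
    records = []
    for k, row in df.iterrows():
        pos, is_ins = _parse_location(row["Location"], k + 2, path)
        records.append(
            VariantRecord(
                chromosome=chromosome,
                position_bp=pos,
                ref_allele=row["Ref"] if row["Ref"] else "-",
                alt_allele=row["Allele"],
                var_type=row["Type"],
                gene=row["Gene"],
                exon=row["Exon Number"],
                consequence=row["Consequence"],
                aa_change=row["A.A.Change"] or "-",
            )
        )
    return records


def write_variant_table(path, records: list[VariantRecord]) -> None:
    rows = []
    for r in records:
        loc = f"{r.position_bp}^{r.position_bp + 1}" if r.var_type == "Ins" else str(r.position_bp)
        rows.append(
            {
                "Location": loc,
                "Type": r.var_type,
                "Ref": r.ref_allele,
                "Allele": r.alt_allele,
                "Gene": r.gene,
                "Exon Number": r.exon,
                "Consequence": r.consequence,
                "A.A.Change": r.aa_change,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_table1() -> list[VariantRecord]:
    """The packaged fixture of the published CFA13 risk-region variant table."""
    with resources.as_file(resources.files("lymphmap") / "data" / "table1.tsv") as p:
        return read_variant_table(p, chromosome="13")


def load_case_subtypes() -> pd.DataFrame:
    """Packaged worked-example fixture: immunophenotype of the subtyped cases."""
    with resources.as_file(resources.files("lymphmap") / "data" / "case_subtypes.tsv") as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Minimal VCF-like TSV

GT_TO_CODE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}


def read_vcf_like(path) -> pd.DataFrame:
    """Minimal VCF-like TSV: CHROM, POS, REF, ALT, then one genotype column
    per sample with 0/0-style codes.  Returns a tidy DataFrame with the
    genotype columns translated to dose codes (missing = -1)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    required = ["CHROM", "POS", "REF", "ALT"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    for c in sample_cols:
        bad = ~df[c].isin(GT_TO_CODE)
        if bad.any():
            ln = int(np.flatnonzero(bad)[0]) + 2
            raise InputError(f"{path}:{ln}: invalid genotype {df[c][bad].iloc[0]!r}")
        df[c] = df[c].map(GT_TO_CODE)
    return df


# ---------------------------------------------------------------------------
# BED-like annotation intervals

def read_intervals(path) -> pd.DataFrame:
    """BED-like annotation: chrom, start, end, feature, gene[, extra].

    Input is half-open 0-based (BED convention); returned intervals are
    1-based inclusive, and the conversion is logged.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "feature", "gene", "extra"],
        dtype={"chrom": str, "feature": str, "gene": str, "extra": str},
    )
    if df[["start", "end"]].isna().any().any():
        raise InputError(f"{path}: missing interval coordinates")
    if (df["end"] <= df["start"]).any():
        raise InputError(f"{path}: empty or inverted interval")
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    logger.info("read %d intervals from %s (converted BED half-open to 1-based inclusive)", len(df), path)
    return df
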