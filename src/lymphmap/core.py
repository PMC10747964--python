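"""Core in-memory containers shared across the pipeline.

The two central objects are :class:`GenotypeMatrix` (samples x SNPs allele-dose
matrix plus SNP map, optionally phased) and the phenotype table, which is a
plain :class:`pandas.DataFrame` with columns ``sample_id``, ``status``
(``case``/``control``) and ``age_years``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dose in the integer dose matrix.
MISSING = -1

SNP_TABLE_COLUMNS = ["chrom", "pos", "snp_id", "allele_a", "allele_b"]


class InputError(ValueError):
    """Malformed user-supplied data (files, pedigrees, tables)."""


class ConfigError(ValueError):
    """Invalid configuration / parameter combination."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dose matrix with a SNP map and optional phase.

    Doses count copies of ``allele_b`` (the counted allele, recorded per
    SNP), so dose 0 is the ``allele_a`` homozygote.  ``haplotypes`` is a
    pair of (n_samples, n_snps) uint8 arrays (0 = allele_a, 1 = allele_b)
    when phase is available; dose must equal the haplotype sum wherever the
    dose is not missing.
    """

    sample_ids: list[str]
    snp_table: pd.DataFrame
    doses: np.ndarray
    haplotypes: tuple[np.ndarray, np.ndarray] | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses)
        if self.doses.shape != (len(self.sample_ids), len(self.snp_table)):
            raise InputError(
                f"dose matrix shape {self.doses.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_table)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicated sample ids")
        for col in ("chrom", "pos"):
            if col not in self.snp_table.columns:
                raise InputError(f"snp_table missing required column {col!r}")
        pos = self.snp_table["pos"].to_numpy()
        chrom = self.snp_table["chrom"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise InputError(f"positions not strictly increasing on chromosome {c}")
        if self.haplotypes is not None:
            h1, h2 = self.haplotypes
            ok = self.doses == MISSING
            if not np.all((h1 + h2 == self.doses) | ok):
                raise InputError("doses inconsistent with haplotype sums")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_table)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted allele (allele_b) per SNP.

        Missing doses are ignored; a SNP missing in every sample gets NaN.
        """
        d = np.where(self.doses == MISSING, np.nan, self.doses).astype(float)
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_samples(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        haps = None
        if self.haplotypes is not None:
            haps = (self.haplotypes[0][idx], self.haplotypes[1][idx])
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_table=self.snp_table.copy(),
            doses=self.doses[idx],
            haplotypes=haps,
            sample_meta=meta,
        )

    def subset_snps(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        haps = None
        if self.haplotypes is not None:
            haps = (self.haplotypes[0][:, idx], self.haplotypes[1][:, idx])
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_table=self.snp_table.iloc[idx].reset_index(drop=True),
            doses=self.doses[:, idx],
            haplotypes=haps,
            sample_meta=self.sample_meta,
        )

    def by_sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise InputError(f"unknown sample id {sample_id!r}") from exc


def make_phenotype_table(sample_ids, status, age_years) -> pd.DataFrame:
    """Assemble the phenotype table with its contract checked."""
    df = pd.DataFrame(
        {"sample_id": list(sample_ids), "status": list(status), "age_years": age_years}
    )
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise InputError(f"invalid status values: {sorted(bad)}")
    return df


def check_phenotypes_cover(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame) -> None:
    missing = set(phenotypes["sample_id"]) - set(genotypes.sample_ids)
    if missing:
        raise InputError(f"phenotype ids absent from genotype matrix: {sorted(missing)[:5]}")
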