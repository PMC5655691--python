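"""Core genotype/haplotype containers shared by all analysis stages.

Genotypes are held animals x SNPs, coded -1 / 0 / +1 for the two homozygotes
and the heterozygote of the counted allele, with :data:`MISSING` marking
missing calls.  Haplotypes are held 2*animals x SNPs as 0/1 allele
indicators, two consecutive rows per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (outside the valid {-1, 0, +1} codes).
MISSING: int = -9

VALID_CODES = frozenset({-1, 0, 1, MISSING})


@dataclass
class GenotypePanel:
    """Biallelic genotypes for one population with their map positions.

    Parameters
    ----------
    population_id
        Label of the population the panel belongs to (e.g. ``"PL"``).
    animal_ids, snp_ids
        Row and column labels; ``snp_ids`` must be unique.
    chrom
        Per-SNP chromosome label.
    pos_bp
        Per-SNP base-pair position, strictly increasing within a chromosome.
    genotypes
        ``(n_animals, n_snp)`` int8 array in {-1, 0, +1, MISSING}.
    alleles
        Optional ``(n_snp, 2)`` array of allele labels ``(counted, other)``
        used to harmonise orientation between panels.
    """

    population_id: str
    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    genotypes: np.ndarray
    alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids are not unique")
        codes = np.unique(self.genotypes)
        if not set(codes.tolist()) <= VALID_CODES:
            raise ValueError(f"invalid genotype codes {set(codes.tolist()) - VALID_CODES}")
        for c in np.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {c}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to the SNP columns in ``index`` (kept order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            genotypes=self.genotypes[:, index],
            alleles=None if self.alleles is None else self.alleles[index],
        )

    def snp_map(self) -> pd.DataFrame:
        """Marker map as a DataFrame (snp_id, chrom, pos_bp)."""
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos_bp": self.pos_bp}
        )

    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the counted (+1) allele per SNP, missing calls excluded.

        SNPs with no observed genotype get NaN.
        """
        obs = self.genotypes != MISSING
        n_obs = obs.sum(axis=0)
        dose = np.where(obs, self.genotypes + 1, 0).sum(axis=0)  # 0/1/2 copies
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, dose / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency (counted-allele frequency folded to <= 0.5)."""
        p = self.counted_allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix, two rows per animal, columns as in the panel."""

    population_id: str
    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    haplotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != 2 * len(self.animal_ids):
            raise ValueError("haplotype panel needs exactly two rows per animal")
        if self.haplotypes.shape[1] != len(self.snp_ids):
            raise ValueError("haplotype column count does not match snp_ids")
        if not set(np.unique(self.haplotypes).tolist()) <= {0, 1}:
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def to_genotypes(self, population_id: str | None = None) -> GenotypePanel:
        """Collapse haplotype pairs to -1/0/+1 genotypes."""
        g = self.haplotypes[0::2] + self.haplotypes[1::2] - 1
        return GenotypePanel(
            population_id=population_id or self.population_id,
            animal_ids=list(self.animal_ids),
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            genotypes=g.astype(np.int8),
        )
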