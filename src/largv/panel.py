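"""Genotype containers and dosage standardization.

A :class:`GenotypePanel` holds hard-call allele dosages (0/1/2, NaN for
missing) for ``n`` individuals at ``m`` SNPs, together with per-SNP metadata
(identifier, chromosome, 1-based position, alleles, minor-allele frequency,
missingness).  All downstream LD and association computations operate on the
standardized matrix produced by :func:`standardize`, in which every column has
mean zero and (population, i.e. denominator-``n``) standard deviation one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every snp_meta frame must carry
META_COLUMNS = ("snp_id", "chrom", "pos", "allele_ref", "allele_alt")


class MonomorphicSNPError(ValueError):
    """Raised when a SNP has zero dosage variance (standardization undefined)."""


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix plus per-SNP metadata.

    Parameters
    ----------
    genotypes
        ``(n, m)`` float array of alternate-allele dosages in {0, 1, 2};
        missing calls are NaN.
    snp_meta
        One row per SNP with at least ``snp_id, chrom, pos, allele_ref,
        allele_alt``.  ``maf`` and ``missing_frac`` are computed from the
        dosages if absent.  SNPs must be sorted by (chrom, pos), strictly
        increasing within chromosome.
    individual_ids
        ``n`` unique sample identifiers.
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (individuals x SNPs) array")
        n, m = self.genotypes.shape
        if len(self.snp_meta) != m:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {m} genotype columns"
            )
        missing = [c for c in META_COLUMNS if c not in self.snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta missing columns: {missing}")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match genotype rows")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        self.snp_meta = self.snp_meta.reset_index(drop=True).copy()
        self._check_sorted()
        if "maf" not in self.snp_meta.columns or "missing_frac" not in self.snp_meta.columns:
            self._compute_freq_stats()

    def _check_sorted(self) -> None:
        meta = self.snp_meta
        for _, grp in meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    "SNPs must be sorted by position, strictly increasing "
                    "within each chromosome"
                )

    def _compute_freq_stats(self) -> None:
        g = self.genotypes
        if g.shape[0] == 0:
            self.snp_meta["maf"] = np.nan
            self.snp_meta["missing_frac"] = np.nan
            return
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(g, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        self.snp_meta["maf"] = maf
        self.snp_meta["missing_frac"] = np.isnan(g).mean(axis=0)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to SNP columns ``index`` (order preserved)."""
        index = np.asarray(index)
        return GenotypePanel(
            self.genotypes[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            list(self.individual_ids),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        panel = GenotypePanel(
            self.genotypes[index, :],
            self.snp_meta.drop(columns=["maf", "missing_frac"], errors="ignore"),
            [self.individual_ids[i] for i in index],
        )
        return panel


@dataclass
class StandardizedGenotypes:
    """Column-standardized dosages: mean 0, population SD 1 per SNP."""

    matrix: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]


def standardize(panel: GenotypePanel) -> StandardizedGenotypes:
    """Mean-impute missing dosages, then z-score every SNP column.

    Missing dosages are replaced by the column mean computed over observed
    calls (hence they become exactly zero after centering).  Standardization
    divides by the population SD (denominator ``n``), consistent with the
    ``X'X / N`` scaling used throughout the LD computations.

    Raises
    ------
    MonomorphicSNPError
        If any column has zero variance after imputation.
    ValueError
        If the panel is empty.
    """
    g = panel.genotypes
    if g.size == 0:
        raise ValueError("empty genotype panel")
    x = g.copy()
    mask = np.isnan(x)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(x, axis=0)
    if np.any(np.isnan(means)):
        bad = panel.snp_meta["snp_id"].iloc[int(np.argmax(np.isnan(means)))]
        raise MonomorphicSNPError(f"SNP {bad} has no observed genotypes")
    if mask.any():
        x[mask] = np.broadcast_to(means, x.shape)[mask]
    means = x.mean(axis=0)
    sds = x.std(axis=0)  # ddof=0: population SD
    zero = sds <= 0
    if np.any(zero):
        bad = panel.snp_meta["snp_id"].iloc[int(np.argmax(zero))]
        raise MonomorphicSNPError(
            f"SNP {bad} is monomorphic (zero dosage variance); remove it with QC"
        )
    return StandardizedGenotypes((x - means) / sds, means, sds)
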