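"""Synthetic genotype panels, additive polygenic traits, and GWAS scans.

Genotypes come from a latent-Gaussian threshold model: each haplotype is a
correlated Gaussian vector (independent, AR(1), or block-equicorrelated
across SNPs) dichotomized at per-SNP allele-frequency quantiles, and the
genotype is the sum of two independent haplotypes.  This gives exact control
over both the LD structure and the allele-frequency spectrum at O(n m) cost.

Phenotypes follow the strictly additive model y = X beta + epsilon with
standardized genotypes: causal effects are Gaussian, scaled so the realized
genetic variance equals the configured h2, with no interaction or haplotype
effects.  ``gwas`` produces the per-SNP univariate summary statistics
(b, se, p, n) that the regional estimator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import GenotypePanel, StandardizedGenotypes, standardize


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``ld_model`` is one of ``independent``, ``ar1`` (latent correlation
    ``rho`` between adjacent SNPs, decaying geometrically), or ``blockwise``
    (equicorrelation ``rho`` inside consecutive blocks of ``block_len`` SNPs,
    independence across blocks).  ``h2`` is the realized proportion of trait
    variance explained by all causal SNPs jointly; ``prop_causal`` the
    fraction of SNPs carrying effects.  Positions are laid out every
    ``bp_spacing`` bp on a single chromosome.
    """

    n_individuals: int
    n_snps: int
    ld_model: str = "independent"
    rho: float = 0.8
    block_len: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.0
    prop_causal: float = 1.0
    seed: int = 0
    chrom: str = "1"
    bp_spacing: int = 1000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.ld_model not in {"independent", "ar1", "blockwise"}:
            raise ValueError(f"unknown ld_model '{self.ld_model}'")
        if not (0.0 < self.prop_causal <= 1.0):
            raise ValueError("prop_causal must lie in (0, 1]")


def _latent_haplotypes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(2n, m) latent Gaussian matrix with the configured SNP-SNP correlation."""
    h, m = 2 * cfg.n_individuals, cfg.n_snps
    z = rng.standard_normal((h, m))
    if cfg.ld_model == "ar1" and cfg.rho > 0:
        scale = np.sqrt(1.0 - cfg.rho**2)
        out = np.empty_like(z)
        out[:, 0] = z[:, 0]
        for j in range(1, m):
            out[:, j] = cfg.rho * out[:, j - 1] + scale * z[:, j]
        return out
    if cfg.ld_model == "blockwise" and cfg.rho > 0:
        shared_per_block = rng.standard_normal((h, int(np.ceil(m / cfg.block_len))))
        shared = np.repeat(shared_per_block, cfg.block_len, axis=1)[:, :m]
        return np.sqrt(cfg.rho) * shared + np.sqrt(1.0 - cfg.rho) * z
    return z


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw a genotype panel under the configured LD model (seed-deterministic).

    Alternate-allele frequencies are uniform on ``maf_range`` (so MAF = alt
    frequency); each haplotype carries the alternate allele when its latent
    value falls below the frequency quantile.  In the vanishingly rare event
    a column comes out monomorphic at small n, one random individual is set
    heterozygous so downstream standardization stays defined.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    latent = _latent_haplotypes(cfg, rng)
    thresholds = sps.norm.ppf(freqs)
    haps = (latent < thresholds).astype(np.int8)
    geno = (haps[:n] + haps[n:]).astype(float)

    mono = np.flatnonzero(geno.std(axis=0) == 0)
    for j in mono:
        geno[rng.integers(0, n), j] = 1.0 if geno[0, j] != 1.0 else 0.0

    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": cfg.chrom,
            "pos": np.arange(1, m + 1) * cfg.bp_spacing,
            "allele_ref": "A",
            "allele_alt": "C",
        }
    )
    return GenotypePanel(geno, meta, [f"ind{i:06d}" for i in range(n)])


@dataclass
class SimulatedTrait:
    """Phenotype realization with its generating effects and ground truth."""

    beta: np.ndarray        # standardized-scale effects (0 for non-causal SNPs)
    y: np.ndarray
    genetic_values: np.ndarray
    causal: np.ndarray      # indices of causal SNPs
    var_y: float = field(default=1.0)

    def realized_variance(self, std: StandardizedGenotypes, region: np.ndarray | None = None) -> float:
        """Realized Var(X_region beta_region) / Var(y) — the simulation truth.

        Uses the in-sample variance of the regional genetic values, removing
        effect-sampling noise from recovery comparisons.
        """
        if region is None:
            g = self.genetic_values
        else:
            g = std.matrix[:, region] @ self.beta[region]
        return float(np.var(g) / self.var_y)


def simulate_effects_and_phenotype(
    panel: GenotypePanel | StandardizedGenotypes,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedTrait:
    """Additive trait y = X beta + eps with realized genetic variance h2.

    Causal SNPs are a uniform draw of ``round(prop_causal * m)`` columns;
    their effects are i.i.d. Gaussian, rescaled so the sample variance of
    ``X beta`` equals h2 exactly; the Gaussian noise is rescaled so the
    sample variance of y is 1.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    std = standardize(panel) if isinstance(panel, GenotypePanel) else panel
    n, m = std.matrix.shape
    eps = rng.standard_normal(n)
    beta = np.zeros(m)
    if cfg.h2 == 0.0:
        causal = np.empty(0, dtype=np.int64)
        y = (eps - eps.mean()) / eps.std()
        g = np.zeros(n)
    else:
        n_causal = max(1, int(round(cfg.prop_causal * m)))
        causal = np.sort(rng.choice(m, size=n_causal, replace=False))
        raw = rng.standard_normal(n_causal)
        g = std.matrix[:, causal] @ raw
        raw *= np.sqrt(cfg.h2) / g.std()
        beta[causal] = raw
        g = std.matrix[:, causal] @ raw
        eps = eps - eps.mean()
        eps *= np.sqrt(1.0 - cfg.h2) / eps.std()
        y = g + eps
    return SimulatedTrait(
        beta=beta, y=y, genetic_values=g, causal=causal, var_y=float(np.var(y))
    )


def gwas(
    panel: GenotypePanel | StandardizedGenotypes,
    y: np.ndarray,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Univariate OLS scan of y on each standardized SNP (with intercept).

    Returns the summary-statistic table the regional estimator consumes:
    ``b`` is the per-standardized-genotype slope (= correlation times SD of
    y), ``se`` its OLS standard error, ``p`` the two-sided t-test p-value.
    """
    if isinstance(panel, GenotypePanel):
        std = standardize(panel)
        meta = panel.snp_meta if meta is None else meta
    else:
        std = panel
    x = std.matrix
    n, m = x.shape
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise ValueError("phenotype length does not match the panel")
    yc = y - y.mean()
    tss = float(yc @ yc)
    b = x.T @ yc / n                       # slope: sum x y / sum x^2, sum x^2 = n
    rss = np.maximum(tss - n * b**2, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, b / se, np.inf * np.sign(b))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    out = pd.DataFrame(
        {
            "snp_id": meta["snp_id"].astype(str).to_numpy() if meta is not None
            else [f"snp{j}" for j in range(m)],
            "b": b,
            "se": se,
            "p": p,
            "n_eff": n,
        }
    )
    if meta is not None:
        out.insert(1, "chrom", meta["chrom"].astype(str).to_numpy())
        out.insert(2, "pos", meta["pos"].to_numpy())
        out.insert(3, "effect_allele", meta["allele_alt"].astype(str).to_numpy())
        out.insert(4, "other_allele", meta["allele_ref"].astype(str).to_numpy())
    return out
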