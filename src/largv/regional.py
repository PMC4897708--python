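"""Regional genetic variance from GWAS summary statistics.

Given per-SNP univariate effects ``b_d`` on the standardized-genotype /
standardized-trait scale and the windowed LD adjustments ``eta_d``, the
variance explained by a SNP set S is estimated as

    rho2(S) = sum_{d in S} b_d^2 / eta_d  -  m_eff(S) / N,

with ``m_eff(S) = sum 1/eta_d`` the effective number of markers and ``N`` the
GWAS sample size.  Dividing each squared effect by eta_d removes the
double-counting induced by LD (a SNP duplicated k times contributes once, not
k times), and subtracting ``m_eff / N`` removes the chi-square noise floor of
the squared effects so the estimator has expectation zero under the null —
mirroring the adjusted R^2 of a per-region multiple regression, to which the
estimator is asymptotically equivalent under strictly additive effects.

The module also provides the variance upper bound, analytic and delete-one-
block jackknife confidence intervals, block ranking with cumulative sums, and
the extended-region enrichment test used for linkage-peak analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .blocks import BlockPartition
from .ld import EtaVector

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class RegionalEstimate:
    """Variance explained by a SNP set, with noise correction and CI."""

    region_id: str
    m_snps: int
    m_eff: float
    raw_sum: float          # sum b_d^2 / eta_d
    noise_term: float       # m_eff / N (or per-SNP sum of 1/(eta_d n_d))
    estimate: float         # raw_sum - noise_term
    variance_bound: float
    ci_low: float
    ci_high: float
    n_used: float


def per_snp_variance(b: float, eta: float) -> float:
    """Variance explained by one SNP: b^2 / eta (eta >= 1 required)."""
    if eta < 1.0 - 1e-9:
        raise ValueError(f"eta = {eta} < 1 violates the LD-adjustment convention")
    return float(b) ** 2 / float(eta)


def variance_bound(m_eff: float, n: float, estimate: float) -> float:
    """Upper bound on Var(rho2 estimate): 2 m_eff / N^2 + 4 max(estimate, 0) / N.

    The first term is the exact null variance of the noise-corrected sum for
    Gaussian effect estimates; the second covers the signal contribution and
    vanishes under the null.
    """
    if n <= 1 or m_eff <= 0:
        raise ValueError("need N > 1 and m_eff > 0")
    return 2.0 * m_eff / n**2 + 4.0 * max(float(estimate), 0.0) / n


def harmonize(
    stats: pd.DataFrame,
    eta_table: pd.DataFrame,
    scale: str = "beta",
    sd_y: float = 1.0,
    drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Align GWAS summary statistics with the LD panel's eta table.

    ``stats`` needs columns ``snp_id, effect_allele, other_allele, b, se,
    n_eff`` (``p`` optional); ``eta_table`` needs ``snp_id, chrom, pos, eta``
    and — for allele checks — ``allele_alt, allele_ref`` (the panel's coded
    and other allele) plus ``maf`` for raw-scale conversion.

    ``scale``:
      * ``"beta"`` — b already per standardized genotype on a unit-variance
        trait; used as-is.
      * ``"raw"``  — per-allele effect; converted by
        ``b * sqrt(2 maf (1 - maf)) / sd_y``.
      * ``"z"``    — reconstruct b on the standardized scale as
        ``(b / se) / sqrt(n_eff)`` (recommended for meta-analysis input with
        unknown trait units).

    Effects whose allele pair is swapped relative to the panel are
    sign-flipped; mismatching pairs are dropped, as are strand-ambiguous
    (A/T, C/G) SNPs when ``drop_ambiguous``.  Returns the intersection,
    sorted by (chrom, pos), with the aligned standardized-scale ``b`` and
    attrs recording drop/flip counts.
    """
    if scale not in {"beta", "raw", "z"}:
        raise ValueError("scale must be one of beta/raw/z")
    merged = eta_table.merge(stats, on="snp_id", how="inner", suffixes=("", "_stats"))
    n_input = len(stats)
    if n_input and len(merged) < 0.5 * n_input:
        logger.warning(
            "only %d of %d summary-stat SNPs matched the LD panel", len(merged), n_input
        )

    flipped = np.zeros(len(merged), dtype=bool)
    keep = np.ones(len(merged), dtype=bool)
    n_ambig = 0
    if {"effect_allele", "other_allele"}.issubset(merged.columns) and {
        "allele_alt",
        "allele_ref",
    }.issubset(merged.columns):
        ea = merged["effect_allele"].astype(str).str.upper()
        oa = merged["other_allele"].astype(str).str.upper()
        alt = merged["allele_alt"].astype(str).str.upper()
        ref = merged["allele_ref"].astype(str).str.upper()
        same = (ea == alt) & (oa == ref)
        swapped = (ea == ref) & (oa == alt)
        flipped = swapped.to_numpy()
        keep = (same | swapped).to_numpy()
        if drop_ambiguous:
            ambig = [
                (a, b) in AMBIGUOUS_PAIRS for a, b in zip(ea, oa, strict=True)
            ]
            ambig = np.asarray(ambig)
            n_ambig = int((ambig & keep).sum())
            keep &= ~ambig

    out = merged.loc[keep].copy()
    b = out["b"].to_numpy(dtype=float)
    if scale == "raw":
        if "maf" not in out.columns:
            raise ValueError("raw-scale conversion needs a maf column in the eta table")
        maf = out["maf"].to_numpy(dtype=float)
        b = b * np.sqrt(2.0 * maf * (1.0 - maf)) / sd_y
    elif scale == "z":
        b = (b / out["se"].to_numpy(dtype=float)) / np.sqrt(
            out["n_eff"].to_numpy(dtype=float)
        )
    b[flipped[keep]] *= -1.0
    out["b"] = b
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    out.attrs["n_dropped"] = int(n_input - len(out))
    out.attrs["n_flipped"] = int(flipped[keep].sum())
    out.attrs["n_ambiguous"] = n_ambig
    logger.info(
        "harmonized %d SNPs (%d flipped, %d ambiguous dropped, %d total dropped)",
        len(out), out.attrs["n_flipped"], n_ambig, out.attrs["n_dropped"],
    )
    return out


def _noise(eta: np.ndarray, n_eff: np.ndarray | None, n: float | None) -> tuple[float, float]:
    """(noise_term, n_used): per-SNP 1/(eta n) sum, or m_eff/N with a scalar N."""
    m_eff = float(np.sum(1.0 / eta))
    if n is not None:
        return m_eff / float(n), float(n)
    if n_eff is None:
        raise ValueError("provide a scalar N or per-SNP n_eff")
    noise = float(np.sum(1.0 / (eta * n_eff)))
    return noise, m_eff / noise  # harmonic-style effective N


def regional_estimate(
    aligned: pd.DataFrame,
    region: np.ndarray | None = None,
    n: float | None = None,
    region_id: str = "region",
    ci: str = "analytic",
) -> RegionalEstimate:
    """LD-adjusted variance explained by the SNPs in ``region``.

    ``aligned`` is a harmonized table with columns ``b`` and ``eta`` (and
    ``n_eff`` when ``n`` is not given); ``region`` indexes its rows (default:
    all).  Returns the noise-corrected estimate with its variance bound and a
    95% analytic CI.
    """
    sub = aligned if region is None else aligned.iloc[np.asarray(region)]
    if len(sub) == 0:
        raise ValueError(f"region '{region_id}' contains no SNPs with summary statistics")
    eta = sub["eta"].to_numpy(dtype=float)
    if np.any(eta < 1.0 - 1e-9):
        raise ValueError("eta values below 1 in harmonized table")
    b = sub["b"].to_numpy(dtype=float)
    n_eff = sub["n_eff"].to_numpy(dtype=float) if "n_eff" in sub.columns else None
    raw = float(np.sum(b**2 / eta))
    m_eff = float(np.sum(1.0 / eta))
    noise, n_used = _noise(eta, n_eff, n)
    if n_used <= 1:
        raise ValueError("sample size must exceed 1")
    est = raw - noise
    vb = variance_bound(m_eff, n_used, est)
    half = 1.959963984540054 * math.sqrt(vb)
    return RegionalEstimate(
        region_id=region_id,
        m_snps=len(sub),
        m_eff=m_eff,
        raw_sum=raw,
        noise_term=noise,
        estimate=est,
        variance_bound=vb,
        ci_low=est - half,
        ci_high=est + half,
        n_used=n_used,
    )


def confidence_interval(
    aligned: pd.DataFrame,
    n: float | None = None,
    method: str = "analytic",
    partition: BlockPartition | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% CI for the genome-wide (all-SNP) estimate.

    ``analytic`` uses the variance upper bound (conservative); ``block_jackknife``
    deletes one block at a time (>= 30 blocks required) and uses the standard
    delete-one jackknife variance, the default for genome-wide sums.
    """
    z = sps.norm.ppf(0.5 + level / 2.0)
    full = regional_estimate(aligned, n=n, region_id="genome")
    if method == "analytic":
        half = z * math.sqrt(full.variance_bound)
        return full.estimate - half, full.estimate + half
    if method != "block_jackknife":
        raise ValueError("method must be 'analytic' or 'block_jackknife'")
    if partition is None or partition.n_blocks < 30:
        raise ValueError(
            "block jackknife needs a partition with >= 30 blocks; use analytic instead"
        )
    labels = _block_labels(aligned, partition)
    groups = [g for g in pd.unique(labels) if g >= 0]
    if len(groups) < 30:
        raise ValueError("fewer than 30 blocks contain summary statistics")
    loo = []
    for g in groups:
        keep = np.flatnonzero(labels != g)
        loo.append(regional_estimate(aligned, region=keep, n=n).estimate)
    loo = np.asarray(loo)
    g = len(loo)
    var = (g - 1) / g * float(np.sum((loo - loo.mean()) ** 2))
    half = z * math.sqrt(var)
    return full.estimate - half, full.estimate + half


def _block_labels(aligned: pd.DataFrame, partition: BlockPartition) -> np.ndarray:
    """Block index per aligned row, matched by snp_id (-1 when unassigned)."""
    mapping = dict(
        zip(partition.snp_ids, partition.block_of(), strict=True)
    )
    return np.asarray([mapping.get(s, -1) for s in aligned["snp_id"].astype(str)])


def _min_p(sub: pd.DataFrame) -> float:
    if "p" in sub.columns and sub["p"].notna().any():
        return float(np.nanmin(sub["p"].to_numpy(dtype=float)))
    if "se" in sub.columns:
        z = np.abs(sub["b"].to_numpy(dtype=float) / sub["se"].to_numpy(dtype=float))
        return float(2.0 * sps.norm.sf(z.max()))
    return float("nan")


def rank_blocks(
    aligned: pd.DataFrame,
    partition: BlockPartition,
    n: float | None = None,
) -> pd.DataFrame:
    """Per-block estimates sorted by decreasing regional variance.

    Adds a cumulative-sum column (for top-k% analyses) and each block's
    minimum univariate association p-value as a diagnostic for whether a
    block's variance stems from one strong hit or many weak ones.
    """
    labels = _block_labels(aligned, partition)
    rows = []
    frame = partition.to_frame()
    for j, b in enumerate(partition.blocks):
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            continue
        est = regional_estimate(aligned, region=idx, n=n, region_id=f"block{j}")
        rows.append(
            {
                "block_id": f"block{j}",
                "chrom": b.chrom,
                "start_bp": frame["start_bp"][j],
                "end_bp": frame["end_bp"][j],
                "m": est.m_snps,
                "m_eff": est.m_eff,
                "raw_sum": est.raw_sum,
                "estimate": est.estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "min_p": _min_p(aligned.iloc[idx]),
            }
        )
    out = pd.DataFrame(rows).sort_values("estimate", ascending=False, kind="stable")
    out["cumulative"] = out["estimate"].cumsum()
    return out.reset_index(drop=True)


def enrichment_test(
    aligned: pd.DataFrame,
    center: tuple[str, int],
    half_width_bp: int,
    n: float | None = None,
    n_resample: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Excess regional variance of a physical window vs. the genome-wide average.

    The target is the estimate over SNPs within ``center +/- half_width_bp``;
    the reference distribution comes from ``n_resample`` contiguous windows of
    the SAME SNP count placed uniformly at random along the genome (never
    spanning a chromosome break), which equalizes the null variance.  The
    two-sided p-value is the empirical tail probability (r + 1) /
    (n_resample + 1) of a reference deviation at least as large as the
    observed excess; the CI shifts the reference quantiles to the excess scale.
    """
    if n_resample < 100:
        logger.warning("n_resample = %d < 100 gives a coarse p-value grid", n_resample)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom, pos = str(center[0]), int(center[1])
    chroms = aligned["chrom"].astype(str).to_numpy()
    positions = aligned["pos"].to_numpy()
    in_win = (chroms == chrom) & (np.abs(positions - pos) <= half_width_bp)
    m_t = int(in_win.sum())
    if m_t == 0:
        raise ValueError(f"no summary-stat SNPs within {half_width_bp} bp of {chrom}:{pos}")

    eta = aligned["eta"].to_numpy(dtype=float)
    b = aligned["b"].to_numpy(dtype=float)
    per_snp = b**2 / eta
    if n is not None:
        per_noise = (1.0 / eta) / float(n)
    else:
        per_noise = 1.0 / (eta * aligned["n_eff"].to_numpy(dtype=float))
    contrib = per_snp - per_noise
    target = float(contrib[in_win].sum())

    # valid start indices: window of m_t consecutive rows within one chromosome
    m_all = len(aligned)
    if m_t > m_all:
        raise ValueError("window larger than the genome")
    starts_ok = np.flatnonzero(chroms[: m_all - m_t + 1] == chroms[m_t - 1 :])
    if starts_ok.size == 0:
        raise ValueError("no chromosome long enough for an equal-SNP-count window")
    csum = np.concatenate([[0.0], np.cumsum(contrib)])
    draws = starts_ok[rng.integers(0, starts_ok.size, size=n_resample)]
    ref = csum[draws + m_t] - csum[draws]

    ref_mean = float(ref.mean())
    excess = target - ref_mean
    centered = ref - ref_mean
    r = int(np.sum(np.abs(centered) >= abs(excess) - 1e-15))
    p = (r + 1) / (n_resample + 1)
    q_lo, q_hi = np.quantile(centered, [0.025, 0.975])
    return {
        "region": f"{chrom}:{pos}+/-{half_width_bp}",
        "m_snps": m_t,
        "target": target,
        "reference_mean": ref_mean,
        "excess": excess,
        "ci_low": excess - float(q_hi),
        "ci_high": excess - float(q_lo),
        "p_two_sided": float(p),
        "n_resample": int(n_resample),
    }
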