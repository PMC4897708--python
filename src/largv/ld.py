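"""Windowed linkage disequilibrium (r^2), per-SNP LD adjustments and m_eff.

LD between SNPs d and k is the squared sample Pearson correlation of their
standardized dosage columns (composite LD from unphased genotypes).  Only
pairs within ``window`` SNPs of each other on the same chromosome arm are
computed; more distant pairs are assumed to be in linkage equilibrium
(r^2 = 0).  The per-SNP adjustment

    eta_d = sum_{k: |k - d| <= window, same arm} r^2_{d,k}

includes the self term r^2_{d,d} = 1, so eta_d >= 1 with equality in perfect
linkage equilibrium, and the effective number of markers of a SNP set S,

    m_eff(S) = sum_{d in S} 1 / eta_d,

equals |S| exactly when there is no LD and is strictly smaller otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import StandardizedGenotypes

_CHUNK = 512  # columns per BLAS block when filling the band


@dataclass
class WindowedLD:
    """Banded store of pairwise r^2 within a fixed SNP-count window.

    ``band[d, off]`` holds r^2 between SNPs ``d`` and ``d + off`` for
    ``0 <= off <= window``; entries past the end of the panel or spanning an
    arm boundary are zero.  ``band[:, 0]`` is identically 1.
    """

    window: int
    band: np.ndarray            # (m, window + 1)
    arm_ids: np.ndarray         # integer arm label per SNP
    n_samples: int | None = None  # individuals behind the r^2 estimates

    @property
    def n_snps(self) -> int:
        return self.band.shape[0]

    def r2(self, d: int, k: int) -> float:
        """r^2 between SNPs d and k (0 outside the window / across arms)."""
        if d > k:
            d, k = k, d
        off = k - d
        if off > self.window or self.arm_ids[d] != self.arm_ids[k]:
            return 0.0
        return float(self.band[d, off])

    def dense(self) -> np.ndarray:
        """Full m x m r^2 matrix with out-of-band entries set to 0 (tests)."""
        m = self.n_snps
        out = np.zeros((m, m))
        for off in range(self.window + 1):
            if off >= m:
                break
            vals = self.band[: m - off, off]
            idx = np.arange(m - off)
            out[idx, idx + off] = vals
            out[idx + off, idx] = vals
        return out


def assign_arms(meta: pd.DataFrame, arm_boundaries: dict[str, int] | None = None) -> np.ndarray:
    """Integer arm label per SNP.

    Each chromosome is one arm unless ``arm_boundaries`` maps its name to a
    centromere position (bp); SNPs at ``pos <= boundary`` form the p arm.
    """
    arm_ids = np.empty(len(meta), dtype=np.int64)
    next_id = 0
    for chrom, grp in meta.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if arm_boundaries and str(chrom) in arm_boundaries:
            cut = arm_boundaries[str(chrom)]
            p_arm = grp["pos"].to_numpy() <= cut
            arm_ids[idx[p_arm]] = next_id
            arm_ids[idx[~p_arm]] = next_id + 1
            next_id += 2
        else:
            arm_ids[idx] = next_id
            next_id += 1
    return arm_ids


def windowed_r2(
    std: StandardizedGenotypes,
    meta: pd.DataFrame,
    window: int = 100,
    arm_boundaries: dict[str, int] | None = None,
) -> WindowedLD:
    """Banded pairwise r^2 of standardized dosage columns.

    Because columns are standardized with population SD, the correlation of
    columns d, k is simply ``x_d . x_k / n``; the band is filled in column
    chunks so only ``m * (window + 1)`` values are ever materialized.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = std.matrix
    n, m = x.shape
    if len(meta) != m:
        raise ValueError(f"snp_meta has {len(meta)} rows for {m} columns")
    arm_ids = assign_arms(meta, arm_boundaries)

    band = np.zeros((m, window + 1))
    band[:, 0] = 1.0
    for s in range(0, m, _CHUNK):
        e = min(m, s + _CHUNK)
        hi = min(m, e + window)
        corr = x[:, s:e].T @ x[:, s:hi] / n
        for off in range(1, window + 1):
            diag = np.diagonal(corr, offset=off)
            if diag.size == 0:
                continue
            stop = min(e, s + diag.size)
            band[s:stop, off] = diag[: stop - s] ** 2
    # clip tiny numerical overshoot, zero out cross-arm pairs
    np.clip(band, 0.0, 1.0, out=band)
    for off in range(1, window + 1):
        if off >= m:
            break
        cross = arm_ids[: m - off] != arm_ids[off:]
        band[: m - off, off][cross] = 0.0
    return WindowedLD(window=window, band=band, arm_ids=arm_ids, n_samples=n)


@dataclass
class EtaVector:
    """Per-SNP LD adjustments eta_d, aligned with the source panel."""

    eta: np.ndarray
    window: int
    snp_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.eta)


def eta_adjustments(
    ld: WindowedLD,
    snp_ids: list[str] | None = None,
    sampling_correction: bool = True,
) -> EtaVector:
    """eta_d = sum of r^2 between SNP d and every same-arm SNP within the window.

    The self term contributes 1, neighbors contribute their banded r^2 (zero
    across arm boundaries), and the window truncates naturally at arm ends.

    Sample r^2 overestimates population LD by (1 - r^2)/(n - 2) per pair,
    which inflates eta by ~2 window/n and deflates the variance estimate by
    the same relative amount.  When the LD store carries its sample size and
    ``sampling_correction`` is on (the default), each stored pair enters as
    the approximately unbiased r^2 - (1 - r^2)/(n - 2), and eta is floored
    at its mathematical minimum of 1.
    """
    m = ld.n_snps
    n = ld.n_samples
    correct = sampling_correction and n is not None and n > 3
    eta = np.ones(m)
    for off in range(1, ld.window + 1):
        if off >= m:
            break
        v = ld.band[: m - off, off]
        if correct:
            present = ld.arm_ids[: m - off] == ld.arm_ids[off:]
            v = np.where(present, v - (1.0 - v) / (n - 2), 0.0)
        eta[: m - off] += v
        eta[off:] += v
    np.maximum(eta, 1.0, out=eta)
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(m)]
    return EtaVector(eta=eta, window=ld.window, snp_ids=list(snp_ids))


def effective_marker_count(eta: EtaVector | np.ndarray, subset=None) -> float:
    """m_eff = sum over the subset of 1/eta_d; equals the SNP count iff no LD."""
    values = eta.eta if isinstance(eta, EtaVector) else np.asarray(eta, dtype=float)
    if subset is not None:
        values = values[np.asarray(subset)]
    if values.size == 0:
        raise ValueError("empty SNP subset")
    if np.any(values < 1.0 - 1e-9):
        raise ValueError("eta values below 1 violate the self-term convention")
    return float(np.sum(1.0 / values))
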