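"""Readers and writers for genotype, summary-statistic and result files.

Supports PLINK bed/bim/fam triplets (SNP-major 2-bit codes, read and
written bit-exactly), VCF via cyvcf2 (GT converted to alternate-allele
dosage), whitespace/tab GWAS summary tables with configurable column
mapping, and the TSV artifacts the pipeline exchanges (eta adjustments,
block definitions, per-block estimates).  Also houses the QC filters
(missingness, MAF, Hardy-Weinberg exact test) applied before LD estimation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import Block, BlockPartition
from .ld import EtaVector
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit PLINK codes -> dosage of the A1 (coded) allele; 0b01 is missing
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def _plink_path(prefix, ext):
    return Path(str(prefix) + "." + ext)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a bed/bim/fam triplet into a GenotypePanel.

    The A1 (first bim allele, conventionally the minor allele) is the coded
    allele: dosages count A1 copies.  Positions are 1-based from the bim.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        _plink_path(prefix, "bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        _plink_path(prefix, "fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    if fam["iid"].duplicated().any():
        raise ValueError("duplicate IID in fam file")
    n, m = len(fam), len(bim)
    raw = _plink_path(prefix, "bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"{prefix}.bed is not a SNP-major PLINK bed file (bad magic bytes)"
        )
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed is truncated: expected {bytes_per_snp * m} data bytes, "
            f"found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    # expand each byte into four 2-bit codes, little-endian within the byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    geno = _BED_DECODE[codes[:, :n]].T  # (n, m)

    meta = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "allele_ref": bim["a2"],
            "allele_alt": bim["a1"],
        }
    )
    return GenotypePanel(geno, meta, fam["iid"].tolist())


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as bed/bim/fam (A1 = coded/alt allele)."""
    prefix = Path(prefix)
    meta = panel.snp_meta
    n, m = panel.n_individuals, panel.n_snps
    bim = pd.DataFrame(
        {
            "chrom": meta["chrom"], "snp_id": meta["snp_id"], "cm": 0,
            "pos": meta["pos"], "a1": meta["allele_alt"], "a2": meta["allele_ref"],
        }
    )
    bim.to_csv(_plink_path(prefix, "bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": panel.individual_ids, "iid": panel.individual_ids,
         "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(_plink_path(prefix, "fam"), sep="\t", header=False, index=False)

    g = panel.genotypes.T  # (m, n)
    codes = np.full(g.shape, 0b01, dtype=np.uint8)  # missing
    codes[g == 2] = 0b00
    codes[g == 1] = 0b10
    codes[g == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    packed = np.zeros((m, codes.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(_plink_path(prefix, "bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, half_call_missing: bool = True) -> GenotypePanel:
    """Read a VCF into a GenotypePanel (alt-allele dosage from GT).

    Multi-allelic records are skipped (with a logged count); half calls are
    treated as missing when ``half_call_missing``, otherwise as the observed
    allele's dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta_rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [allele1, allele2, phased]
        dos = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a = [x for x in gt[:2] if x >= 0]
            if len(a) == 2:
                dos[i] = float(sum(a))
            elif len(a) == 1 and not half_call_missing:
                dos[i] = float(a[0])
            else:
                dos[i] = np.nan
        rows.append(dos)
        meta_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "allele_ref": var.REF,
                "allele_alt": var.ALT[0],
            }
        )
    if n_multi:
        logger.info("skipped %d multi-allelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypePanel(np.column_stack(rows), pd.DataFrame(meta_rows), samples)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCFv4.2 text file."""
    meta = panel.snp_meta
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids) + "\n"
        )
        for j in range(panel.n_snps):
            row = meta.iloc[j]
            calls = [
                gt_map.get(g, "./.") for g in panel.genotypes[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                f"{row['allele_ref']}\t{row['allele_alt']}\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypePanel:
    """Dispatch on format: 'plink_bed' (prefix) or 'vcf' (file path)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz"} else "plink_bed"
    if fmt == "plink_bed":
        return read_plink(path.with_suffix("") if path.suffix == ".bed" else path)
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format '{fmt}'")


# ---------------------------------------------------------------------------
# QC

@dataclass
class QCConfig:
    max_missing_snp: float = 0.02
    max_missing_ind: float = 0.02
    min_maf: float = 0.02
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_missing_snp", "max_missing_ind", "min_maf", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value (Wigginton et al. recurrence).

    Sums the probabilities of all heterozygote counts (given the allele
    counts) no more likely than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over possible het counts with the same parity as `rare`
    het_max = min(rare, 2 * n - rare)
    probs = {}
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(het-2)/P(het) = het (het-1) / ((r+2)(c+2)) with
    # r, c the two homozygote counts at het
    h = mid
    while h >= 2:
        r = (rare - h) // 2
        c = n - h - r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (r + 1) * (c + 1))
        h -= 2
    h = mid
    while h <= het_max - 2:
        r = (rare - h) // 2
        c = n - h - r
        probs[h + 2] = probs[h] * 4.0 * r * c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def apply_qc(panel: GenotypePanel, qc: QCConfig | None = None) -> tuple[GenotypePanel, dict]:
    """Filter individuals and SNPs in a fixed order; return the panel and report.

    Order: individual missingness -> SNP missingness -> MAF -> HWE exact
    test.  Raises if no SNP survives.
    """
    qc = qc or QCConfig()
    report = {}
    g = panel.genotypes

    ind_miss = np.isnan(g).mean(axis=1)
    keep_ind = ind_miss <= qc.max_missing_ind
    report["individuals_missingness"] = int((~keep_ind).sum())
    if not keep_ind.all():
        panel = panel.subset_individuals(np.flatnonzero(keep_ind))
        g = panel.genotypes

    snp_miss = np.isnan(g).mean(axis=0)
    keep = snp_miss <= qc.max_missing_snp
    report["snps_missingness"] = int((~keep).sum())

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = keep & (maf < qc.min_maf)
    report["snps_maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    fail_hwe = np.zeros_like(keep)
    for j in np.flatnonzero(keep):
        col = g[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = int((col == 0).sum())
        if hwe_exact_p(n_het, n_hom_ref, n_hom_alt) < qc.hwe_p_min:
            fail_hwe[j] = True
    report["snps_hwe"] = int(fail_hwe.sum())
    keep &= ~fail_hwe

    if not keep.any():
        raise ValueError("QC removed every SNP")
    out = panel.subset_snps(np.flatnonzero(keep))
    report["snps_kept"] = out.n_snps
    report["individuals_kept"] = out.n_individuals
    logger.info("QC report: %s", report)
    return out, report


# ---------------------------------------------------------------------------
# Tabular artifacts

DEFAULT_SUMSTAT_COLUMNS = {
    "SNP": "snp_id", "CHR": "chrom", "POS": "pos", "A1": "effect_allele",
    "A2": "other_allele", "BETA": "b", "SE": "se", "N": "n_eff", "P": "p",
}


def read_sumstats(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited GWAS summary table (optionally gzipped).

    ``column_map`` maps file headers to canonical names; defaults cover
    SNP/CHR/POS/A1/A2/BETA/SE/N/P.  Requires at least snp_id, b, se.
    """
    column_map = {**DEFAULT_SUMSTAT_COLUMNS, **(column_map or {})}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=r"\s+")
    df = df.rename(columns=column_map)
    required = {"snp_id", "b", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics lack required columns: {sorted(missing)}")
    df["snp_id"] = df["snp_id"].astype(str)
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df


def write_eta(eta: EtaVector, meta: pd.DataFrame, path: str | Path) -> None:
    """Eta TSV: snp_id, chrom, pos, eta, window plus the panel's alleles/maf
    (needed downstream for harmonization)."""
    out = pd.DataFrame(
        {
            "snp_id": meta["snp_id"].astype(str),
            "chrom": meta["chrom"].astype(str),
            "pos": meta["pos"].astype(int),
            "eta": eta.eta,
            "window": eta.window,
            "allele_alt": meta["allele_alt"].astype(str),
            "allele_ref": meta["allele_ref"].astype(str),
            "maf": meta["maf"] if "maf" in meta.columns else np.nan,
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_eta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    if not {"snp_id", "eta"}.issubset(df.columns):
        raise ValueError("eta table must have snp_id and eta columns")
    return df


def write_blocks(partition: BlockPartition, path_bed: str | Path, path_map: str | Path | None = None) -> None:
    partition.to_frame().to_csv(path_bed, sep="\t", index=False, float_format="%.12g")
    if path_map is not None:
        partition.snp_map().to_csv(path_map, sep="\t", index=False)


def read_blocks(path_bed: str | Path, snp_ids: list[str] | None = None,
                min_size: int = 0, max_size: int = 0) -> BlockPartition:
    df = pd.read_csv(path_bed, sep="\t", dtype={"chrom": str})
    blocks = [
        Block(
            chrom=row["chrom"], arm=int(row.get("arm", 0)),
            start=int(row["start_index"]), end=int(row["end_index"]),
            start_bp=int(row["start_bp"]) + 1, end_bp=int(row["end_bp"]),
            boundary_max_r2=float(row["boundary_max_r2"]),
        )
        for _, row in df.iterrows()
    ]
    return BlockPartition(
        blocks=blocks, min_size=min_size, max_size=max_size,
        snp_ids=list(snp_ids) if snp_ids else [],
    )
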