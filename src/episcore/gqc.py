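"""Genotype I/O and quality control.

Implements the standard SNP-level filters (call rate, minor-allele frequency,
Hardy-Weinberg exact test), sample-level filters (call rate, heterozygosity
outliers), annotation-based SNP pre-selection, composite LD, and genotype PCA,
plus a self-contained PLINK1 binary reader/writer.

PLINK1 ``.bed`` layout (SNP-major): three magic bytes ``6c 1b 01`` followed by
``ceil(n_samples / 4)`` bytes per SNP; each sample occupies two bits with
``00`` = homozygous A1, ``10`` = heterozygous, ``11`` = homozygous A2 and
``01`` = missing.  A1 is the counted (minor) allele, so codes map to dosages
2 / 1 / 0 / missing respectively.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MISSING, FormatError, GenotypeMatrix

__all__ = [
    "read_plink",
    "write_plink",
    "read_sample_table",
    "hwe_exact_test",
    "filter_snps",
    "filter_samples",
    "select_by_annotation",
    "ld_r2",
    "genotype_pca",
]

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit PLINK code -> minor-allele count (-1 = missing)
_CODE_TO_CALL = np.array([2, -1, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


# ---------------------------------------------------------------------------
# PLINK1 binary I/O
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK1 .bed/.bim/.fam fileset into a :class:`GenotypeMatrix`.

    ``bed_path`` may be the fileset prefix, in which case the companion paths
    are derived.  SNP order follows the ``.bim`` file; calls count the A1
    allele with missing preserved.
    """
    bed = Path(bed_path)
    if bed.suffix != ".bed" and bim_path is None:
        bed = bed.with_suffix(".bed")
    if bim_path is None:
        bim_path = bed.with_suffix(".bim")
    if fam_path is None:
        fam_path = bed.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "sample_id": str},
    )
    n, m = len(fam), len(bim)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed}: invalid PLINK .bed magic at byte offset 0: "
            f"expected {_BED_MAGIC.hex()} got {raw[:3].hex()}"
        )
    stride = (n + 3) // 4
    expected = 3 + stride * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed}: truncated or oversized .bed: expected {expected} bytes "
            f"for {n} samples x {m} SNPs, found {len(raw)} (at byte offset "
            f"{min(len(raw), expected)})"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, stride)
    # expand 2-bit codes: sample k of a SNP sits at bits (2k, 2k+1) of byte k//4
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, stride * 4)[:, :n]
    calls = _CODE_TO_CALL[codes].T.copy()  # samples x SNPs

    snp_meta = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    sample_meta = fam[["sample_id", "fid", "sex", "pheno"]].copy()
    return GenotypeMatrix(calls, snp_meta, sample_meta)


def write_plink(geno: GenotypeMatrix, prefix, status: np.ndarray | None = None) -> None:
    """Write a :class:`GenotypeMatrix` as PLINK1 .bed/.bim/.fam.

    ``status`` (0/1 per sample), when given, is stored in the .fam phenotype
    column using PLINK's 1=control / 2=case convention; otherwise -9.
    """
    prefix = str(prefix)
    n, m = geno.calls.shape
    stride = (n + 3) // 4
    body = np.zeros((m, stride), dtype=np.uint8)
    # lookup over calls {-1,0,1,2} shifted by +1
    lut4 = np.empty(4, dtype=np.uint8)
    for call, c in _CALL_TO_CODE.items():
        lut4[call + 1] = c
    shifts = np.arange(4, dtype=np.uint8) * 2
    pad = (-n) % 4
    for j in range(m):
        code = lut4[geno.calls[:, j].astype(np.int16) + 1]
        if pad:
            code = np.concatenate([code, np.zeros(pad, dtype=np.uint8)])
        body[j] = (code.reshape(-1, 4) << shifts).sum(axis=1).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": geno.snp_meta["chrom"],
            "snp": geno.snp_meta["snp"],
            "cm": 0,
            "pos": geno.snp_meta["pos"],
            "a1": geno.snp_meta["a1"],
            "a2": geno.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    pheno = np.full(n, -9, dtype=np.int64)
    if status is not None:
        pheno = np.asarray(status, dtype=np.int64) + 1
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": pheno,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_sample_table(path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV with a header and a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: phenotype table lacks a sample_id column")
    if "status" in df.columns:
        bad = ~df["status"].isin((0, 1))
        if bad.any():
            raise FormatError(f"{path}: status must be 0/1; {int(bad.sum())} bad rows")
    return df


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (of matching parity) whose probability does not
    exceed that of the observed configuration.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("HWE test undefined for all-zero counts")
    n_a = 2 * n_aa + n_Aa  # minor allele count (either orientation works)
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts), multinomial conditional on margins
    n_hom_rare = (rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_common + 1)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def hwe_pvalues(geno: GenotypeMatrix, sample_mask: np.ndarray | None = None) -> np.ndarray:
    """HWE exact p per SNP, computed over the selected samples."""
    calls = geno.calls if sample_mask is None else geno.calls[sample_mask]
    out = np.empty(geno.n_snps)
    for j in range(geno.n_snps):
        col = calls[:, j]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        out[j] = np.nan if (n0 + n1 + n2) == 0 else hwe_exact_test(n0, n1, n2)
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_snps(
    geno: GenotypeMatrix,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
    status: np.ndarray | None = None,
    hwe_on_controls: bool = True,
) -> tuple[GenotypeMatrix, dict]:
    """Apply SNP-level QC: call rate, MAF and HWE-exact filters.

    A SNP is removed when its missing rate exceeds ``max_missing``, its MAF is
    below ``min_maf``, or its HWE exact p is below ``hwe_alpha``.  HWE is by
    default computed on controls only (requires ``status``), the conventional
    choice that avoids discarding genuinely disease-associated SNPs; pass
    ``hwe_on_controls=False`` to use all samples.

    Returns the filtered matrix and a report of per-criterion removal counts.
    """
    for name, t in (("max_missing", max_missing), ("min_maf", min_maf),
                    ("hwe_alpha", hwe_alpha)):
        if not (0.0 < t < 1.0):
            raise ValueError(f"{name} must be in (0, 1)")
    miss = geno.snp_missing_rate()
    maf = geno.maf()
    mask = None
    if hwe_on_controls:
        if status is None:
            raise ValueError("hwe_on_controls=True requires status")
        mask = np.asarray(status) == 0
    hwe_p = hwe_pvalues(geno, mask)

    fail_miss = miss > max_missing
    fail_maf = maf < min_maf
    fail_hwe = np.nan_to_num(hwe_p, nan=1.0) < hwe_alpha
    keep = ~(fail_miss | fail_maf | fail_hwe)
    report = {
        "n_input": geno.n_snps,
        "n_removed_missing": int(fail_miss.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_hwe": int(fail_hwe.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("all SNPs removed by QC filters")
    return geno.take_snps(np.flatnonzero(keep)), report


def filter_samples(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    max_missing: float = 0.2,
    het_sd: float = 3.0,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Sample-level QC: call-rate and heterozygosity-outlier filters.

    Removes samples with genotype missing rate above ``max_missing`` or with
    heterozygosity rate more than ``het_sd`` standard deviations from the
    cohort mean.  A zero (or undefined) SD makes the heterozygosity rule
    vacuous: all samples pass it.
    """
    if het_sd <= 0:
        raise ValueError("het_sd must be positive")
    miss = geno.sample_missing_rate()
    het = geno.heterozygosity_rate()
    mu = np.nanmean(het)
    sd = np.nanstd(het)
    fail_miss = miss > max_missing
    if sd > 0:
        fail_het = np.abs(het - mu) > het_sd * sd
        fail_het = np.nan_to_num(fail_het, nan=False).astype(bool)
    else:
        fail_het = np.zeros(geno.n_samples, dtype=bool)
    keep = ~(fail_miss | fail_het)
    report = {
        "n_input": geno.n_samples,
        "n_removed_missing": int(fail_miss.sum()),
        "n_removed_het": int(fail_het.sum()),
        "n_kept": int(keep.sum()),
    }
    idx = np.flatnonzero(keep)
    return geno.take_samples(idx), pheno.iloc[idx].reset_index(drop=True), report


def select_by_annotation(
    geno: GenotypeMatrix,
    annot: pd.DataFrame,
    min_score: float = 15.0,
    max_gene_distance: float = 5000.0,
) -> GenotypeMatrix:
    """Keep SNPs annotated near a gene and predicted deleterious.

    ``annot`` has columns ``snp, nearest_gene, gene_distance,
    deleteriousness_score`` (CADD-like).  SNPs absent from the annotation are
    dropped; retained SNPs satisfy ``score >= min_score`` and
    ``gene_distance <= max_gene_distance``.
    """
    if len(annot) == 0:
        warnings.warn("empty annotation table: no SNPs retained")
        return geno.take_snps(np.array([], dtype=np.intp))
    ok = annot[
        (annot["deleteriousness_score"] >= min_score)
        & (annot["gene_distance"] <= max_gene_distance)
    ]["snp"]
    keep = np.flatnonzero(np.isin(geno.snp_ids, np.asarray(ok, dtype=object)))
    if keep.size == 0:
        warnings.warn("annotation filter removed every SNP")
    return geno.take_snps(keep)


# ---------------------------------------------------------------------------
# LD and PCA
# ---------------------------------------------------------------------------

def ld_r2(geno: GenotypeMatrix, snp_a, snp_b) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages.

    Computed over samples observed at both SNPs.  Returns ``NaN`` (with a
    warning) when fewer than two complete pairs exist or either SNP has zero
    variance among them.
    """
    ia, ib = geno.snp_index(snp_a), geno.snp_index(snp_b)
    a = geno.calls[:, ia]
    b = geno.calls[:, ib]
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok].astype(np.float64)
    b = b[ok].astype(np.float64)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn(f"LD undefined for pair ({snp_a}, {snp_b})")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def genotype_pca(geno: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component coordinates of the genotype matrix.

    Missing calls are mean-imputed per SNP, columns are standardized
    (monomorphic columns contribute zeros), and coordinates are taken from
    the SVD.  Axis signs are fixed by making the largest-magnitude SNP
    loading of each component positive.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return np.zeros((geno.n_samples, 0))
    d = geno.dosage()
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu, d)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    z = (d - d.mean(axis=0)) / sd
    rank = min(z.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank bound {rank}")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    flip = np.sign(vt[np.arange(k), np.abs(vt[:k]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return u[:, :k] * s[:k] * flip
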