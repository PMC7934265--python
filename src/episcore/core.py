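"""Core in-memory containers shared across the pipeline.

Genotypes are stored as minor-allele counts in an ``int8`` matrix of shape
``(n_samples, n_snps)`` with ``-1`` marking a missing call.  SNP and sample
metadata travel alongside as :class:`pandas.DataFrame` objects, mirroring the
layout of PLINK1 filesets (``.bim`` / ``.fam``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: required columns of ``GenotypeMatrix.snp_meta``
SNP_META_COLUMNS = ("snp", "chrom", "pos", "a1", "a2")


class ConfigError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


class FormatError(ValueError):
    """Raised when an on-disk genotype file is malformed."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele count matrix with metadata.

    Parameters
    ----------
    calls
        ``int8`` array, shape ``(n_samples, n_snps)``; values in ``{0, 1, 2}``
        count the A1 (minor) allele, ``-1`` is missing.
    snp_meta
        One row per SNP with columns ``snp, chrom, pos, a1, a2``.  ``a1`` is
        the counted allele.
    sample_meta
        One row per sample with at least a ``sample_id`` column.
    """

    calls: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ConfigError("calls must be a 2-D samples x SNPs array")
        n, m = self.calls.shape
        if len(self.snp_meta) != m:
            raise ConfigError(f"snp_meta has {len(self.snp_meta)} rows for {m} SNPs")
        if len(self.sample_meta) != n:
            raise ConfigError(
                f"sample_meta has {len(self.sample_meta)} rows for {n} samples"
            )
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ConfigError(f"snp_meta lacks columns {sorted(missing_cols)}")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ConfigError("calls must be in {0,1,2} or -1 for missing")
        if (np.asarray(self.snp_meta["pos"]) <= 0).any():
            raise ConfigError("SNP positions must be positive")
        same = self.snp_meta["a1"].astype(str) == self.snp_meta["a2"].astype(str)
        if same.any():
            raise ConfigError("allele pairs must be distinct")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    # -- basic geometry -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.sample_meta["sample_id"].to_numpy()

    def snp_index(self, snp) -> int:
        """Column index of a SNP given by id (str) or position (int)."""
        if isinstance(snp, (int, np.integer)):
            return int(snp)
        hits = np.flatnonzero(self.snp_ids == snp)
        if hits.size == 0:
            raise KeyError(f"SNP {snp!r} not in matrix")
        return int(hits[0])

    # -- derived per-SNP / per-sample statistics ----------------------------
    def dosage(self) -> np.ndarray:
        """Calls as float with ``NaN`` for missing."""
        d = self.calls.astype(np.float64)
        d[self.calls == MISSING] = np.nan
        return d

    def snp_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele (A1) frequency per SNP over non-missing calls.

        Returns the frequency of the counted allele folded onto [0, 0.5].
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / (2.0 * n_obs)
        return np.minimum(freq, 1.0 - freq)

    def heterozygosity_rate(self) -> np.ndarray:
        """Per-sample fraction of heterozygous calls among non-missing calls."""
        obs = (self.calls != MISSING).sum(axis=1)
        het = (self.calls == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs > 0, het / obs, np.nan)

    # -- subsetting ---------------------------------------------------------
    def take_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.sample_meta.copy(),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index],
            self.snp_meta.copy(),
            self.sample_meta.iloc[index].reset_index(drop=True),
        )


@dataclass
class JointTable:
    """3 x 3 x 2 genotype-by-status count table for one SNP pair.

    ``counts[g1, g2, s]`` is the number of samples with ``g1`` minor alleles
    at ``snp_a``, ``g2`` at ``snp_b`` and case/control status ``s``
    (``s = 1`` for cases).  Only samples with both genotypes observed are
    counted.
    """

    counts: np.ndarray
    snp_a: str
    snp_b: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3, 2):
            raise ValueError("JointTable counts must have shape (3, 3, 2)")
        if (self.counts < 0).any():
            raise ValueError("JointTable counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def control(self) -> np.ndarray:
        return self.counts[:, :, 0]

    def case(self) -> np.ndarray:
        return self.counts[:, :, 1]


@dataclass
class EffectTable:
    """Per-cell effect sizes and MDR labels for one interaction.

    ``log_or[g1, g2]`` is the natural-log odds ratio of the cell against the
    rest of the table; ``high_risk[g1, g2]`` marks cells whose case:control
    ratio exceeds the training data's overall case:control ratio
    ``threshold`` (the MDR labeling rule).
    """

    snp_a: str
    snp_b: str
    log_or: np.ndarray
    high_risk: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.log_or = np.asarray(self.log_or, dtype=np.float64)
        self.high_risk = np.asarray(self.high_risk, dtype=bool)
        if self.log_or.shape != (3, 3) or self.high_risk.shape != (3, 3):
            raise ValueError("EffectTable matrices must be 3 x 3")


class GroupSummary(NamedTuple):
    """Summary statistics (n, mean, SD) of one group, as printed in cohort tables."""

    n: int
    mean: float
    sd: float
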