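"""Synthetic case-control genotype/phenotype data with planted epistasis.

The generator emulates the ingredients of a case-control epistasis study:
biallelic SNPs in Hardy-Weinberg equilibrium with configurable minor-allele
frequencies, covariate-linked baseline risk (sex, age, genotyping batch),
additive per-allele main effects, and pairwise interactions defined by 3x3
penetrance tables.  Disease liability is additive on the logit scale: each
planted pair contributes ``logit(p[g1, g2]) - baseline_logit`` so that a flat
penetrance table contributes nothing and downstream logistic models are
correctly specified.

Age at onset is drawn from an exponential model whose rate increases with the
disease liability, so higher-risk individuals convert earlier; unaffected
individuals are censored at their last-record age.  Real cohorts give no
generative model for onset, so this is a deliberately simple stand-in that
preserves the qualitative risk-onset ordering used in survival evaluation.

Randomness is governed by a single integer seed.  Draw order is fixed and
documented: genotypes come from stream ``(seed, 0)`` (MAFs first, then the
genotype matrix column-block, then the missingness mask) and phenotypes from
stream ``(seed, 1)`` (sex, age, batch, case status, onset), so regenerating
phenotypes never perturbs genotypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ConfigError, GenotypeMatrix

__all__ = [
    "PenetranceTable",
    "CovariateSpec",
    "SimulationConfig",
    "product_penetrance",
    "checkerboard_penetrance",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "write_dataset",
]


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class PenetranceTable:
    """3x3 matrix of disease probabilities indexed by (g1, g2) minor-allele counts."""

    p: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=np.float64)
        if arr.shape != (3, 3):
            raise ConfigError("penetrance table must be 3 x 3")
        if (arr < 0).any() or (arr > 1).any():
            raise ConfigError("penetrance entries must lie in [0, 1]")
        object.__setattr__(self, "p", arr)

    def logit_contribution(self, baseline_logit: float) -> np.ndarray:
        """Per-cell additive contribution on the logit scale."""
        return _logit(self.p) - baseline_logit


def product_penetrance(baseline_p: float, log_or: float) -> PenetranceTable:
    """Penetrance with a multiplicative allele-product interaction.

    ``logit p[g1, g2] = logit(baseline_p) + log_or * g1 * g2`` — the pattern a
    logistic product-term test is designed for, and a genuine departure from
    the homogeneous-association log-linear model.
    """
    g = np.arange(3)
    return PenetranceTable(_expit(_logit(baseline_p) + log_or * np.outer(g, g)))


def checkerboard_penetrance(baseline_p: float, log_or: float) -> PenetranceTable:
    """Pure-epistasis pattern: risk alternates with the parity of g1 + g2.

    At MAF 0.5 the marginal (single-SNP) effects vanish exactly, leaving only
    the interaction — useful for testing that interaction signal survives the
    removal of main-effect SNPs.
    """
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    sign = np.where((g1 + g2) % 2 == 0, 1.0, -1.0)
    return PenetranceTable(_expit(_logit(baseline_p) + log_or * sign))


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions and logit-scale effects of the simulated covariates.

    Defaults emulate an elderly case-control cohort: mean age 75 with SD 8,
    a slight excess of women, and two genotyping batches with no batch effect
    on risk unless one is configured.
    """

    female_prob: float = 0.55
    age_mean: float = 75.0
    age_sd: float = 8.0
    n_batches: int = 2
    sex_effect: float = 0.0
    age_effect: float = 0.0  # per year, centred at age_mean
    batch_effects: tuple[float, ...] | None = None

    def resolved_batch_effects(self) -> np.ndarray:
        if self.batch_effects is None:
            return np.zeros(self.n_batches)
        eff = np.asarray(self.batch_effects, dtype=np.float64)
        if eff.size != self.n_batches:
            raise ConfigError("batch_effects length must equal n_batches")
        return eff


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 2000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted_pairs: tuple[tuple[int, int, PenetranceTable], ...] = ()
    main_effects: tuple[tuple[int, float], ...] = ()
    baseline_logit: float = 0.0
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    missing_rate: float = 0.0
    seed: int = 0
    mafs: tuple[float, ...] | None = None  # explicit per-SNP MAFs (overrides maf_range)
    # onset model: hazard rate = exp(onset_beta * liability) / onset_scale,
    # onset = onset_min + Exponential(1/rate), censored at censor_age
    onset_min: float = 60.0
    onset_scale: float = 15.0
    onset_beta: float = 0.4
    censor_age: float = 95.0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1:
            raise ConfigError("n_samples and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        seen: set[int] = set()
        for i, j, table in self.planted_pairs:
            if i == j:
                raise ConfigError("planted pair indices must be distinct")
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                raise ConfigError("planted pair index out of range")
            if not isinstance(table, PenetranceTable):
                raise ConfigError("planted pairs need a PenetranceTable")
            seen.update((i, j))
        for i, _ in self.main_effects:
            if not (0 <= i < self.n_snps):
                raise ConfigError("main-effect index out of range")
        if self.mafs is not None and len(self.mafs) != self.n_snps:
            raise ConfigError("explicit mafs must have length n_snps")

    def effect_snp_indices(self) -> np.ndarray:
        """Indices of SNPs carrying planted effects (exempt from missingness)."""
        idx: set[int] = set()
        for i, j, _ in self.planted_pairs:
            idx.update((i, j))
        idx.update(i for i, _ in self.main_effects)
        return np.array(sorted(idx), dtype=np.intp)

    def to_yaml(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = dataclasses.asdict(self)
        d["covariates"] = dataclasses.asdict(self.covariates)
        d["mafs"] = None if self.mafs is None else [float(m) for m in self.mafs]
        d["planted_pairs"] = [
            {"snp_a": int(i), "snp_b": int(j), "penetrance": np.asarray(t.p).tolist()}
            for i, j, t in self.planted_pairs
        ]
        d["main_effects"] = [[int(i), float(b)] for i, b in self.main_effects]
        return yaml.safe_dump(clean(d), sort_keys=False)


def _geno_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 0])


def _pheno_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 1])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a samples x SNPs minor-allele-count matrix under HWE.

    Each SNP is independent across samples and loci with genotype frequencies
    ``(1-q)^2, 2q(1-q), q^2`` for its MAF ``q`` (a Binomial(2, q) draw).
    Missingness is applied uniformly at ``missing_rate``, except at SNPs that
    carry planted effects, which stay fully observed so that effect recovery
    is not confounded with missing-data handling.
    """
    rng = _geno_rng(config)
    if config.mafs is not None:
        mafs = np.asarray(config.mafs, dtype=np.float64)
        if (mafs <= 0).any() or (mafs > 0.5).any():
            raise ConfigError("explicit mafs must lie in (0, 0.5]")
    else:
        lo, hi = config.maf_range
        mafs = rng.uniform(lo, hi, size=config.n_snps)
    calls = rng.binomial(2, mafs, size=(config.n_samples, config.n_snps)).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(size=calls.shape) < config.missing_rate
        mask[:, config.effect_snp_indices()] = False
        calls[mask] = -1
    width = len(str(config.n_snps))
    snp_meta = pd.DataFrame(
        {
            "snp": [f"snp{i:0{width}d}" for i in range(config.n_snps)],
            "chrom": "1",
            "pos": np.arange(1, config.n_snps + 1) * 10_000,
            "a1": "A",
            "a2": "G",
            "maf": mafs,
        }
    )
    sample_meta = pd.DataFrame(
        {"sample_id": [f"S{i:06d}" for i in range(config.n_samples)]}
    )
    return GenotypeMatrix(calls, snp_meta, sample_meta)


def liability(geno: GenotypeMatrix, config: SimulationConfig,
              sex: np.ndarray, age: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Per-sample logit-scale disease liability given genotypes and covariates."""
    cov = config.covariates
    eta = np.full(geno.n_samples, config.baseline_logit, dtype=np.float64)
    eta += cov.sex_effect * sex
    eta += cov.age_effect * (age - cov.age_mean)
    eta += cov.resolved_batch_effects()[batch]
    for i, beta in config.main_effects:
        g = geno.calls[:, i].astype(np.float64)
        if (g < 0).any():
            raise ConfigError("main-effect SNPs must be fully observed")
        eta += beta * g
    for i, j, table in config.planted_pairs:
        g1 = geno.calls[:, i]
        g2 = geno.calls[:, j]
        if (g1 < 0).any() or (g2 < 0).any():
            raise ConfigError("planted-pair SNPs must be fully observed")
        eta += table.logit_contribution(config.baseline_logit)[g1, g2]
    return eta


def simulate_phenotype(geno: GenotypeMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Draw covariates, case-control status and onset/censoring ages.

    Returns a sample table with columns ``sample_id, status, sex, age, batch,
    onset_age, censored, liability``.  ``sex`` is 1 for female; ``censored``
    is 1 when no onset was observed (all controls, plus cases whose latent
    onset fell beyond ``censor_age``); ``liability`` is the true logit-scale
    risk, kept for diagnostics.
    """
    rng = _pheno_rng(config)
    cov = config.covariates
    n = geno.n_samples
    sex = (rng.random(n) < cov.female_prob).astype(np.int8)
    age = rng.normal(cov.age_mean, cov.age_sd, size=n)
    age = np.clip(age, config.onset_min + 1.0, None)
    batch = rng.integers(0, cov.n_batches, size=n).astype(np.int16)
    eta = liability(geno, config, sex, age, batch)
    status = (rng.random(n) < _expit(eta)).astype(np.int8)

    # Latent onset: exponential waiting time after onset_min with rate
    # increasing in liability; higher-risk individuals convert earlier.
    centred = eta - np.mean(eta)
    wait = rng.exponential(config.onset_scale * np.exp(-config.onset_beta * centred))
    latent_onset = config.onset_min + wait
    onset_age = np.where(status == 1, np.minimum(latent_onset, config.censor_age), age)
    censored = np.where(
        (status == 1) & (latent_onset <= config.censor_age), 0, 1
    ).astype(np.int8)

    return pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "status": status,
            "sex": sex,
            "age": np.round(age, 2),
            "batch": batch,
            "onset_age": np.round(onset_age, 2),
            "censored": censored,
            "liability": eta,
        }
    )


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    geno = simulate_genotypes(config)
    pheno = simulate_phenotype(geno, config)
    return geno, pheno


def write_dataset(geno: GenotypeMatrix, pheno: pd.DataFrame, prefix,
                  config: SimulationConfig | None = None) -> None:
    """Write PLINK1 .bed/.bim/.fam plus the phenotype TSV (and config YAML)."""
    from .gqc import write_plink

    prefix = str(prefix)
    write_plink(geno, prefix, status=pheno["status"].to_numpy())
    pheno.drop(columns=["liability"], errors="ignore").to_csv(
        prefix + ".pheno.tsv", sep="\t", index=False
    )
    if config is not None:
        with open(prefix + ".config.yaml", "w") as fh:
            fh.write(config.to_yaml())
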