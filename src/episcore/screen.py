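"""Main-effect scan and exhaustive pairwise epistasis screening.

Three interaction tests operate on the 3 x 3 x 2 genotype-by-status table of
a SNP pair (cases and controls tallied separately over pairwise-complete
samples):

* ``logistic`` — logistic regression with additive dosage coding and a single
  product term; 1-df likelihood-ratio test.  Because the model depends on the
  data only through the joint genotype table, the fit is performed on the nine
  aggregated genotype patterns, which is exactly the per-sample MLE.
* ``boost`` — the BOOST statistic: twice the gap between the saturated
  log-likelihood of the table and the maximized log-likelihood of the
  homogeneous-association log-linear model (all two-way margins, no three-way
  term), fitted by iterative proportional fitting; chi-square with 4 df.
* ``joint`` — the joint-effects statistic: the case-versus-control difference
  of the four log odds ratios of the 2x2 subtables anchored at the (0, 0)
  genotype cell, standardized by its delta-method covariance; chi-square with
  4 df.

Pairs with any of the 18 contingency cells below ``min_cell`` (default 3) are
excluded before testing; excluded pairs do not enter the FDR denominator.
Contingency tables are built with bit-level operations (three packed bit
planes per SNP, popcounts of conjunctions) and, for the all-pairs scan, with
an equivalent BLAS formulation; both must agree exactly with a naive tally.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, JointTable
from .gqc import ld_r2

__all__ = [
    "build_joint_table",
    "build_joint_tables_batch",
    "cell_filter",
    "logistic_interaction_test",
    "boost_test",
    "joint_effects_test",
    "main_effect_scan",
    "screen_all_pairs",
    "fdr_adjust",
    "prune_pairs_by_ld",
    "posthoc_genotypic_test",
    "ScreenResult",
]

METHODS = ("logistic", "boost", "joint")


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

def _bit_planes(calls_col: np.ndarray) -> list[np.ndarray]:
    """Three packed bit vectors marking genotypes 0, 1, 2 of one SNP."""
    return [np.packbits(calls_col == g) for g in (0, 1, 2)]


def build_joint_table(geno: GenotypeMatrix, pheno: pd.DataFrame,
                      snp_a, snp_b) -> JointTable:
    """3x3x2 genotype-by-status counts for one SNP pair via bitwise popcounts.

    Each SNP is encoded as three bit planes (one per genotype); status as two
    more.  Cell counts are popcounts of the AND of three planes.  Samples
    missing at either SNP appear in no plane conjunction and are excluded
    from all 18 cells.
    """
    ia, ib = geno.snp_index(snp_a), geno.snp_index(snp_b)
    status = np.asarray(pheno["status"], dtype=np.int8)
    a_planes = _bit_planes(geno.calls[:, ia])
    b_planes = _bit_planes(geno.calls[:, ib])
    s_planes = [np.packbits(status == s) for s in (0, 1)]
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    for g1, g2, s in itertools.product(range(3), range(3), range(2)):
        conj = a_planes[g1] & b_planes[g2] & s_planes[s]
        counts[g1, g2, s] = int(np.bitwise_count(conj).sum())
    return JointTable(counts, str(geno.snp_ids[ia]), str(geno.snp_ids[ib]))


def build_joint_tables_batch(geno: GenotypeMatrix, status: np.ndarray,
                             pairs: np.ndarray) -> np.ndarray:
    """Stacked 3x3x2 tables for an array of SNP-index pairs, shape (P, 3, 3, 2).

    Uses dense one-hot genotype planes and matrix products per status stratum;
    exactly equivalent to the bitwise tally (verified by tests), but lets BLAS
    do the popcount-equivalent reductions for the all-pairs scan.
    """
    status = np.asarray(status, dtype=np.int8)
    n, m = geno.calls.shape
    onehot = np.empty((3, n, m), dtype=np.float32)
    for g in range(3):
        onehot[g] = geno.calls == g
    pairs = np.asarray(pairs)
    out = np.empty((len(pairs), 3, 3, 2), dtype=np.int64)
    for s in (0, 1):
        sel = status == s
        planes = onehot[:, sel, :]
        # cross[g1, g2] over all SNP pairs: (m, m) per genotype combination
        for g1 in range(3):
            for g2 in range(3):
                cross = planes[g1].T @ planes[g2]
                out[:, g1, g2, s] = np.rint(
                    cross[pairs[:, 0], pairs[:, 1]]
                ).astype(np.int64)
    return out


def cell_filter(table: JointTable | np.ndarray, min_cell: int = 3) -> bool:
    """True (pair excluded) iff any of the 18 cells holds fewer than min_cell."""
    if min_cell < 0:
        raise ValueError("min_cell must be non-negative")
    counts = table.counts if isinstance(table, JointTable) else np.asarray(table)
    return bool((counts < min_cell).any())


def cell_filter_batch(tables: np.ndarray, min_cell: int = 3) -> np.ndarray:
    return (tables < min_cell).any(axis=(1, 2, 3))


# ---------------------------------------------------------------------------
# Logistic interaction test (aggregated Newton fit)
# ---------------------------------------------------------------------------

_G1, _G2 = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
_X_FULL = np.column_stack(
    [np.ones(9), _G1.ravel(), _G2.ravel(), (_G1 * _G2).ravel()]
)
_X_NULL = _X_FULL[:, :3]


def _fit_logistic_grouped(y: np.ndarray, ntot: np.ndarray, X: np.ndarray,
                          max_iter: int = 60, tol: float = 1e-10):
    """Batched Newton-Raphson for grouped-binomial logistic regression.

    y, ntot: (B, 9) case counts and totals per genotype pattern; X: (9, p).
    Returns (loglik, converged), log-likelihood without binomial constants.
    """
    B, K = y.shape
    p_dim = X.shape[1]
    beta = np.zeros((B, p_dim))
    tot_case = y.sum(axis=1)
    tot = ntot.sum(axis=1)
    frac = np.clip(tot_case / np.maximum(tot, 1), 1e-9, 1 - 1e-9)
    beta[:, 0] = np.log(frac / (1 - frac))
    converged = np.zeros(B, dtype=bool)
    active = ~converged
    for _ in range(max_iter):
        eta = beta @ X.T
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = ntot * mu * (1.0 - mu)
        grad = (y - ntot * mu) @ X
        hess = np.einsum("bk,kp,kq->bpq", w, X, X)
        hess += 1e-10 * np.eye(p_dim)
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(h, g, rcond=None)[0]
                             for h, g in zip(hess, grad)])
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step * active[:, None]
        done = np.abs(step).max(axis=1) < tol
        converged |= done & active
        active = ~converged
        if not active.any():
            break
    eta = beta @ X.T
    with np.errstate(over="ignore"):
        # y*eta - n*log(1+exp(eta)), stable for large |eta|
        ll = (y * eta - ntot * np.logaddexp(0.0, eta)).sum(axis=1)
    return ll, converged


def logistic_interaction_tables(tables: np.ndarray):
    """Vectorized 1-df LRT for the dosage-product term over stacked tables."""
    tables = np.asarray(tables, dtype=np.float64)
    if tables.ndim == 3:
        tables = tables[None]
    y = tables[:, :, :, 1].reshape(len(tables), 9)
    ntot = tables.sum(axis=3).reshape(len(tables), 9)
    ll1, conv1 = _fit_logistic_grouped(y, ntot, _X_FULL)
    ll0, conv0 = _fit_logistic_grouped(y, ntot, _X_NULL)
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    ok = conv1 & conv0
    return stat, p, ok


def logistic_interaction_test(geno: GenotypeMatrix, pheno: pd.DataFrame,
                              snp_a, snp_b) -> tuple[float, float]:
    """logit(status) ~ 1 + g_a + g_b + g_a*g_b; LRT p for the product term.

    Additive dosage coding, no covariates at the screening stage.  Returns
    (statistic, p); p is NaN when the fit did not converge.
    """
    table = build_joint_table(geno, pheno, snp_a, snp_b)
    stat, p, ok = logistic_interaction_tables(table.counts)
    if not ok[0]:
        warnings.warn(f"logistic fit did not converge for ({snp_a}, {snp_b})")
        return float(stat[0]), float("nan")
    return float(stat[0]), float(p[0])


# ---------------------------------------------------------------------------
# BOOST test
# ---------------------------------------------------------------------------

def ipf_homogeneous(tables: np.ndarray, tol: float = 1e-8,
                    max_sweeps: int = 10_000) -> np.ndarray:
    """Fit the homogeneous-association log-linear model to stacked 3x3x2 tables.

    Iterative proportional fitting matches the three two-way margins
    (g1,g2), (g1,status), (g2,status); convergence is declared when no cell
    changes by more than ``tol`` within a sweep.
    """
    T = np.asarray(tables, dtype=np.float64)
    single = T.ndim == 3
    if single:
        T = T[None]
    fit = np.full_like(T, T.mean(axis=(1, 2, 3), keepdims=True))
    active = np.ones(len(T), dtype=bool)
    for sweep in range(max_sweeps):
        prev = fit[active].copy()
        sub = fit[active]
        tgt = T[active]
        for axes in ((3,), (2,), (1,)):
            m_fit = sub.sum(axis=axes, keepdims=True)
            m_tgt = tgt.sum(axis=axes, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(m_fit > 0, m_tgt / np.maximum(m_fit, 1e-300), 0.0)
            sub = sub * ratio
        fit[active] = sub
        delta = np.abs(sub - prev).max(axis=(1, 2, 3))
        still = delta > tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
        if not active.any():
            break
    else:
        raise RuntimeError(
            f"IPF did not converge in {max_sweeps} sweeps; offending tables: "
            f"{T[active][:3]!r}"
        )
    return fit[0] if single else fit


def boost_tables(tables: np.ndarray):
    """Vectorized BOOST statistic (4-df chi-square) over stacked tables."""
    T = np.asarray(tables, dtype=np.float64)
    if T.ndim == 3:
        T = T[None]
    fit = ipf_homogeneous(T)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(T > 0, T * np.log(T / np.maximum(fit, 1e-300)), 0.0)
    stat = np.maximum(2.0 * term.sum(axis=(1, 2, 3)), 0.0)
    p = stats.chi2.sf(stat, df=4)
    return stat, p


def boost_test(table: JointTable | np.ndarray) -> tuple[float, float]:
    """BOOST interaction test: 2*(l_sat - l_hom) against chi-square(4)."""
    counts = table.counts if isinstance(table, JointTable) else np.asarray(table)
    stat, p = boost_tables(counts)
    return float(stat[0]), float(p[0])


# ---------------------------------------------------------------------------
# Joint-effects test
# ---------------------------------------------------------------------------

_JE_CELLS = [(1, 1), (1, 2), (2, 1), (2, 2)]


def joint_effects_tables(tables: np.ndarray):
    """Vectorized joint-effects statistic over stacked tables.

    For each status stratum, the four log odds ratios
    ``lam_ij = ln n_ij - ln n_i0 - ln n_0j + ln n_00`` (i, j in {1, 2}) are
    compared between cases and controls via the quadratic form
    ``d' V^-1 d`` with the delta-method covariance ``V = V_case + V_ctrl``.

    Variance terms use ``1 / (n + 0.5)`` rather than ``1 / n``: with the
    small cell counts this screen admits (>= 3), ``E[1/n] > 1/E[n]`` inflates
    the naive variance and makes the test conservative; the half-count
    correction restores nominal type-I error (checked by calibration tests).
    """
    T = np.asarray(tables, dtype=np.float64)
    if T.ndim == 3:
        T = T[None]
    B = len(T)
    lam = np.empty((B, 2, 4))
    V = np.zeros((B, 2, 4, 4))
    ok = (T > 0).all(axis=(1, 2, 3))
    safe = np.maximum(T, 1e-300)
    logn = np.log(safe)
    inv = 1.0 / (safe + 0.5)
    for s in (0, 1):
        for a, (i, j) in enumerate(_JE_CELLS):
            lam[:, s, a] = (
                logn[:, i, j, s] - logn[:, i, 0, s]
                - logn[:, 0, j, s] + logn[:, 0, 0, s]
            )
            for b, (k, l) in enumerate(_JE_CELLS):
                cov = inv[:, 0, 0, s].copy()
                if i == k:
                    cov += inv[:, i, 0, s]
                if j == l:
                    cov += inv[:, 0, j, s]
                if i == k and j == l:
                    cov += inv[:, i, j, s]
                V[:, s, a, b] = cov
    d = lam[:, 1] - lam[:, 0]
    Vsum = V[:, 0] + V[:, 1]
    stat = np.full(B, np.nan)
    for b in range(B):
        if not ok[b]:
            continue
        try:
            stat[b] = float(d[b] @ np.linalg.solve(Vsum[b], d[b]))
        except np.linalg.LinAlgError:
            ok[b] = False
    p = np.where(ok, stats.chi2.sf(np.nan_to_num(stat), df=4), np.nan)
    return stat, p, ok


def joint_effects_test(table: JointTable | np.ndarray) -> tuple[float, float]:
    """Joint-effects interaction test; returns (statistic, p).

    Requires all 18 cells positive (guaranteed after the cell filter at
    min_cell >= 1); p is NaN when the covariance is singular or a cell is
    empty.
    """
    counts = table.counts if isinstance(table, JointTable) else np.asarray(table)
    stat, p, ok = joint_effects_tables(counts)
    if not ok[0]:
        warnings.warn("joint-effects statistic undefined (empty cell or singular V)")
    return float(stat[0]), float(p[0])


# ---------------------------------------------------------------------------
# Main-effect scan
# ---------------------------------------------------------------------------

def _covariate_design(pheno: pd.DataFrame, covariates, n_pcs: int) -> np.ndarray:
    cols = [np.ones(len(pheno))]
    for c in covariates:
        if c == "batch":
            dummies = pd.get_dummies(pheno["batch"], drop_first=True)
            for col in dummies.columns:
                cols.append(dummies[col].to_numpy(dtype=np.float64))
        elif c in pheno.columns:
            cols.append(pheno[c].to_numpy(dtype=np.float64))
    for k in range(1, n_pcs + 1):
        name = f"pc{k}"
        if name in pheno.columns:
            cols.append(pheno[name].to_numpy(dtype=np.float64))
    return np.column_stack(cols)


def main_effect_scan(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "age", "batch"),
    n_pcs: int = 3,
) -> pd.DataFrame:
    """Per-SNP covariate-adjusted logistic association scan.

    Fits ``logit(status) ~ dosage + covariates`` per SNP (additive coding,
    complete cases) and reports the 1-df Wald p for the dosage term, plus the
    genomic-inflation factor lambda = median(chi2) / 0.4549 as a DataFrame
    attribute ``lambda_gc``.  Monomorphic or non-converging SNPs get NaN p
    with a reason flag.
    """
    import statsmodels.api as sm

    status = pheno["status"].to_numpy(dtype=np.float64)
    if min((status == 0).sum(), (status == 1).sum()) < 2:
        raise ValueError("need at least two samples of each status")
    C = _covariate_design(pheno, covariates, n_pcs)
    rows = []
    for j in range(geno.n_snps):
        g = geno.calls[:, j].astype(np.float64)
        ok = g >= 0
        gj = g[ok]
        flag = ""
        beta = se = p = np.nan
        if np.unique(gj).size < 2:
            flag = "monomorphic"
        else:
            X = np.column_stack([C[ok], gj])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(status[ok], X).fit(disp=0, maxiter=100)
                beta = res.params[-1]
                se = res.bse[-1]
                p = res.pvalues[-1]
                if not res.mle_retvals.get("converged", True) or not np.isfinite(se):
                    flag = "unreliable"
                    p = np.nan
            except Exception:
                flag = "fit_failed"
        rows.append((geno.snp_ids[j], beta, se, p, flag))
    out = pd.DataFrame(rows, columns=["snp", "beta", "se", "p", "flag"])
    chi2 = stats.chi2.isf(out["p"].dropna(), df=1)
    out.attrs["lambda_gc"] = float(np.median(chi2) / 0.45494) if len(chi2) else np.nan
    return out


# ---------------------------------------------------------------------------
# All-pairs screening, FDR, LD pruning
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Tidy screening output: one row per reported (pair, method) test."""

    results: pd.DataFrame
    n_pairs: int
    n_pairs_cell_filtered: int
    n_valid_tests: int


def screen_all_pairs(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    min_cell: int = 3,
    p_report: float = 1.0,
) -> ScreenResult:
    """Exhaustive pairwise interaction screen over all C(m, 2) SNP pairs.

    Applies the 18-cell count filter first, runs each requested test on the
    surviving pairs, and reports every test with ``p <= p_report``.  The
    number of valid tests (pairs passing the filter times methods) is
    recorded for FDR correction.  Pair identity is canonical: ``snp_a`` is
    the lexicographically smaller SNP id, so results do not depend on column
    order of the input matrix.
    """
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    m = geno.n_snps
    ia, ib = np.triu_indices(m, k=1)
    pairs = np.column_stack([ia, ib])
    status = pheno["status"].to_numpy()
    tables = build_joint_tables_batch(geno, status, pairs)
    filtered = cell_filter_batch(tables, min_cell)
    valid = ~filtered
    vt = tables[valid].astype(np.float64)
    vpairs = pairs[valid]

    frames = []
    for method in methods:
        if len(vt) == 0:
            continue
        if method == "logistic":
            stat, p, ok = logistic_interaction_tables(vt)
            p = np.where(ok, p, np.nan)
        elif method == "boost":
            stat, p = boost_tables(vt)
        else:
            stat, p, ok = joint_effects_tables(vt)
        keep = np.nan_to_num(p, nan=np.inf) <= p_report
        ids = geno.snp_ids
        a_ids = ids[vpairs[keep, 0]]
        b_ids = ids[vpairs[keep, 1]]
        swap = a_ids > b_ids
        frames.append(pd.DataFrame({
            "snp_a": np.where(swap, b_ids, a_ids),
            "snp_b": np.where(swap, a_ids, b_ids),
            "method": method,
            "stat": stat[keep],
            "p": p[keep],
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["snp_a", "snp_b", "method"], kind="stable")
        df = df.reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["snp_a", "snp_b", "method", "stat", "p"])
    return ScreenResult(
        results=df,
        n_pairs=len(pairs),
        n_pairs_cell_filtered=int(filtered.sum()),
        n_valid_tests=int(valid.sum()) * len(methods),
    )


def fdr_adjust(results: pd.DataFrame, n_valid_tests: int | None = None) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment pooled across methods.

    ``n_valid_tests`` sets the BH denominator (the number of tests actually
    performed after cell filtering, which may exceed the number of reported
    rows when a reporting threshold was applied); defaults to the number of
    rows with a defined p.
    """
    df = results.copy()
    p = df["p"].to_numpy(dtype=np.float64)
    defined = np.isfinite(p)
    m = int(n_valid_tests) if n_valid_tests is not None else int(defined.sum())
    adj = np.full_like(p, np.nan)
    if defined.sum():
        ps = p[defined]
        order = np.argsort(ps, kind="stable")
        ranked = ps[order] * m / (np.arange(len(ps)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty_like(ranked)
        vals[order] = np.minimum(ranked, 1.0)
        adj[defined] = vals
    df["fdr"] = adj
    return df


def prune_pairs_by_ld(results: pd.DataFrame, geno: GenotypeMatrix,
                      max_r2: float = 0.2) -> pd.DataFrame:
    """Drop interactions whose two SNPs are in LD (r^2 > max_r2).

    Pairs with undefined r^2 are retained with a warning; an ``ld_r2`` column
    is added.
    """
    df = results.copy()
    uniq = df[["snp_a", "snp_b"]].drop_duplicates()
    r2 = {}
    for a, b in uniq.itertuples(index=False):
        r2[(a, b)] = ld_r2(geno, a, b)
    vals = np.array([r2[(a, b)] for a, b in zip(df["snp_a"], df["snp_b"])])
    df["ld_r2"] = vals
    undef = np.isnan(vals)
    if undef.any():
        warnings.warn(f"{int(undef.sum())} pairs with undefined LD retained")
    keep = undef | (vals <= max_r2)
    return df[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Post-hoc covariate-adjusted genotypic test
# ---------------------------------------------------------------------------

def posthoc_genotypic_test(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_a,
    snp_b,
    covariates: tuple[str, ...] = ("sex", "age", "batch"),
    n_pcs: int = 3,
) -> tuple[float, float, int]:
    """Covariate-adjusted genotypic interaction test for one pair.

    Likelihood-ratio test of a logistic model with indicator terms for the
    joint-genotype cells (reference (0, 0)) plus covariates against the
    covariates-only model.  Nominal df is 8; cells unobserved in the data
    drop their indicator and reduce the df accordingly.  Returns
    (statistic, p, df).
    """
    import statsmodels.api as sm

    ia, ib = geno.snp_index(snp_a), geno.snp_index(snp_b)
    g1 = geno.calls[:, ia]
    g2 = geno.calls[:, ib]
    ok = (g1 != MISSING) & (g2 != MISSING)
    status = pheno["status"].to_numpy(dtype=np.float64)[ok]
    C = _covariate_design(pheno, covariates, n_pcs)[ok]
    cell = (g1[ok] * 3 + g2[ok]).astype(np.intp)
    present = np.unique(cell)
    indicators = [
        (cell == c).astype(np.float64) for c in present if c != 0
    ]
    df_test = len(indicators)
    if df_test == 0:
        return float("nan"), float("nan"), 0
    X0 = C
    X1 = np.column_stack([C] + indicators)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll0 = sm.Logit(status, X0).fit(disp=0, maxiter=200).llf
        ll1 = sm.Logit(status, X1).fit(disp=0, maxiter=200).llf
    statv = max(2.0 * (ll1 - ll0), 0.0)
    return float(statv), float(stats.chi2.sf(statv, df=df_test)), df_test
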