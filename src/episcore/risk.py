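"""Risk scores built from single SNPs and SNP-SNP interactions.

The polygenic risk score (PRS) of individual *j* averages effect-allele
dosages weighted by per-SNP log odds ratios over the SNPs observed for that
individual:

    PRS_j = sum_i G_ij * E_i / N_j

The epistasis risk score (ERS) does the analogous thing over interactions:
each interaction contributes the log odds ratio of the 3x3 joint-genotype
cell the individual falls into (effect tables estimated on training data,
never the scored set), averaged over the N_j interactions with both
genotypes observed:

    ERS_j = sum_i ( sum_k C_ijk * E_ik ) / N_j

The combined risk score mixes the two linearly, CRS_j = w*PRS_j +
(1-w)*ERS_j, with w chosen by grid search to maximize AUC on a selection
dataset distinct from the evaluation dataset.

The multifactor-dimensionality-reduction (MDR) layer labels each joint
genotype cell high-risk when its case:control ratio exceeds the training
data's overall case:control ratio and predicts case for samples in
high-risk cells; permutation tests of the resulting predictions select
interactions with non-random predictive effect across independent test sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, EffectTable, GenotypeMatrix, JointTable
from .evaluate import roc_auc

__all__ = [
    "estimate_effect_table",
    "compute_prs",
    "compute_ers",
    "compute_crs",
    "select_w",
    "mdr_predict",
    "permutation_select",
    "effect_tables_to_frame",
    "effect_tables_from_frame",
]


def estimate_effect_table(table: JointTable, or_mode: str = "cell_vs_rest") -> EffectTable:
    """Per-cell log odds ratios and MDR high/low labels from a joint table.

    With ``or_mode="cell_vs_rest"`` (default) the OR of cell k is the 2x2
    odds ratio of (case_k, control_k) against the summed counts of all other
    cells; ``"cell_vs_reference"`` uses the (0, 0) cell as the comparator
    instead.  A cell is labeled high-risk when its case:control ratio
    exceeds the table-wide case:control ratio (the MDR threshold T).
    Log-ORs are finite for every cell with positive case and control counts,
    which the cell filter guarantees.
    """
    if or_mode not in ("cell_vs_rest", "cell_vs_reference"):
        raise ValueError(f"unknown or_mode {or_mode!r}")
    case = table.case().astype(np.float64)
    ctrl = table.control().astype(np.float64)
    tot_case = case.sum()
    tot_ctrl = ctrl.sum()
    if tot_case == 0 or tot_ctrl == 0:
        raise ValueError("effect table requires both cases and controls")
    with np.errstate(divide="ignore", invalid="ignore"):
        if or_mode == "cell_vs_rest":
            rest_case = tot_case - case
            rest_ctrl = tot_ctrl - ctrl
            log_or = np.log((case / ctrl) / (rest_case / rest_ctrl))
        else:
            log_or = np.log((case / ctrl) / (case[0, 0] / ctrl[0, 0]))
        ratio = case / ctrl
    threshold = tot_case / tot_ctrl
    high = ratio > threshold
    return EffectTable(table.snp_a, table.snp_b, log_or, high, float(threshold))


def _resolve_weight_orientation(geno: GenotypeMatrix, weights: pd.DataFrame):
    """Map weight rows to matrix columns and effect-allele orientation."""
    meta = geno.snp_meta.set_index("snp")
    cols, flip, eff = [], [], []
    for row in weights.itertuples(index=False):
        if row.snp not in meta.index:
            continue
        a1 = str(meta.at[row.snp, "a1"])
        a2 = str(meta.at[row.snp, "a2"])
        allele = str(row.effect_allele)
        if allele == a1:
            f = False
        elif allele == a2:
            f = True
        else:
            warnings.warn(f"effect allele {allele} of {row.snp} matches neither "
                          f"{a1} nor {a2}; SNP skipped")
            continue
        cols.append(geno.snp_index(row.snp))
        flip.append(f)
        eff.append(float(row.effect_size))
    return np.array(cols, dtype=np.intp), np.array(flip, bool), np.array(eff)


def compute_prs(geno: GenotypeMatrix, weights: pd.DataFrame) -> pd.Series:
    """Per-sample PRS from a weight table (columns snp, effect_allele, effect_size).

    Effect-allele orientation is resolved against the matrix alleles: when
    the effect allele is the non-counted allele, the dosage is reflected
    (2 - calls).  The per-sample denominator N_j counts the weight SNPs with
    an observed genotype; samples observing none get NaN.
    """
    cols, flip, eff = _resolve_weight_orientation(geno, weights)
    if cols.size == 0:
        raise ValueError("no weight SNPs overlap the genotype matrix")
    d = geno.calls[:, cols].astype(np.float64)
    obs = d != MISSING
    d[~obs] = 0.0
    d[:, flip] = np.where(obs[:, flip], 2.0 - d[:, flip], 0.0)
    num = d @ eff
    n_used = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_used > 0, num / n_used, np.nan)
    return pd.Series(score, index=geno.sample_ids, name="prs")


def _dedupe(effect_tables) -> list[EffectTable]:
    seen = set()
    out = []
    for et in effect_tables:
        key = frozenset((et.snp_a, et.snp_b))
        if key in seen:
            continue
        seen.add(key)
        out.append(et)
    return out


def compute_ers(geno: GenotypeMatrix, effect_tables) -> pd.Series:
    """Per-sample ERS from frozen per-interaction effect tables.

    Each interaction with both genotypes observed contributes the log-OR of
    the sample's joint-genotype cell; the sum is divided by the number of
    contributing interactions N_j.  Duplicate interactions (unordered pair
    identity) are dropped, first occurrence kept.  Samples with N_j = 0 get
    NaN.  Scoring depends only on the sample's own genotypes and the frozen
    tables, so it is invariant to the rest of the scored set.
    """
    tables = _dedupe(effect_tables)
    if not tables:
        raise ValueError("no effect tables supplied")
    total = np.zeros(geno.n_samples)
    n_used = np.zeros(geno.n_samples)
    for et in tables:
        ia = geno.snp_index(et.snp_a)
        ib = geno.snp_index(et.snp_b)
        g1 = geno.calls[:, ia]
        g2 = geno.calls[:, ib]
        ok = (g1 != MISSING) & (g2 != MISSING)
        contrib = et.log_or[g1[ok], g2[ok]]
        good = np.isfinite(contrib)
        idx = np.flatnonzero(ok)[good]
        total[idx] += contrib[good]
        n_used[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_used > 0, total / n_used, np.nan)
    return pd.Series(score, index=geno.sample_ids, name="ers")


def compute_crs(prs: pd.Series, ers: pd.Series, w: float) -> pd.Series:
    """CRS_j = w * PRS_j + (1 - w) * ERS_j; absent if either score is absent."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    prs, ers = prs.align(ers)
    out = w * prs + (1.0 - w) * ers
    out.name = "crs"
    return out


def select_w(prs: pd.Series, ers: pd.Series, status: np.ndarray,
             grid_step: float = 0.01) -> float:
    """Grid-search the PRS/ERS mixing weight maximizing AUC on a selection set.

    Evaluates w in {0, grid_step, ..., 1}; ties resolve to the smallest w.
    The selection dataset must be distinct from the evaluation dataset and
    contain both classes.
    """
    status = np.asarray(status)
    if np.unique(status[np.isfinite(status.astype(float))]).size < 2:
        raise ValueError("selection set must contain both cases and controls")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid = np.minimum(grid, 1.0)
    best_w, best_auc = 0.0, -np.inf
    for w in grid:
        crs = compute_crs(prs, ers, float(w))
        ok = np.isfinite(crs.to_numpy())
        auc = roc_auc(crs.to_numpy()[ok], status[ok])
        if auc > best_auc + 1e-12:
            best_auc = auc
            best_w = float(w)
    return best_w


def mdr_predict(effect_table: EffectTable, g1, g2) -> np.ndarray:
    """Predict case (1) iff the (g1, g2) cell is labeled high-risk."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    return effect_table.high_risk[g1, g2].astype(np.int8)


def _balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    case = truth == 1
    ctrl = ~case
    sens = (pred[case] == 1).mean()
    spec = (pred[ctrl] == 0).mean()
    return 0.5 * (sens + spec)


def permutation_select(
    interactions,
    train: tuple[GenotypeMatrix, np.ndarray],
    test_sets,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Select interactions whose MDR predictions beat permuted predictions.

    For each (snp_a, snp_b) interaction an MDR model is trained on ``train``
    and its balanced accuracy measured on every test set (samples with both
    genotypes observed).  The null distribution is obtained by randomly
    permuting the prediction vector against the labels ``n_perm`` times —
    realized as draws of the number of correctly labeled cases from the
    hypergeometric law that an exchangeable permutation induces — and the
    permutation p is the add-one estimator ``(1 + #{null >= obs}) /
    (1 + n_perm)``.  An interaction is selected iff p < alpha in every test
    set.  Interactions whose test labels collapse to a single class are
    skipped with a reason.  Deterministic under ``seed``.
    """
    if len(test_sets) < 2:
        raise ValueError("need at least two test sets")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    from .screen import build_joint_table

    geno_tr, status_tr = train
    pheno_tr = pd.DataFrame({"status": np.asarray(status_tr)})
    rng = np.random.default_rng(seed)
    rows = []
    for snp_a, snp_b in interactions:
        jt = build_joint_table(geno_tr, pheno_tr, snp_a, snp_b)
        et = estimate_effect_table(jt)
        pvals, bas = [], []
        reason = ""
        for geno_te, status_te in test_sets:
            g1 = geno_te.calls[:, geno_te.snp_index(snp_a)]
            g2 = geno_te.calls[:, geno_te.snp_index(snp_b)]
            ok = (g1 != MISSING) & (g2 != MISSING)
            truth = np.asarray(status_te)[ok]
            if np.unique(truth).size < 2:
                reason = "single_class"
                break
            pred = mdr_predict(et, g1[ok], g2[ok])
            obs = _balanced_accuracy(pred, truth)
            n1 = int((truth == 1).sum())
            n0 = int((truth == 0).sum())
            k = int((pred == 1).sum())
            a = rng.hypergeometric(n1, n0, k, size=n_perm) if 0 < k < n1 + n0 \
                else np.full(n_perm, max(0, k - n0) if k else 0)
            null_ba = 0.5 * (a / n1 + (n0 - (k - a)) / n0)
            p = (1.0 + np.sum(null_ba >= obs - 1e-12)) / (1.0 + n_perm)
            pvals.append(p)
            bas.append(obs)
        n_sets = len(test_sets)
        if reason:
            rows.append((snp_a, snp_b, np.nan, *([np.nan] * n_sets), np.nan,
                         False, reason))
            continue
        selected = all(p < alpha for p in pvals)
        rows.append((snp_a, snp_b, float(np.mean(bas)), *map(float, pvals),
                     float(max(pvals)), selected, ""))
    p_cols = [f"p_test{k + 1}" for k in range(len(test_sets))]
    df = pd.DataFrame(
        rows,
        columns=["snp_a", "snp_b", "mean_balanced_accuracy", *p_cols,
                 "max_p", "selected", "skip_reason"],
    )
    return df


# ---------------------------------------------------------------------------
# Effect-table serialization (TSV round trip)
# ---------------------------------------------------------------------------

def effect_tables_to_frame(effect_tables) -> pd.DataFrame:
    rows = []
    for et in effect_tables:
        row = {"snp_a": et.snp_a, "snp_b": et.snp_b, "threshold": et.threshold}
        for g1 in range(3):
            for g2 in range(3):
                row[f"log_or_{g1}{g2}"] = et.log_or[g1, g2]
                row[f"high_{g1}{g2}"] = int(et.high_risk[g1, g2])
        rows.append(row)
    return pd.DataFrame(rows)


def effect_tables_from_frame(df: pd.DataFrame) -> list[EffectTable]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        log_or = np.array(
            [[d[f"log_or_{g1}{g2}"] for g2 in range(3)] for g1 in range(3)]
        )
        high = np.array(
            [[bool(d[f"high_{g1}{g2}"]) for g2 in range(3)] for g1 in range(3)]
        )
        out.append(EffectTable(d["snp_a"], d["snp_b"], log_or, high,
                               float(d["threshold"])))
    return out
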