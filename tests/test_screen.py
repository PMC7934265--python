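"""Interaction tests against independent oracles; screening bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import episcore as ep
from episcore.screen import (
    boost_tables,
    build_joint_tables_batch,
    cell_filter_batch,
    ipf_homogeneous,
    joint_effects_tables,
    logistic_interaction_tables,
    _JE_CELLS,
)
from conftest import random_joint_tables


# ---------------------------------------------------------------------------
# Contingency table construction
# ---------------------------------------------------------------------------

def naive_tally(g1, g2, status):
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    for a, b, s in zip(g1, g2, status):
        if a >= 0 and b >= 0:
            counts[a, b, s] += 1
    return counts


def test_bitwise_equals_naive_tally(small_dataset):
    geno, pheno = small_dataset
    status = pheno["status"].to_numpy()
    rng = np.random.default_rng(1)
    for _ in range(50):
        i, j = rng.choice(geno.n_snps, size=2, replace=False)
        jt = ep.build_joint_table(geno, pheno, int(i), int(j))
        assert np.array_equal(jt.counts,
                              naive_tally(geno.calls[:, i], geno.calls[:, j], status))


def test_batch_builder_equals_bitwise(small_dataset):
    geno, pheno = small_dataset
    status = pheno["status"].to_numpy()
    ia, ib = np.triu_indices(geno.n_snps, k=1)
    pairs = np.column_stack([ia, ib])
    batch = build_joint_tables_batch(geno, status, pairs)
    rng = np.random.default_rng(2)
    for k in rng.choice(len(pairs), size=40, replace=False):
        jt = ep.build_joint_table(geno, pheno, int(pairs[k, 0]), int(pairs[k, 1]))
        assert np.array_equal(batch[k], jt.counts)


def test_missing_excluded_and_total_conserved(small_dataset):
    geno, pheno = small_dataset
    jt = ep.build_joint_table(geno, pheno, 0, 1)
    complete = ((geno.calls[:, 0] >= 0) & (geno.calls[:, 1] >= 0)).sum()
    assert jt.total == complete < geno.n_samples


def test_cell_filter_rules():
    t = np.full((3, 3, 2), 5)
    assert not ep.cell_filter(ep.JointTable(t, "a", "b"), 3)
    t2 = t.copy()
    t2[1, 2, 0] = 2
    assert ep.cell_filter(ep.JointTable(t2, "a", "b"), 3)
    assert not ep.cell_filter(ep.JointTable(t2, "a", "b"), 0)
    assert not ep.cell_filter(ep.JointTable(np.full((3, 3, 2), 3), "a", "b"), 3)


# ---------------------------------------------------------------------------
# Logistic interaction test vs per-sample maximum-likelihood oracle
# ---------------------------------------------------------------------------

def _expand_table(table):
    rows = []
    for g1 in range(3):
        for g2 in range(3):
            for s in range(2):
                rows += [[g1, g2, s]] * int(table[g1, g2, s])
    return np.array(rows)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_logistic_lrt_matches_statsmodels(seed):
    import statsmodels.api as sm

    table = random_joint_tables(1, seed, 3, 25)[0]
    data = _expand_table(table)
    g1, g2, y = data[:, 0].astype(float), data[:, 1].astype(float), data[:, 2]
    X1 = np.column_stack([np.ones_like(g1), g1, g2, g1 * g2])
    ll1 = sm.Logit(y, X1).fit(disp=0, method="newton").llf
    ll0 = sm.Logit(y, X1[:, :3]).fit(disp=0, method="newton").llf
    oracle = 2 * (ll1 - ll0)
    stat, p, ok = logistic_interaction_tables(table.astype(float))
    assert ok[0]
    assert stat[0] == pytest.approx(oracle, abs=1e-6)


def test_logistic_power_on_planted_pair(planted_dataset):
    geno, pheno, i, j = planted_dataset
    stat, p = ep.logistic_interaction_test(geno, pheno, i, j)
    assert p < 1e-4


# ---------------------------------------------------------------------------
# BOOST vs log-linear GLM oracle
# ---------------------------------------------------------------------------

def glm_homogeneous_deviance(table):
    """Poisson GLM fit of the homogeneous-association model; returns deviance."""
    import statsmodels.formula.api as smf

    g1, g2, s = np.meshgrid(range(3), range(3), range(2), indexing="ij")
    df = pd.DataFrame({
        "y": table.ravel(), "g1": g1.ravel().astype(str),
        "g2": g2.ravel().astype(str), "s": s.ravel().astype(str),
    })
    import statsmodels.api as sm
    model = smf.glm("y ~ C(g1)*C(g2) + C(g1)*C(s) + C(g2)*C(s)", data=df,
                    family=sm.families.Poisson())
    return model.fit().deviance


def test_boost_zero_on_homogeneous_table():
    # independence table: margins multiply, no three-way term
    a = np.array([10.0, 20.0, 15.0])
    b = np.array([30.0, 10.0, 25.0])
    c = np.array([2.0, 3.0])
    table = np.einsum("i,j,k->ijk", a, b, c)
    stat, p = ep.boost_test(np.rint(table * 60 / table.sum()).astype(int))
    # rounding perturbs slightly; refit of an exactly homogeneous table is exact
    stat2, p2 = ep.boost_test(table)
    assert stat2 == pytest.approx(0.0, abs=1e-8)
    assert p2 == pytest.approx(1.0, abs=1e-6)


def test_boost_matches_glm_oracle():
    tables = random_joint_tables(30, 7, 3, 50)
    stat, _ = boost_tables(tables.astype(float))
    for k in range(len(tables)):
        assert stat[k] == pytest.approx(glm_homogeneous_deviance(tables[k]),
                                        abs=1e-6)


def test_ipf_matches_margins():
    tables = random_joint_tables(10, 9, 3, 40).astype(float)
    fit = ipf_homogeneous(tables)
    for axes in ((3,), (2,), (1,)):
        assert np.allclose(fit.sum(axis=axes), tables.sum(axis=axes), atol=1e-6)


# ---------------------------------------------------------------------------
# Joint-effects test
# ---------------------------------------------------------------------------

def joint_effects_oracle(table):
    """Scalar delta-method implementation with explicit loops."""
    table = np.asarray(table, dtype=float)
    lam = np.zeros((2, 4))
    V = np.zeros((2, 4, 4))
    for s in range(2):
        n = table[:, :, s]
        for a, (i, j) in enumerate(_JE_CELLS):
            lam[s, a] = np.log(n[i, j]) - np.log(n[i, 0]) - np.log(n[0, j]) \
                + np.log(n[0, 0])
            for b, (k, l) in enumerate(_JE_CELLS):
                cov = 1.0 / (n[0, 0] + 0.5)
                if i == k:
                    cov += 1.0 / (n[i, 0] + 0.5)
                if j == l:
                    cov += 1.0 / (n[0, j] + 0.5)
                if (i, j) == (k, l):
                    cov += 1.0 / (n[i, j] + 0.5)
                V[s, a, b] = cov
    d = lam[1] - lam[0]
    return float(d @ np.linalg.inv(V[0] + V[1]) @ d)


def test_joint_effects_zero_for_proportional_tables():
    rng = np.random.default_rng(5)
    ctrl = rng.integers(5, 40, size=(3, 3))
    table = np.stack([ctrl, ctrl * 3], axis=2)
    stat, p = ep.joint_effects_test(table)
    assert stat == pytest.approx(0.0, abs=1e-10)


def test_joint_effects_matches_delta_oracle():
    tables = random_joint_tables(50, 13, 3, 50)
    stat, p, ok = joint_effects_tables(tables.astype(float))
    assert ok.all()
    for k in range(len(tables)):
        assert stat[k] == pytest.approx(joint_effects_oracle(tables[k]), rel=1e-9)


def test_joint_effects_empty_cell_flagged():
    t = np.full((3, 3, 2), 5)
    t[2, 2, 0] = 0
    with pytest.warns(UserWarning):
        stat, p = ep.joint_effects_test(t)
    assert np.isnan(p)


# ---------------------------------------------------------------------------
# Main-effect scan
# ---------------------------------------------------------------------------

def test_main_effect_scan_null_calibrated():
    cfg = ep.SimulationConfig(n_samples=1600, n_snps=3000,
                              maf_range=(0.1, 0.5), seed=31)
    geno, pheno = ep.simulate_dataset(cfg)
    scan = ep.main_effect_scan(geno, pheno)
    pvals = scan["p"].dropna().to_numpy()
    assert 0.9 < scan.attrs["lambda_gc"] < 1.1
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_main_effect_scan_detects_planted():
    cfg = ep.SimulationConfig(
        n_samples=4000, n_snps=20, mafs=(0.3,) * 20,
        main_effects=((4, 0.5),), baseline_logit=-0.3, seed=33,
    )
    geno, pheno = ep.simulate_dataset(cfg)
    scan = ep.main_effect_scan(geno, pheno)
    assert scan.loc[4, "p"] < 1e-4
    assert scan["p"].idxmin() == 4


def test_main_effect_scan_flags_monomorphic(small_dataset):
    geno, pheno = small_dataset
    calls = geno.calls.copy()
    calls[:, 0] = 0
    geno2 = ep.GenotypeMatrix(calls, geno.snp_meta, geno.sample_meta)
    scan = ep.main_effect_scan(geno2, pheno)
    assert scan.loc[0, "flag"] == "monomorphic"
    assert np.isnan(scan.loc[0, "p"])


# ---------------------------------------------------------------------------
# screen_all_pairs, FDR, LD pruning
# ---------------------------------------------------------------------------

def test_pair_enumeration_count(small_dataset):
    geno, pheno = small_dataset
    res = ep.screen_all_pairs(geno.take_snps(np.arange(10)), pheno,
                              min_cell=0)
    assert res.n_pairs == 45
    assert res.n_valid_tests == 45 * 3


def test_screen_detects_planted_pair(planted_dataset):
    geno, pheno, i, j = planted_dataset
    res = ep.screen_all_pairs(geno, pheno, p_report=1e-4)
    want = tuple(sorted((geno.snp_ids[i], geno.snp_ids[j])))
    hit_methods = set(
        res.results[(res.results.snp_a == want[0]) & (res.results.snp_b == want[1])]
        ["method"]
    )
    assert len(hit_methods) >= 2


def test_screen_invariant_to_snp_order(small_dataset):
    geno, pheno = small_dataset
    sub = geno.take_snps(np.arange(12))
    rng = np.random.default_rng(3)
    perm = rng.permutation(12)
    res1 = ep.screen_all_pairs(sub, pheno, min_cell=3)
    res2 = ep.screen_all_pairs(sub.take_snps(perm), pheno, min_cell=3)
    k = ["snp_a", "snp_b", "method"]
    d1 = res1.results.sort_values(k).reset_index(drop=True)
    d2 = res2.results.sort_values(k).reset_index(drop=True)
    assert d1[k].equals(d2[k])
    assert np.allclose(d1["p"], d2["p"], rtol=1e-10)


def test_fdr_closed_form_and_oracle():
    df = pd.DataFrame({"p": [0.01, 0.02, 0.03]})
    adj = ep.fdr_adjust(df)["fdr"].to_numpy()
    assert np.allclose(adj, [0.03, 0.03, 0.03])
    single = ep.fdr_adjust(pd.DataFrame({"p": [0.2]}))["fdr"].iloc[0]
    assert single == pytest.approx(0.2)

    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(17)
    p = rng.uniform(size=1000)
    mine = ep.fdr_adjust(pd.DataFrame({"p": p}))["fdr"].to_numpy()
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(mine, ref, atol=1e-12)
    # monotone: adjusted ordering preserves raw ordering
    order = np.argsort(p)
    assert (np.diff(mine[order]) >= -1e-15).all()


def test_fdr_custom_denominator():
    df = pd.DataFrame({"p": [1e-6, 1e-4]})
    adj = ep.fdr_adjust(df, n_valid_tests=1000)["fdr"].to_numpy()
    assert adj[0] == pytest.approx(1e-3)
    assert adj[1] == pytest.approx(0.05)


def test_prune_pairs_by_ld(small_dataset):
    geno, pheno = small_dataset
    calls = geno.calls.copy()
    calls[:, 1] = calls[:, 0]  # duplicate SNP -> r2 = 1
    dup = ep.GenotypeMatrix(calls, geno.snp_meta, geno.sample_meta)
    ids = dup.snp_ids
    df = pd.DataFrame({
        "snp_a": [ids[0], ids[2]], "snp_b": [ids[1], ids[3]],
        "method": "boost", "stat": [1.0, 1.0], "p": [0.5, 0.5],
    })
    pruned = ep.prune_pairs_by_ld(df, dup, 0.2)
    assert list(pruned["snp_a"]) == [ids[2]]
    assert pruned["ld_r2"].iloc[0] < 0.2


# ---------------------------------------------------------------------------
# Post-hoc genotypic test
# ---------------------------------------------------------------------------

def test_posthoc_equals_unadjusted_oracle(small_dataset):
    import statsmodels.api as sm

    geno, pheno = small_dataset
    ph = pheno[["sample_id", "status"]].copy()  # no covariates supplied
    stat, p, df = ep.posthoc_genotypic_test(geno, ph, 0, 1, covariates=(),
                                            n_pcs=0)
    g1, g2 = geno.calls[:, 0], geno.calls[:, 1]
    ok = (g1 >= 0) & (g2 >= 0)
    y = pheno["status"].to_numpy(dtype=float)[ok]
    cell = g1[ok] * 3 + g2[ok]
    cells = [c for c in np.unique(cell) if c != 0]
    X = np.column_stack([np.ones(ok.sum())] +
                        [(cell == c).astype(float) for c in cells])
    ll1 = sm.Logit(y, X).fit(disp=0).llf
    ll0 = sm.Logit(y, X[:, :1]).fit(disp=0).llf
    assert stat == pytest.approx(2 * (ll1 - ll0), abs=1e-6)
    assert df == len(cells)


def test_posthoc_attenuates_batch_confounding():
    rng = np.random.default_rng(23)
    n = 3000
    batch = rng.integers(0, 2, n)
    # batch drives both genotype frequency and status
    q = np.where(batch == 1, 0.45, 0.2)
    g1 = rng.binomial(2, q)
    g2 = rng.binomial(2, q)
    status = rng.binomial(1, np.where(batch == 1, 0.65, 0.35))
    calls = np.column_stack([g1, g2]).astype(np.int8)
    snp_meta = pd.DataFrame({"snp": ["x", "y"], "chrom": "1",
                             "pos": [1, 2], "a1": "A", "a2": "G"})
    sample_meta = pd.DataFrame({"sample_id": [f"i{k}" for k in range(n)]})
    geno = ep.GenotypeMatrix(calls, snp_meta, sample_meta)
    pheno = pd.DataFrame({"sample_id": sample_meta.sample_id,
                          "status": status, "batch": batch})
    stat_unadj, _, _ = ep.posthoc_genotypic_test(geno, pheno, "x", "y",
                                                 covariates=(), n_pcs=0)
    stat_adj, _, _ = ep.posthoc_genotypic_test(geno, pheno, "x", "y",
                                               covariates=("batch",), n_pcs=0)
    assert stat_adj < stat_unadj
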