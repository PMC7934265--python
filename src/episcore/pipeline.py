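"""End-to-end orchestration: QC -> scan -> pairwise screen -> FDR/LD prune ->
risk scores -> survival/ROC evaluation.

``run_pipeline`` executes the stages in order on a PLINK fileset plus
phenotype TSV, writing per-stage TSV outputs and a machine-readable manifest
(thresholds, seed, per-stage filter counts, output checksums) into a run
directory.  Because a single dataset stands in for the separate discovery
and evaluation cohorts of a multi-cohort design, samples are split
deterministically (by seed) into a discovery half used for screening and
effect-table estimation and two test sets used for weight selection and
held-out evaluation — scores are never evaluated on the data that produced
their effect tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gqc, risk, screen, syndata
from .core import GenotypeMatrix
from .evaluate import assign_quantiles, kaplan_meier, logrank_test, roc_auc

__all__ = ["RunConfig", "run_pipeline", "make_demo"]


@dataclass
class RunConfig:
    """All pipeline thresholds, with the study's canonical defaults."""

    bfile: str = ""
    pheno: str = ""
    annot: str | None = None
    weights: str | None = None
    max_snp_missing: float = 0.1
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    max_sample_missing: float = 0.2
    het_sd: float = 3.0
    min_score: float = 15.0
    max_gene_distance: float = 5000.0
    n_pcs: int = 3
    methods: tuple[str, ...] = ("logistic", "boost", "joint")
    min_cell: int = 3
    p_report: float = 1e-5
    max_pair_ld: float = 0.2
    tiers: tuple[float, ...] = (1e-7, 1e-6, 1e-5)
    n_perm: int = 10_000
    perm_alpha: float = 0.05
    w_grid: float = 0.01
    quantiles: int = 4
    seed: int = 0
    resume: bool = False  # skip stages whose output files already exist

    def __post_init__(self) -> None:
        for name in ("max_snp_missing", "min_maf", "hwe_alpha",
                     "max_sample_missing", "max_pair_ld"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.min_cell < 0 or self.n_perm < 100 or self.quantiles < 2:
            raise ValueError("invalid min_cell / n_perm / quantiles")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["tiers"] = [float(t) for t in self.tiers]
        return yaml.safe_dump(d, sort_keys=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_samples(n: int, seed: int) -> dict[str, np.ndarray]:
    """Deterministic discovery/testA/testB split (50/25/25)."""
    rng = np.random.default_rng([int(seed), 2])
    perm = rng.permutation(n)
    n_disc = n // 2
    n_a = (n - n_disc) // 2
    return {
        "discovery": np.sort(perm[:n_disc]),
        "test_a": np.sort(perm[n_disc:n_disc + n_a]),
        "test_b": np.sort(perm[n_disc + n_a:]),
    }


def _derive_prs_weights(scan: pd.DataFrame, geno: GenotypeMatrix,
                        n_top: int = 22) -> pd.DataFrame:
    """Synthetic PRS weight table from the discovery main-effect scan.

    Stands in for an external GWAS effect-size table when none is supplied:
    the ``n_top`` SNPs by main-effect p define the score, each weighted by
    its fitted per-allele log-OR with the counted allele as effect allele.
    """
    ok = scan.dropna(subset=["p"]).sort_values("p").head(n_top)
    meta = geno.snp_meta.set_index("snp")
    return pd.DataFrame(
        {
            "snp": ok["snp"].to_numpy(),
            "effect_allele": [meta.at[s, "a1"] for s in ok["snp"]],
            "effect_size": ok["beta"].to_numpy(),
        }
    )


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and return the run directory.

    Writes: ``qc_report.json``, ``scan.tsv``, ``screen.tsv`` (with FDR and
    LD columns), ``effect_tables.tsv``, ``scores.tsv``, ``permutation.tsv``,
    ``evaluation.json``, ``km_quantiles.tsv``, ``config.yaml`` and
    ``manifest.json``.  Any stage failure aborts with the stage named in the
    raised error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    (outdir / "config.yaml").write_text(config.to_yaml())

    def stage(name, output=None):
        def deco(fn):
            if config.resume and output is not None and (outdir / output).exists():
                out = {"resumed_from": output}
            else:
                try:
                    out = fn()
                except Exception as exc:  # noqa: BLE001 - annotate stage, re-raise
                    raise RuntimeError(
                        f"pipeline stage {name!r} failed: {exc}"
                    ) from exc
            manifest["stages"][name] = out
            return out
        return deco

    # ---- load ------------------------------------------------------------
    @stage("load")
    def _load():
        if not Path(config.pheno).exists():
            raise FileNotFoundError(f"phenotype file not found: {config.pheno}")
        return {"bfile": config.bfile, "pheno": config.pheno}

    geno = gqc.read_plink(config.bfile)
    pheno = gqc.read_sample_table(config.pheno)
    pheno = pheno.set_index("sample_id").loc[geno.sample_ids].reset_index()

    # ---- QC: samples first, then SNPs ------------------------------------
    @stage("qc")
    def _qc():
        nonlocal geno, pheno
        geno, pheno, sample_report = gqc.filter_samples(
            geno, pheno, config.max_sample_missing, config.het_sd
        )
        if config.annot:
            annot = pd.read_csv(config.annot, sep="\t")
            geno = gqc.select_by_annotation(
                geno, annot, config.min_score, config.max_gene_distance
            )
        geno, snp_report = gqc.filter_snps(
            geno,
            config.max_snp_missing,
            config.min_maf,
            config.hwe_alpha,
            status=pheno["status"].to_numpy(),
        )
        report = {"samples": sample_report, "snps": snp_report}
        (outdir / "qc_report.json").write_text(json.dumps(report, indent=2))
        return report

    # ---- PCA covariates ---------------------------------------------------
    @stage("pca")
    def _pca():
        nonlocal pheno
        k = min(config.n_pcs, max(geno.n_snps - 1, 0))
        pcs = gqc.genotype_pca(geno, k)
        for i in range(k):
            pheno[f"pc{i + 1}"] = pcs[:, i]
        return {"n_pcs": k}

    # ---- main-effect scan --------------------------------------------------
    @stage("scan", output="scan.tsv")
    def _scan():
        scan = screen.main_effect_scan(geno, pheno, n_pcs=config.n_pcs)
        scan.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        return {"n_snps": len(scan), "lambda_gc": scan.attrs["lambda_gc"]}

    scan = pd.read_csv(outdir / "scan.tsv", sep="\t")

    split = _split_samples(geno.n_samples, config.seed)
    sets = {k: (geno.take_samples(v), pheno.iloc[v].reset_index(drop=True))
            for k, v in split.items()}
    disc_geno, disc_pheno = sets["discovery"]

    # ---- pairwise screen ---------------------------------------------------
    @stage("screen", output="screen.tsv")
    def _screen():
        res = screen.screen_all_pairs(
            disc_geno, disc_pheno, config.methods, config.min_cell,
            p_report=1.0,
        )
        adj = screen.fdr_adjust(res.results, res.n_valid_tests)
        adj = screen.prune_pairs_by_ld(adj, disc_geno, config.max_pair_ld)
        n_before = len(adj)
        reported = adj[adj["p"] <= config.p_report].reset_index(drop=True)
        meta = disc_geno.snp_meta.set_index("snp")
        for side in ("a", "b"):
            reported[f"chr_{side}"] = [meta.at[s, "chrom"] for s in reported[f"snp_{side}"]]
            reported[f"pos_{side}"] = [meta.at[s, "pos"] for s in reported[f"snp_{side}"]]
        cols = ["snp_a", "chr_a", "pos_a", "snp_b", "chr_b", "pos_b",
                "method", "stat", "p", "fdr", "ld_r2"]
        reported[cols].to_csv(outdir / "screen.tsv", sep="\t", index=False)
        return {
            "n_pairs": res.n_pairs,
            "n_pairs_cell_filtered": res.n_pairs_cell_filtered,
            "n_valid_tests": res.n_valid_tests,
            "n_tests_after_ld_prune": n_before,
            "n_reported": len(reported),
        }

    hits = pd.read_csv(outdir / "screen.tsv", sep="\t")

    # ---- effect tables and risk scores -------------------------------------
    @stage("score", output="scores.tsv")
    def _score():
        pair_best = (hits.groupby(["snp_a", "snp_b"], as_index=False)["p"].min())
        tier_tables: dict[float, list] = {}
        all_pairs = []
        for _, row in pair_best.iterrows():
            jt = screen.build_joint_table(disc_geno, disc_pheno,
                                          row["snp_a"], row["snp_b"])
            et = risk.estimate_effect_table(jt)
            all_pairs.append((row["p"], et))
        for tier in config.tiers:
            tier_tables[tier] = [et for p, et in all_pairs if p <= tier]
        if all_pairs:
            risk.effect_tables_to_frame([et for _, et in all_pairs]).to_csv(
                outdir / "effect_tables.tsv", sep="\t", index=False
            )

        if config.weights:
            weights = pd.read_csv(config.weights, sep="\t")
        else:
            weights = _derive_prs_weights(scan, disc_geno)
        scores = {}
        for name in ("test_a", "test_b"):
            g, ph = sets[name]
            df = pd.DataFrame({"sample_id": g.sample_ids,
                               "dataset": name,
                               "status": ph["status"].to_numpy()})
            df["prs"] = risk.compute_prs(g, weights).to_numpy()
            for tier in config.tiers:
                tabs = tier_tables[tier]
                col = f"ers_{tier:g}"
                df[col] = (risk.compute_ers(g, tabs).to_numpy()
                           if tabs else np.nan)
            scores[name] = df
        # CRS: w selected on the opposite test set (finest tier with tables)
        usable = [t for t in config.tiers if tier_tables[t]]
        crs_info = {}
        if usable:
            tier = usable[-1]
            col = f"ers_{tier:g}"
            for name, other in (("test_a", "test_b"), ("test_b", "test_a")):
                sel = scores[other]
                ok = sel[[col, "prs"]].notna().all(axis=1)
                w = risk.select_w(
                    sel.loc[ok, "prs"], sel.loc[ok, col],
                    sel.loc[ok, "status"].to_numpy(), config.w_grid,
                )
                df = scores[name]
                df["crs"] = w * df["prs"] + (1 - w) * df[col]
                crs_info[name] = {"w": w, "tier": tier}
        out = pd.concat(scores.values(), ignore_index=True)
        out.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        return {
            "n_interactions_per_tier": {f"{t:g}": len(tier_tables[t])
                                        for t in config.tiers},
            "crs": crs_info,
            "n_prs_snps": len(weights),
        }

    scores = pd.read_csv(outdir / "scores.tsv", sep="\t")

    # ---- permutation selection ---------------------------------------------
    @stage("permutation", output="permutation.tsv")
    def _perm():
        pair_best = hits.groupby(["snp_a", "snp_b"], as_index=False)["p"].min()
        inter = list(pair_best[["snp_a", "snp_b"]].itertuples(index=False,
                                                              name=None))
        if not inter:
            return {"n_interactions": 0, "n_selected": 0}
        test_sets = [
            (sets[k][0], sets[k][1]["status"].to_numpy())
            for k in ("test_a", "test_b")
        ]
        df = risk.permutation_select(
            inter, (disc_geno, disc_pheno["status"].to_numpy()),
            test_sets, config.n_perm, config.perm_alpha, config.seed,
        )
        df.to_csv(outdir / "permutation.tsv", sep="\t", index=False)
        return {"n_interactions": len(df), "n_selected": int(df["selected"].sum())}

    # ---- evaluation ---------------------------------------------------------
    @stage("evaluate")
    def _evaluate():
        report: dict = {"auc": {}, "logrank": {}}
        ev = scores[scores["dataset"] == "test_b"].reset_index(drop=True)
        ph = sets["test_b"][1]
        score_cols = [c for c in ev.columns
                      if c.startswith(("prs", "ers", "crs"))]
        km_rows = []
        for col in score_cols:
            vals = ev[col].to_numpy(dtype=np.float64)
            ok = np.isfinite(vals)
            if ok.sum() < config.quantiles or ph["status"][ok].nunique() < 2:
                continue
            report["auc"][col] = roc_auc(vals[ok], ev["status"][ok].to_numpy())
            if {"onset_age", "censored"} <= set(ph.columns):
                labels = assign_quantiles(vals[ok], config.quantiles)
                time = ph["onset_age"].to_numpy(dtype=np.float64)[ok]
                event = 1 - ph["censored"].to_numpy()[ok]
                if event.sum() > 0 and np.unique(labels).size > 1:
                    chi2, p = logrank_test(time, event, labels)
                    report["logrank"][col] = {"chi2": chi2, "p": p}
                    for g in range(config.quantiles):
                        sel = labels == g
                        if event[sel].sum() == 0:
                            continue
                        km = kaplan_meier(time[sel], event[sel])
                        km.insert(0, "quantile", g + 1)
                        km.insert(0, "score", col)
                        km_rows.append(km)
        if km_rows:
            pd.concat(km_rows, ignore_index=True).to_csv(
                outdir / "km_quantiles.tsv", sep="\t", index=False
            )
        (outdir / "evaluation.json").write_text(json.dumps(report, indent=2))
        return report

    manifest["outputs"] = {
        p.name: _checksum(p) for p in sorted(outdir.iterdir())
        if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def make_demo(seed: int, outdir) -> Path:
    """Write a small synthetic dataset with known structure plus a summary.

    Two planted interactions (allele-product pattern, per-product log-OR 0.6,
    penetrance anchored at the cohort baseline) and two main-effect SNPs among
    300 SNPs / 4000 samples; the summary file states what a screen of the
    dataset is expected to find.  Sized so the planted pairs are recoverable
    from the discovery half of the pipeline's sample split.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(seed), 3])
    n_snps = 300
    baseline_p = 0.3
    mafs = rng.uniform(0.05, 0.5, n_snps)
    planted = [(40, 80), (150, 260)]
    mains = [(5, 0.30), (220, -0.25)]
    for i, j in planted:
        mafs[i] = mafs[j] = 0.4
    for i, _ in mains:
        mafs[i] = 0.3
    table = syndata.product_penetrance(baseline_p, 0.6)
    config = syndata.SimulationConfig(
        n_samples=4000,
        n_snps=n_snps,
        mafs=tuple(mafs),
        planted_pairs=tuple((i, j, table) for i, j in planted),
        main_effects=tuple(mains),
        baseline_logit=float(np.log(baseline_p / (1 - baseline_p))),
        missing_rate=0.02,
        seed=int(seed),
    )
    geno, pheno = syndata.simulate_dataset(config)
    prefix = outdir / "demo"
    syndata.write_dataset(geno, pheno, prefix, config)
    ids = geno.snp_ids
    lines = [
        "Synthetic demo dataset",
        f"samples: {config.n_samples}  SNPs: {config.n_snps}  seed: {seed}",
        "planted interactions (allele-product log-OR 0.6):",
        *[f"  {ids[i]} x {ids[j]}" for i, j in planted],
        "planted main effects (per-allele log-OR):",
        *[f"  {ids[i]}: {b:+.2f}" for i, b in mains],
        "expected screen outcome: the planted pairs rank among the smallest",
        "interaction p-values for at least two of the three tests; the",
        "planted main-effect SNPs top the single-SNP scan.",
    ]
    (outdir / "demo_summary.txt").write_text("\n".join(lines) + "\n")
    return prefix
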