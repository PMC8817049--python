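"""Calibration and recovery experiments exercising the whole pipeline.

Each function simulates data under the study conditions encoded in
:class:`~medtwas.simulate.SimConfig`, runs the corresponding method, and
returns the operating characteristics (type-I error, power, coverage,
recovery error).  They back both the test suite and the reproduction
script, so the numbers a reader sees are always recomputed from scratch.
Problem sizes default to the designed study conditions; every function is
deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import followup, h2ge, heritability, qtl, train, twas
from .simulate import (
    SimConfig,
    gene_genetic_values,
    marginal_zscores,
    simulate_gene_zscores,
    simulate_genotypes,
    simulate_expression,
    simulate_mediators,
    TruthLedger,
)

__all__ = [
    "burden_null_calibration",
    "burden_vs_grex",
    "added_last_operating",
    "h2ge_recovery",
    "model_route_comparison",
    "h2_recovery",
    "egger_coverage",
    "gbat_null_calibration",
]


def _seeds(seed: int, k: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, k)]


# ---------------------------------------------------------------------------
# weighted burden test


def burden_null_calibration(
    n_draws: int = 10_000,
    n_gwas: int = 5_000,
    n_ref: int = 500,
    n_blocks: int = 50,
    seed: int = 0,
) -> dict:
    """Type-I error of the weighted burden test under a null GWAS.

    Simulates GWAS-cohort genotypes and traits with no genetic effect,
    computes per-variant Z-scores, and tests one random sparse weight
    vector per (LD block, null trait) pair against LD from an independent
    reference panel.  Returns the rejection rate at alpha = 0.05.
    """
    s1, s2, s3 = _seeds(seed, 3)
    cfg = SimConfig(n_blocks=n_blocks, n_genes=n_blocks // 2,
                    n_mediators=n_blocks - n_blocks // 2, seed=s1)
    gwas_geno = simulate_genotypes(cfg, n_gwas, seed=s1)
    ref_geno = simulate_genotypes(cfg, n_ref, seed=s2)
    ref = twas.ld_matrix(ref_geno)
    rng = np.random.default_rng(s3)

    V = cfg.variants_per_block
    n_traits = int(np.ceil(n_draws / n_blocks))
    # standardized genotypes once; each null trait gives one Z vector
    X = gwas_geno.dosages
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    rejections, total = 0, 0
    for _ in range(n_traits):
        y = rng.standard_normal(n_gwas)
        yc = y - y.mean()
        r = (Xc.T @ yc) / (sx * np.sqrt(yc @ yc))
        z = r * np.sqrt(n_gwas - 2) / np.sqrt(1 - r**2)
        for b in range(n_blocks):
            if total >= n_draws:
                break
            cols = slice(b * V, (b + 1) * V)
            w = np.zeros(V)
            nz = rng.choice(V, size=5, replace=False)
            w[nz] = rng.standard_normal(5)
            zt, p = twas.burden_z(w, z[cols], ref.sigma[cols, cols])
            rejections += p < 0.05
            total += 1
    return {"type1": rejections / total, "n": total}


def burden_vs_grex(
    n_genes: int = 200,
    n_gwas: int = 10_000,
    seed: int = 0,
) -> dict:
    """Agreement of summary-statistic burden Z with individual-level GReX Z.

    One LD block per gene; sparse random SNP weights define each gene's
    GReX; a trait loading on a subset of genes is simulated at the
    individual level.  The burden statistic uses in-sample (matched-panel,
    unshrunk) LD so agreement with the Wald Z from regressing the trait on
    imputed GReX is a pure test of the summary-statistic algebra.
    """
    s1, s2 = _seeds(seed, 2)
    cfg = SimConfig(n_blocks=n_genes, n_genes=n_genes // 2,
                    n_mediators=n_genes - n_genes // 2, seed=s1)
    geno = simulate_genotypes(cfg, n_gwas, seed=s1)
    rng = np.random.default_rng(s2)
    V = cfg.variants_per_block
    Z = geno.standardized()

    weights = np.zeros((n_genes, V))
    for g in range(n_genes):
        nz = rng.choice(V, size=5, replace=False)
        weights[g, nz] = rng.standard_normal(5)
    grex = np.column_stack([
        Z[:, g * V:(g + 1) * V] @ weights[g] for g in range(n_genes)
    ])
    causal = rng.choice(n_genes, size=n_genes // 4, replace=False)
    alpha = np.zeros(n_genes)
    alpha[causal] = rng.standard_normal(len(causal))
    genetic = grex @ alpha
    genetic *= np.sqrt(0.2) / genetic.std()
    y = genetic + rng.standard_normal(n_gwas) * np.sqrt(0.8)

    z_snp = marginal_zscores(geno.dosages, y)
    z_burden = np.empty(n_genes)
    z_wald = np.empty(n_genes)
    for g in range(n_genes):
        cols = slice(g * V, (g + 1) * V)
        sig = np.corrcoef(geno.dosages[:, cols], rowvar=False)
        z_burden[g], _ = twas.burden_z(weights[g], z_snp[cols], sig)
        r = np.corrcoef(grex[:, g], y)[0, 1]
        z_wald[g] = r * np.sqrt(n_gwas - 2) / np.sqrt(1 - r**2)
    corr = float(np.corrcoef(z_burden, z_wald)[0, 1])
    return {"correlation": corr, "n": n_genes}


# ---------------------------------------------------------------------------
# distal-SNPs added-last test


def added_last_operating(
    n_reps: int = 200,
    n_train: int = 300,
    n_gwas: int = 50_000,
    gene_trait_r2: float = 0.004,
    seed: int = 0,
) -> dict:
    """Type-I error and power of the added-last test, two-arm Monte Carlo.

    Each replicate trains a MeTWAS model on a fresh synthetic gene
    (mediated architecture, distal h2 0.2) and draws GWAS summary
    statistics analytically: Z ~ N(sqrt(N) * Sigma * beta_std, Sigma), the
    standard distribution of marginal Z-scores under LD.  In the null arm
    the trait acts only through the gene's local locus; in the power arm
    through the full (local + mediated distal) genetic value.  The per-gene
    trait variance (0.4%) matches the magnitude of the strongest
    single-gene TWAS associations at biobank scale (|Z| in the low teens).
    """
    seeds = _seeds(seed, n_reps)
    null_p, alt_p = [], []
    for r_seed in seeds:
        cfg = SimConfig(n_genes=1, n_mediators=1, n_train=n_train,
                        mediation_fraction=1.0, seed=r_seed)
        geno = simulate_genotypes(cfg, n_train, seed=r_seed)
        med, truth = simulate_mediators(geno, cfg, seed=r_seed + 1)
        expr, truth = simulate_expression(geno, med, cfg, truth, seed=r_seed + 2)
        ma = qtl.mediator_gene_assoc(med, expr)
        feat = expr.features.iloc[0]
        model = train.metwas_train(
            "gene_0", expr.values[:, 0], geno, med, ma,
            int(feat["chrom"]), int(feat["pos"]),
            seed=r_seed, compute_h2=False, cv_folds=5,
        )
        if model.flag == "local_fallback" or model.w_distal.abs().sum() == 0:
            continue

        # population-scale LD from a large reference draw
        big = simulate_genotypes(cfg, 2000, seed=r_seed + 3)
        order = {v: i for i, v in enumerate(big.variants["id"])}
        w_ids = list(model.weights["variant"])
        cols = [order[v] for v in w_ids]
        sig = np.corrcoef(big.dosages[:, cols], rowvar=False)
        sig = 0.999 * sig + 0.001 * np.eye(len(cols))
        w = model.weights["weight"].to_numpy()
        cls = model.weights["cls"].to_numpy()
        rng = np.random.default_rng(r_seed + 7)
        L = np.linalg.cholesky(sig)

        rec = truth.genes["gene_0"]
        beta_std = np.zeros(len(cols))
        for vid, eff in zip(rec["local_ids"], rec["local_effects"]):
            if vid in w_ids:
                beta_std[w_ids.index(vid)] = eff
        beta_d = np.zeros(len(cols))
        for mid, gamma in rec["mediators"].items():
            mrec = truth.mediators[mid]
            for vid, eff in zip(mrec["qtl_ids"], mrec["effects"]):
                if vid in w_ids:
                    beta_d[w_ids.index(vid)] = gamma * eff

        loc = cls == "local"
        for arm, bvec in (("null", beta_std), ("alt", beta_std + beta_d)):
            gv = float(bvec @ sig @ bvec)
            if gv <= 0:
                continue
            scale = np.sqrt(gene_trait_r2 / gv)
            mean = np.sqrt(n_gwas) * (sig @ (bvec * scale))
            z = mean + L @ rng.standard_normal(len(cols))
            try:
                _, p = twas.added_last(
                    w[loc], w[~loc], z[loc], z[~loc],
                    sig[np.ix_(loc, loc)], sig[np.ix_(~loc, ~loc)],
                    sig[np.ix_(~loc, loc)],
                )
            except twas.UntestableError:
                continue
            (null_p if arm == "null" else alt_p).append(p)
    return {
        "type1": float(np.mean(np.asarray(null_p) < 0.05)),
        "power": float(np.mean(np.asarray(alt_p) < 0.05)),
        "n_null": len(null_p),
        "n_alt": len(alt_p),
    }


# ---------------------------------------------------------------------------
# expression-mediated heritability


def h2ge_recovery(
    n_reps: int = 25,
    m_genes: int = 1000,
    n_gwas: int = 50_000,
    true_h2ge: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of expression-mediated trait heritability.

    Gene-level Z-scores are drawn from the LD-score regression generative
    model; the fraction of replicates whose estimate falls within 2
    jackknife SE of the truth is reported, along with the mean estimate
    and mean intercept (1 under the model).
    """
    seeds = _seeds(seed, n_reps)
    hits, ests, intercepts = [], [], []
    for s in seeds:
        z, l, _ = simulate_gene_zscores(m_genes, n_gwas, true_h2ge, seed=s)
        fit = h2ge.h2ge_regression(z, l, n_gwas, m_genes)
        hits.append(abs(fit.h2ge - true_h2ge) <= 2 * fit.se)
        ests.append(fit.h2ge)
        intercepts.append(fit.intercept)
    return {
        "coverage_2se": float(np.mean(hits)),
        "mean_h2ge": float(np.mean(ests)),
        "mean_intercept": float(np.mean(intercepts)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# expression model training routes


def model_route_comparison(
    n_reps: int = 50,
    n_train: int = 300,
    seed: int = 0,
    depma_perms: int = 500,
) -> dict:
    """Do mediator-enriched models beat the local baseline on mediated genes?

    Each replicate simulates one gene with the designed mediated
    architecture (local h2 0.2, distally mediated h2 0.2) at the training
    sample size, trains all three routes with the same folds, and compares
    cross-validated adjusted R^2.  Reports mean paired gains and one-sided
    paired t-test p-values.
    """
    seeds = _seeds(seed, n_reps)
    cv_local, cv_met, cv_dep = [], [], []
    for s in seeds:
        cfg = SimConfig(n_genes=1, n_mediators=1, n_train=n_train,
                        mediation_fraction=1.0, seed=s)
        geno = simulate_genotypes(cfg, n_train, seed=s)
        med, truth = simulate_mediators(geno, cfg, seed=s + 1)
        expr, truth = simulate_expression(geno, med, cfg, truth, seed=s + 2)
        y = expr.values[:, 0]
        feat = expr.features.iloc[0]
        chrom, pos = int(feat["chrom"]), int(feat["pos"])
        ma = qtl.mediator_gene_assoc(med, expr)
        scan = qtl.qtl_scan(geno, expr)
        mq = qtl.qtl_scan(geno, med)
        m_l = train.train_local("gene_0", y, geno, chrom, pos, seed=s,
                                compute_h2=False)
        m_m = train.metwas_train("gene_0", y, geno, med, ma, chrom, pos,
                                 seed=s, compute_h2=False)
        m_d = train.depma_train("gene_0", y, geno, med, scan, mq, chrom, pos,
                                seed=s, compute_h2=False, B=depma_perms)
        cv_local.append(m_l.cv_r2_adjusted)
        cv_met.append(m_m.cv_r2_adjusted)
        cv_dep.append(m_d.cv_r2_adjusted)
    cv_local, cv_met, cv_dep = map(np.asarray, (cv_local, cv_met, cv_dep))

    def _paired_one_sided(a, b):
        t, p = stats.ttest_rel(a, b)
        return p / 2 if t > 0 else 1 - p / 2

    return {
        "mean_cv_local": float(cv_local.mean()),
        "mean_cv_metwas": float(cv_met.mean()),
        "mean_cv_depma": float(cv_dep.mean()),
        "gain_metwas": float((cv_met - cv_local).mean()),
        "gain_depma": float((cv_dep - cv_local).mean()),
        "p_metwas_gt_local": float(_paired_one_sided(cv_met, cv_local)),
        "p_depma_gt_local": float(_paired_one_sided(cv_dep, cv_local)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# variance components


def h2_recovery(
    n_reps: int = 50,
    n: int = 5000,
    m_variants: int = 500,
    true_h2: float = 0.4,
    seed: int = 0,
) -> dict:
    """REML recovery of expression heritability from causal-tagging variants.

    Every variant carries a small effect (infinitesimal architecture); the
    realized genetic component is scaled to the target h2.  Reports the
    mean estimate and its maximum absolute error across replicates.
    """
    seeds = _seeds(seed, n_reps)
    ests = []
    cfg = SimConfig(n_blocks=max(m_variants // 20, 1), variants_per_block=20,
                    n_genes=1, n_mediators=1, seed=0)
    for s in seeds:
        geno = simulate_genotypes(cfg, n, seed=s)
        rng = np.random.default_rng(s + 1)
        Z = geno.standardized()
        beta = rng.standard_normal(Z.shape[1])
        g = Z @ beta
        g = g - g.mean()
        g *= np.sqrt(true_h2) / g.std()
        e = rng.standard_normal(n)
        e = e - e.mean()
        e *= np.sqrt(1 - true_h2) / e.std()
        y = g + e
        grm = heritability.build_grm(geno)
        est = heritability.estimate_h2(y, grm)
        ests.append(est.h2)
    ests = np.asarray(ests)
    return {
        "mean_h2": float(ests.mean()),
        "bias": float(ests.mean() - true_h2),
        "max_abs_err_of_mean": float(abs(ests.mean() - true_h2)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# Egger MR


def egger_coverage(
    n_reps: int = 500,
    n_instruments: int = 20,
    true_effect: float = 0.5,
    seed: int = 0,
) -> dict:
    """95% CI coverage of the Egger slope on valid instruments."""
    rng = np.random.default_rng(seed)
    covered = []
    for _ in range(n_reps):
        bx = rng.normal(0.3, 0.15, n_instruments) * rng.choice([-1, 1], n_instruments)
        sx = np.full(n_instruments, 0.05)
        sy = rng.uniform(0.04, 0.08, n_instruments)
        by = true_effect * bx + rng.standard_normal(n_instruments) * sy
        fit = followup.egger_mr(bx, sx, by, sy)
        covered.append(fit.ci_low <= true_effect <= fit.ci_high)
    return {"coverage": float(np.mean(covered)), "n": n_reps}


# ---------------------------------------------------------------------------
# GBAT


def gbat_null_calibration(
    n_reps: int = 500,
    n: int = 149,
    n_snps: int = 20,
    cis_h2: float = 0.3,
    seed: int = 0,
) -> dict:
    """Null calibration of the gene-based trans association scan.

    The regulator has real cis heritability but the target is independent
    noise; leave-one-out GReX prediction should give uniform p-values
    (Kolmogorov-Smirnov test against U(0,1)).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_blocks=1, variants_per_block=n_snps, n_genes=1,
                    n_mediators=1, seed=0)
    pvals = []
    for i in range(n_reps):
        geno = simulate_genotypes(cfg, n, seed=seed + 1 + i)
        Z = geno.standardized()
        beta = rng.standard_normal(n_snps) * np.array(
            [1.0 if j < 3 else 0.0 for j in range(n_snps)])
        g = Z @ beta
        sd = g.std()
        if sd == 0:
            continue
        g *= np.sqrt(cis_h2) / sd
        y_rp = g + rng.standard_normal(n) * np.sqrt(1 - cis_h2)
        y_tg = rng.standard_normal(n)
        res = followup.gbat(geno.dosages, y_rp, y_tg)
        if res.flag == "":
            pvals.append(res.p)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(np.mean(pvals)),
            "n": len(pvals)}
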