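"""Summary-statistics TWAS machinery.

Given per-gene SNP weights, GWAS per-variant Z-scores and an LD reference
panel, the weighted burden statistic is

    Z_tilde = w_G . Z / sqrt(w_G Sigma w_G')

with Sigma the variant correlation (LD) matrix, compared to a standard
normal.  A permutation test shuffles the weight-to-SNP assignment (Sigma
and Z fixed) to ask whether the same distribution of SNP-gene effect sizes
could give the association by chance; it is triggered for burden results
below the transcriptome-wide threshold (2.5e-6 by default).  The
distal-SNPs added-last test asks what the distal weights add beyond the
local locus, via the conditional of the bivariate normal
(w_d Z_d, w_l Z_l) under the null.

When individual genotypes are available, imputed genetically regulated
expression (GReX) and per-sample association scans replace the summary
route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix
from .train import ExpressionModel

__all__ = [
    "LDReference",
    "Harmonized",
    "UntestableError",
    "ld_matrix",
    "harmonize",
    "burden_z",
    "permutation_test",
    "added_last",
    "impute_grex",
    "grex_assoc",
    "run_twas",
]

PERM_TRIGGER = 2.5e-6
AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class UntestableError(ValueError):
    """Gene cannot be tested (zero burden variance or collinear weights)."""


@dataclass
class LDReference:
    """Regularized variant correlation matrix from a reference panel."""

    variants: pd.DataFrame  # id, chrom, pos, a1 (alt), a2 (ref)
    sigma: np.ndarray
    shrink: float = 0.1

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.sigma[np.ix_(idx, idx)]


def ld_matrix(ref: GenotypeMatrix, variant_ids: list[str] | None = None,
              shrink: float = 0.1) -> LDReference:
    """Estimate LD from a reference cohort with shrinkage toward identity.

    Sigma is regularized as (1 - shrink) * Sigma_hat + shrink * I, which
    guarantees positive definiteness at reference-panel sample sizes.
    Monomorphic variants get zero off-diagonal correlation.
    """
    tab = ref.variants
    if variant_ids is not None:
        keep = tab["id"].isin(variant_ids).to_numpy()
        tab = tab[keep]
        dos = ref.dosages[:, keep]
    else:
        dos = ref.dosages
    sd = dos.std(axis=0)
    Z = np.zeros_like(dos, dtype=float)
    ok = sd > 0
    Z[:, ok] = (dos[:, ok] - dos[:, ok].mean(axis=0)) / sd[ok]
    S = np.corrcoef(dos, rowvar=False) if ok.all() else None
    if S is None or np.isnan(S).any():
        S = (Z.T @ Z) / max(dos.shape[0] - 1, 1)
        np.fill_diagonal(S, 1.0)
    S = (1.0 - shrink) * S + shrink * np.eye(S.shape[0])
    out = tab[["id", "chrom", "pos"]].copy()
    out["a1"] = tab["alt"].to_numpy()
    out["a2"] = tab["ref"].to_numpy()
    return LDReference(variants=out.reset_index(drop=True), sigma=S, shrink=shrink)


@dataclass
class Harmonized:
    """Model weights, GWAS Z and LD aligned to the model's effect alleles."""

    w: np.ndarray
    z: np.ndarray
    sigma: np.ndarray
    cls: np.ndarray           # 'local' / 'distal' per retained variant
    variants: list
    n_gwas: float
    n_flipped: int = 0
    n_dropped: int = 0
    weight_coverage: float = 1.0


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((a1.upper(), a2.upper())) in AMBIGUOUS


def harmonize(model: ExpressionModel, gwas: pd.DataFrame, ref: LDReference,
              drop_ambiguous: bool = True, min_coverage: float = 0.5) -> Harmonized:
    """Align model weights, GWAS Z-scores and LD to shared effect alleles.

    Variants are matched by (chrom, pos); allele swaps flip the GWAS Z
    sign; strand-ambiguous (A/T, C/G) variants are dropped by default.  If
    less than ``min_coverage`` of the model's absolute weight mass is
    matched the gene is skipped with a diagnostic.
    """
    wtab = model.weights
    gw = gwas.set_index(["chrom", "pos"])
    ref_idx = {(c, p): i for i, (c, p) in
               enumerate(zip(ref.variants["chrom"], ref.variants["pos"]))}
    total_mass = np.abs(wtab["weight"]).sum()
    rows, flips, drops = [], 0, 0
    for _, r in wtab.iterrows():
        key = (r["chrom"], r["pos"])
        if key not in gw.index or key not in ref_idx:
            drops += 1
            continue
        g = gw.loc[key]
        if isinstance(g, pd.DataFrame):
            g = g.iloc[0]
        a1, a2 = str(g["a1"]).upper(), str(g["a2"]).upper()
        m1, m2 = str(r["a1"]).upper(), str(r["a2"]).upper()
        if drop_ambiguous and _is_ambiguous(m1, m2):
            drops += 1
            continue
        if (a1, a2) == (m1, m2):
            z = float(g["z"])
        elif (a1, a2) == (m2, m1):
            z = -float(g["z"])
            flips += 1
        else:
            drops += 1
            continue
        rows.append((r["variant"], float(r["weight"]), z, r["cls"],
                     ref_idx[key], float(g["n"])))
    if not rows:
        raise UntestableError(f"{model.gene}: no model variant matched the GWAS panel")
    ids, w, z, cls, ridx, ns = zip(*rows)
    coverage = float(np.abs(np.asarray(w)).sum() / total_mass) if total_mass > 0 else 0.0
    if coverage < min_coverage:
        raise UntestableError(
            f"{model.gene}: only {coverage:.0%} of weight mass matched "
            f"(minimum {min_coverage:.0%})"
        )
    sigma = ref.sigma[np.ix_(ridx, ridx)]
    return Harmonized(
        w=np.asarray(w), z=np.asarray(z), sigma=sigma,
        cls=np.asarray(cls), variants=list(ids),
        n_gwas=float(np.median(ns)), n_flipped=flips, n_dropped=drops,
        weight_coverage=coverage,
    )


def burden_z(w: np.ndarray, z: np.ndarray, sigma: np.ndarray) -> tuple[float, float]:
    """Weighted burden Z-statistic and two-sided standard-normal p."""
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    denom = float(w @ sigma @ w)
    if denom <= 0 or not np.isfinite(denom):
        raise UntestableError("burden variance w' Sigma w is not positive")
    zt = float(w @ z) / np.sqrt(denom)
    return zt, 2.0 * stats.norm.sf(abs(zt))


def permutation_test(w: np.ndarray, z: np.ndarray, sigma: np.ndarray,
                     B: int = 1000, seed: int = 0) -> float:
    """Permutation p for the burden test: shuffle weight-to-SNP assignment.

    GWAS Z and LD stay fixed; the weights are permuted without replacement
    B times and the burden statistic recomputed, p = (1 + exceedances)/(B+1).
    """
    if B < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    rng = np.random.default_rng(seed)
    zt_obs, _ = burden_z(w, z, sigma)
    m = len(w)
    P = np.empty((B, m))
    for b in range(B):
        P[b] = w[rng.permutation(m)]
    numer = P @ z
    denom = np.einsum("bi,ij,bj->b", P, sigma, P)
    good = denom > 0
    zt_perm = np.full(B, np.inf)
    zt_perm[good] = numer[good] / np.sqrt(denom[good])
    return float((1.0 + np.sum(np.abs(zt_perm) >= abs(zt_obs))) / (B + 1.0))


def added_last(
    w_l: np.ndarray, w_d: np.ndarray,
    z_l: np.ndarray, z_d: np.ndarray,
    sigma_ll: np.ndarray, sigma_dd: np.ndarray, sigma_dl: np.ndarray,
) -> tuple[float, float]:
    """Distal-SNPs added-last test.

    Under the null that the distal weighted score adds nothing beyond the
    local one, (w_d Z_d, w_l Z_l) is bivariate normal with
    Var_l = w_l S_ll w_l', Var_d = w_d S_dd w_d', Cov = w_d S_dl w_l'.
    The statistic is the conditional residual
    (w_d Z_d - Cov/Var_l * w_l Z_l) / sqrt(Var_d - Cov^2 / Var_l).
    """
    w_l, w_d = np.asarray(w_l, float), np.asarray(w_d, float)
    z_l, z_d = np.asarray(z_l, float), np.asarray(z_d, float)
    if w_d.size == 0:
        raise UntestableError("model has no distal weights")
    var_l = float(w_l @ sigma_ll @ w_l)
    var_d = float(w_d @ sigma_dd @ w_d)
    cov = float(w_d @ sigma_dl @ w_l)
    if var_l <= 0:
        raise UntestableError("local burden variance is not positive")
    cond_var = var_d - cov**2 / var_l
    if cond_var <= 1e-12:
        raise UntestableError("distal weights fully collinear with local weights")
    zt_l = float(w_l @ z_l)
    zt_d = float(w_d @ z_d)
    stat = (zt_d - cov / var_l * zt_l) / np.sqrt(cond_var)
    return float(stat), 2.0 * stats.norm.sf(abs(stat))


def impute_grex(genotypes: GenotypeMatrix, model: ExpressionModel) -> tuple[np.ndarray, float]:
    """Impute genetically regulated expression into a genotyped cohort.

    Model weights multiply column-standardized dosages; model variants
    absent from the cohort contribute zero, with the matched fraction of
    absolute weight mass reported as coverage.
    """
    z = genotypes.standardized()
    ids = list(genotypes.variants["id"])
    order = {v: i for i, v in enumerate(ids)}
    grex = np.full(genotypes.n_samples, model.intercept, dtype=float)
    mass = matched = 0.0
    for v, w in zip(model.weights["variant"], model.weights["weight"]):
        mass += abs(w)
        if v in order:
            matched += abs(w)
            grex += w * z[:, order[v]]
    coverage = matched / mass if mass > 0 else 0.0
    return grex, float(coverage)


def grex_assoc(
    grex: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    family: str = "linear",
) -> dict:
    """Association of imputed expression with a phenotype (Wald test).

    Linear regression for continuous phenotypes, logistic for binary;
    returns effect, SE, 95% CI and p for the GReX term.
    """
    grex = np.asarray(grex, dtype=float)
    if np.std(grex) < 1e-12:
        raise UntestableError("zero-variance GReX")
    n = len(grex)
    X = np.column_stack([np.ones(n), grex])
    names = ["const", "grex"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
        cnames = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                  else [f"c{i}" for i in range(C.shape[1])])
        names += cnames
    y = np.asarray(phenotype, dtype=float)
    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "logistic":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("logistic family requires a 0/1 phenotype")
        fit = sm.Logit(y, X).fit(disp=0)
    else:
        raise ValueError("family must be 'linear' or 'logistic'")
    ci = fit.conf_int()[1]
    return {
        "effect": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p": float(fit.pvalues[1]),
    }


def run_twas(
    models: list[ExpressionModel],
    gwas: pd.DataFrame,
    ref: LDReference,
    perm_trigger: float = PERM_TRIGGER,
    B: int = 1000,
    seed: int = 0,
    require_admitted: bool = True,
) -> pd.DataFrame:
    """Staged TWAS over a model set: burden, permutation, added-last.

    Mirrors the staged funnel of a summary-statistics TWAS: burden test on
    every admitted gene; permutation test for burden p below
    ``perm_trigger``; added-last test for models with distal weights, with
    BH adjustment across tested genes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        if require_admitted and not model.admitted:
            continue
        rec = {"gene": model.gene, "method": model.method, "n_snps": np.nan,
               "z_burden": np.nan, "p_burden": np.nan, "p_perm": np.nan,
               "z_distal": np.nan, "p_distal": np.nan, "coverage": np.nan,
               "flag": ""}
        try:
            h = harmonize(model, gwas, ref)
        except UntestableError as err:
            rec["flag"] = str(err)
            rows.append(rec)
            continue
        rec["n_snps"] = len(h.w)
        rec["coverage"] = h.weight_coverage
        try:
            zt, p = burden_z(h.w, h.z, h.sigma)
        except UntestableError as err:
            rec["flag"] = str(err)
            rows.append(rec)
            continue
        rec["z_burden"], rec["p_burden"] = zt, p
        if p < perm_trigger:
            rec["p_perm"] = permutation_test(h.w, h.z, h.sigma, B=B,
                                             seed=int(rng.integers(2**31 - 1)))
        loc = h.cls == "local"
        if (~loc).any() and loc.any():
            try:
                stat, p_d = added_last(
                    h.w[loc], h.w[~loc], h.z[loc], h.z[~loc],
                    h.sigma[np.ix_(loc, loc)],
                    h.sigma[np.ix_(~loc, ~loc)],
                    h.sigma[np.ix_(~loc, loc)],
                )
                rec["z_distal"], rec["p_distal"] = stat, p_d
            except UntestableError as err:
                rec["flag"] = str(err)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["p_distal"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "p_distal"], method="fdr_bh")[1]
        out["q_distal"] = q
    return out
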