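"""Expression-mediated trait heritability and genetic correlation.

Gene-level LD-score regression: under a polygenic expression-trait model
the expected TWAS chi-square of gene g is

    E[chi2_g] = 1 + (N l_g / M) * h2_GE + N a

where N is the GWAS sample size, M the number of genes, l_g the gene LD
score (sum of squared predicted-expression correlations of g with all
genes in the set, self included) and ``a`` absorbs population structure.
h2_GE comes from ordinary least squares of chi2 on l, with a block
jackknife over genes for the SE and a one-sided test of h2_GE > 0.

Genetic correlation at the predicted-expression level regresses the
Z-score cross products of two traits on the same LD scores and normalizes
the implied co-heritability by sqrt(h2_GE,1 * h2_GE,2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import GenotypeMatrix
from .twas import impute_grex

__all__ = ["H2GEFit", "RgeFit", "gene_ld_scores", "h2ge_regression", "rge_correlation"]


@dataclass
class H2GEFit:
    h2ge: float
    se: float
    p: float
    intercept: float
    slope: float
    m_genes: int
    n_gwas: float
    flag: str = ""


@dataclass
class RgeFit:
    rge: float
    se: float
    p: float
    h2ge_1: float
    h2ge_2: float
    clamped: bool = False
    flag: str = ""


def gene_ld_scores(models=None, ref: GenotypeMatrix | None = None,
                   grex: np.ndarray | None = None) -> np.ndarray:
    """Gene LD scores l_i = sum_j r^2(GReX_i, GReX_j), self included.

    Either pass trained ``models`` plus a reference panel (expression is
    imputed into the panel) or a precomputed reference GReX matrix
    (samples x genes).
    """
    if grex is None:
        if models is None or ref is None:
            raise ValueError("need either grex or (models, ref)")
        if len(models) < 2:
            raise ValueError("need at least two admitted models")
        grex = np.column_stack([impute_grex(ref, m)[0] for m in models])
    G = np.asarray(grex, dtype=float)
    sd = G.std(axis=0)
    bad = sd < 1e-12
    R = np.corrcoef(G, rowvar=False)
    if bad.any():
        R[bad, :] = 0.0
        R[:, bad] = 0.0
        R[np.diag_indices_from(R)] = 1.0
    return (R**2).sum(axis=1)


def _jackknife(theta_full: float, loo: np.ndarray) -> float:
    b = len(loo)
    return float(np.sqrt((b - 1) / b * np.sum((loo - loo.mean()) ** 2)))


def _block_ols(y: np.ndarray, x: np.ndarray, n_blocks: int):
    """OLS slope/intercept with delete-one-block jackknife slopes."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    blocks = np.array_split(np.arange(n), min(n_blocks, n))
    loo_slope = np.empty(len(blocks))
    for i, blk in enumerate(blocks):
        keep = np.setdiff1d(np.arange(n), blk)
        c, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        loo_slope[i] = c[1]
    return coef[0], coef[1], loo_slope


def h2ge_regression(
    twas_z: np.ndarray,
    ld: np.ndarray,
    n_gwas: float,
    m_genes: int | None = None,
    n_blocks: int = 200,
) -> H2GEFit:
    """Estimate expression-mediated trait heritability by gene LD-score OLS.

    Regresses per-gene chi2 = Z^2 on gene LD scores; the slope rescaled by
    M/N gives h2_GE.  SE comes from a delete-one-block jackknife (200
    blocks by default) and the p-value is one-sided for h2_GE > 0.
    """
    z = np.asarray(twas_z, dtype=float)
    l = np.asarray(ld, dtype=float)
    if len(z) != len(l):
        raise ValueError("Z-scores and LD scores must align")
    M = m_genes if m_genes is not None else len(z)
    flag = "" if M >= 50 else "unstable_few_genes"
    if np.ptp(l) < 1e-12:
        return H2GEFit(h2ge=np.nan, se=np.nan, p=np.nan, intercept=np.nan,
                       slope=np.nan, m_genes=M, n_gwas=n_gwas,
                       flag="constant_ld_scores")
    chi2 = z**2
    icept, slope, loo = _block_ols(chi2, l, n_blocks)
    h2 = slope * M / n_gwas
    se = _jackknife(slope, loo) * M / n_gwas
    p = float(stats.norm.sf(h2 / se)) if se > 0 else np.nan
    return H2GEFit(h2ge=float(h2), se=float(se), p=p, intercept=float(icept),
                   slope=float(slope), m_genes=M, n_gwas=float(n_gwas), flag=flag)


def rge_correlation(
    twas_z1: np.ndarray,
    twas_z2: np.ndarray,
    ld: np.ndarray,
    n1: float,
    n2: float,
    m_genes: int | None = None,
    n_blocks: int = 200,
) -> RgeFit:
    """Genetic correlation between two traits at the predicted-expression level.

    The slope of the Z-score cross product on gene LD scores estimates the
    expression-level co-heritability; normalizing by the two traits'
    h2_GE gives rho_GE, clamped to [-1, 1] with clamping flagged.
    """
    z1 = np.asarray(twas_z1, dtype=float)
    z2 = np.asarray(twas_z2, dtype=float)
    l = np.asarray(ld, dtype=float)
    M = m_genes if m_genes is not None else len(z1)
    fit1 = h2ge_regression(z1, l, n1, M, n_blocks)
    fit2 = h2ge_regression(z2, l, n2, M, n_blocks)
    if not (fit1.h2ge > 0 and fit2.h2ge > 0):
        return RgeFit(rge=np.nan, se=np.nan, p=np.nan, h2ge_1=fit1.h2ge,
                      h2ge_2=fit2.h2ge, flag="nonpositive_h2ge")
    cross = z1 * z2
    _, slope, loo = _block_ols(cross, l, n_blocks)
    gcov = slope * M / np.sqrt(n1 * n2)
    denom = np.sqrt(fit1.h2ge * fit2.h2ge)
    rge = gcov / denom
    se = (_jackknife(slope, loo) * M / np.sqrt(n1 * n2)) / denom
    clamped = False
    if abs(rge) > 1:
        rge = float(np.clip(rge, -1.0, 1.0))
        clamped = True
    p = float(2 * stats.norm.sf(abs(rge) / se)) if se > 0 else np.nan
    return RgeFit(rge=float(rge), se=float(se), p=p, h2ge_1=fit1.h2ge,
                  h2ge_2=fit2.h2ge, clamped=clamped)
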