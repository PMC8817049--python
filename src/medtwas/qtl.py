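"""Linear-model association scans: eQTL, mediator-QTL and mediator-gene.

All scans use the residualize-then-correlate formulation: outcome and
predictor are projected off the covariate span (plus intercept), and the
per-pair simple regression on residuals — with degrees of freedom reduced
by the number of projected-out covariates — reproduces the slope, SE and
t-statistic of the full multiple regression (Frisch–Waugh–Lovell).  A
brute-force per-pair OLS oracle is kept in the test suite.

Variants are classified cis (same chromosome and within ``cis_window`` of
the feature position, closed interval) or distal (farther than the window,
or a different chromosome).  Benjamini–Hochberg q-values are computed
within each scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix, OmicsMatrix

__all__ = ["RankError", "residualize", "qtl_scan", "mediator_gene_assoc"]

CIS_WINDOW = 1_000_000


class RankError(np.linalg.LinAlgError):
    """Covariate matrix is rank deficient."""


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError(f"covariates have {C.shape[0]} rows, data have {n}")
    return np.column_stack([np.ones(n), C])


def _check_rank(X: np.ndarray, names=None) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        labels = [str(b) for b in bad] if names is None else [str(names[b - 1]) for b in bad]
        raise RankError(f"covariate design is rank deficient (columns: {', '.join(labels)})")


def residualize(
    values: np.ndarray | OmicsMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    rescale: bool = True,
):
    """Project feature columns off the covariate span (with intercept).

    Returns ``(residuals, degenerate)``: residual columns are re-scaled to
    unit variance unless their residual variance is (near) zero, in which
    case they are flagged degenerate and left at zero.  Applying the
    projection twice equals applying it once.
    """
    om = values if isinstance(values, OmicsMatrix) else None
    Y = om.values if om is not None else np.asarray(values, dtype=float)
    one_dim = Y.ndim == 1
    if one_dim:
        Y = Y[:, None]
    n = Y.shape[0]
    X = _design(covariates, n)
    names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else None
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    var = R.var(axis=0, ddof=1)
    degenerate = var < 1e-12
    if rescale:
        sd = np.sqrt(np.where(degenerate, 1.0, var))
        R = R / sd
        R[:, degenerate] = 0.0
    if om is not None:
        out = OmicsMatrix(values=R, features=om.features.copy(),
                          samples=list(om.samples), scaled=rescale)
        return out, degenerate
    return (R[:, 0], bool(degenerate[0])) if one_dim else (R, degenerate)


def _pairwise_stats(Xr: np.ndarray, Yr: np.ndarray, df: int):
    """Correlation-based slope/SE/t/p for every (predictor, outcome) pair.

    Xr, Yr are covariate-residualized (not necessarily unit-variance)
    matrices; df is the residual degrees of freedom n - k - 2.
    """
    n = Xr.shape[0]
    xc = Xr - Xr.mean(axis=0)
    yc = Yr - Yr.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    good_x = sx > 1e-10
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(sx, sy)
        r = np.clip(r, -1.0, 1.0)
        beta = r * (sy[None, :] / sx[:, None])
        denom = np.sqrt(np.maximum(1.0 - r**2, 1e-300))
        t = r * np.sqrt(df) / denom
        se = beta / np.where(t == 0, np.nan, t)
        # for r == 0 the SE is still finite: fall back to direct formula
        se_direct = (sy[None, :] / sx[:, None]) / np.sqrt(df)
        se = np.where(np.isnan(se), se_direct, se)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta[~good_x, :] = np.nan
    se[~good_x, :] = np.nan
    t[~good_x, :] = np.nan
    p[~good_x, :] = np.nan
    return beta, se, t, p, ~good_x


def _classify(var_chrom, var_pos, feat_chrom, feat_pos, window) -> np.ndarray:
    same = var_chrom[:, None] == feat_chrom[None, :]
    near = np.abs(var_pos[:, None] - feat_pos[None, :]) <= window
    return same & near


def _scan_frame(pred_ids, feat_ids, beta, se, t, p, cis_mask, degenerate, mode):
    n_pred, n_feat = beta.shape
    keep = np.ones((n_pred, n_feat), dtype=bool)
    if mode == "cis":
        keep = cis_mask
    elif mode == "distal":
        keep = ~cis_mask
    elif mode != "genomewide":
        raise ValueError(f"unknown mode {mode!r}")
    pi, fi = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "feature": np.asarray(feat_ids)[fi],
            "variant": np.asarray(pred_ids)[pi],
            "beta": beta[pi, fi],
            "se": se[pi, fi],
            "t": t[pi, fi],
            "p": p[pi, fi],
            "cls": np.where(cis_mask[pi, fi], "cis", "distal"),
            "degenerate": degenerate[pi],
        }
    )
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out


def qtl_scan(
    genotypes: GenotypeMatrix,
    omics: OmicsMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    mode: str = "genomewide",
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Additive-model SNP-feature association scan.

    Per (feature, variant) pair: slope, SE, t and p of the feature on SNP
    dosage adjusted for covariates, matching full multiple regression.
    Monomorphic variants are emitted with NA statistics and a degeneracy
    flag.  Returns a long DataFrame with BH q-values within the scan.
    """
    n = genotypes.n_samples
    k = 0 if covariates is None else _design(covariates, n).shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > covariates + 2")
    Xr, _ = residualize(genotypes.dosages, covariates, rescale=False)
    Yr, _ = residualize(omics.values, covariates, rescale=False)
    df = n - k - 2
    beta, se, t, p, degen = _pairwise_stats(Xr, Yr, df)
    cis = _classify(
        genotypes.variants["chrom"].to_numpy(),
        genotypes.variants["pos"].to_numpy(),
        omics.features["chrom"].to_numpy(),
        omics.features["pos"].to_numpy(),
        cis_window,
    )
    return _scan_frame(
        genotypes.variants["id"].to_numpy(), omics.features["id"].to_numpy(),
        beta, se, t, p, cis, degen, mode,
    )


def mediator_gene_assoc(
    mediators: OmicsMatrix,
    genes: OmicsMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Mediator-intensity to gene-expression association scan.

    Same linear model as :func:`qtl_scan` with mediator intensity as the
    main predictor; the ``variant`` column holds the mediator id.
    """
    n = mediators.values.shape[0]
    k = 0 if covariates is None else _design(covariates, n).shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > covariates + 2")
    Xr, _ = residualize(mediators.values, covariates, rescale=False)
    Yr, _ = residualize(genes.values, covariates, rescale=False)
    df = n - k - 2
    beta, se, t, p, degen = _pairwise_stats(Xr, Yr, df)
    cis = _classify(
        mediators.features["chrom"].to_numpy(),
        mediators.features["pos"].to_numpy(),
        genes.features["chrom"].to_numpy(),
        genes.features["pos"].to_numpy(),
        cis_window,
    )
    return _scan_frame(
        mediators.features["id"].to_numpy(), genes.features["id"].to_numpy(),
        beta, se, t, p, cis, degen, mode="genomewide",
    )
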