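"""Mediator-to-gene follow-up analyses and qPCR utilities.

* Gene-based trans association (GBAT-style): the regulator's genetically
  regulated expression is predicted from its cis-SNPs by leave-one-out
  cross-validated ridge, then the target gene is regressed on the LOO
  prediction.  The LOO step is what keeps the scan calibrated — in-sample
  prediction leaks the regulator's noise into the predictor and inflates
  the null.
* Egger-regression Mendelian randomization: inverse-variance weighted
  regression of per-instrument outcome effects on exposure effects WITH an
  intercept; the slope estimates the causal effect, the intercept tests
  directional pleiotropy.
* qPCR fold changes by the delta-delta-CT method, and the
  differential-expression decision rule (Bonferroni p threshold combined
  with a log2 fold-change cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import residualize

__all__ = [
    "TransAssocResult",
    "MRFit",
    "gbat",
    "egger_mr",
    "select_instruments",
    "ddct_fold_change",
    "de_call",
    "bonferroni_threshold",
]


@dataclass
class TransAssocResult:
    effect: float
    se: float
    t: float
    p: float
    loo_r2: float
    ridge_lambda: float
    flag: str = ""


@dataclass
class MRFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    ci_low: float
    ci_high: float
    p_slope: float
    p_intercept: float
    n_instruments: int


def _loo_ridge(y: np.ndarray, Z: np.ndarray, lambdas: np.ndarray):
    """Leave-one-out ridge predictions via the hat-matrix identity.

    For each penalty, loo_i = (yhat_i - h_ii y_i) / (1 - h_ii); the penalty
    minimizing LOO squared error of the *regulator* is kept (the target
    plays no role in the choice, so no leakage into the trans test).
    """
    n, m = Z.shape
    best = (np.inf, None, None)
    ZtZ = Z.T @ Z
    for lam in lambdas:
        A = np.linalg.solve(ZtZ + lam * np.eye(m), Z.T)
        H = Z @ A
        h = np.diag(H)
        yhat = H @ y
        denom = np.clip(1.0 - h, 1e-8, None)
        loo = (yhat - h * y) / denom
        err = float(np.mean((y - loo) ** 2))
        if err < best[0]:
            best = (err, loo, lam)
    return best[1], best[2]


def gbat(
    rp_cis_dosages: np.ndarray,
    rp_expression: np.ndarray,
    target_expression: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
) -> TransAssocResult:
    """Trans association of a regulatory-protein gene with a target gene.

    Predicts the regulator's expression from its cis dosages by LOO ridge
    and regresses the (covariate-residualized) target on the LOO
    prediction.  A near-constant LOO prediction (no usable cis signal) is
    flagged untestable.
    """
    y_rp, _ = residualize(np.asarray(rp_expression, float), covariates, rescale=True)
    y_tg, _ = residualize(np.asarray(target_expression, float), covariates, rescale=True)
    X = np.asarray(rp_cis_dosages, dtype=float)
    n, m = X.shape
    sd = X.std(axis=0, ddof=1)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    if lambdas is None:
        lambdas = m * np.array([0.1, 0.5, 1.0, 2.0, 5.0, 20.0])
    pred, lam = _loo_ridge(y_rp, Z, lambdas)
    if np.std(pred) < 1e-10:
        return TransAssocResult(np.nan, np.nan, np.nan, np.nan,
                                loo_r2=0.0, ridge_lambda=float(lam),
                                flag="untestable_no_cis_signal")
    loo_r2 = float(np.corrcoef(y_rp, pred)[0, 1] ** 2)
    xc = pred - pred.mean()
    yc = y_tg - y_tg.mean()
    beta = float((xc @ yc) / (xc @ xc))
    k = 0
    if covariates is not None:
        C = np.asarray(covariates)
        k = 1 if C.ndim == 1 else C.shape[1]
    df = n - 2 - k
    resid = yc - beta * xc
    se = float(np.sqrt((resid @ resid) / df / (xc @ xc)))
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TransAssocResult(effect=beta, se=se, t=float(t), p=float(p),
                            loo_r2=loo_r2, ridge_lambda=float(lam))


def select_instruments(
    beta_exposure: np.ndarray,
    p_exposure: np.ndarray,
    ld: np.ndarray,
    p_outcome_direct: np.ndarray | None = None,
    p_thresh: float = 1e-3,
    r2_thresh: float = 0.1,
    p_outcome_thresh: float = 0.05,
) -> np.ndarray:
    """Greedy instrument selection for MR: exposure-associated, LD-pruned.

    Candidates with exposure p below ``p_thresh`` are walked strongest
    first; a candidate is kept only if its LD r^2 with every kept
    instrument is below ``r2_thresh``.  Optionally, candidates with direct
    outcome association below ``p_outcome_thresh`` are excluded.
    Returns indices of selected instruments.
    """
    p = np.asarray(p_exposure, dtype=float)
    cand = np.flatnonzero(p < p_thresh)
    if p_outcome_direct is not None:
        po = np.asarray(p_outcome_direct, dtype=float)
        cand = cand[po[cand] >= p_outcome_thresh]
    cand = cand[np.argsort(p[cand])]
    kept: list[int] = []
    for c in cand:
        if all(ld[c, k] ** 2 < r2_thresh for k in kept):
            kept.append(int(c))
    return np.asarray(kept, dtype=int)


def egger_mr(
    beta_exposure: np.ndarray,
    se_exposure: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
) -> MRFit:
    """Directional Egger-regression Mendelian randomization.

    Inverse-variance weighted regression of outcome effects on exposure
    effects with an intercept; 95% Wald-type CI on the slope uses the t
    distribution with (k - 2) degrees of freedom.
    """
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    k = len(bx)
    if k < 3:
        raise ValueError(f"Egger regression needs at least 3 instruments, got {k}")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    dof = k - 2
    s2 = float((w * resid**2).sum() / dof)
    cov = s2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(0.975, dof)
    slope, icept = float(coef[1]), float(coef[0])
    p_slope = 2.0 * stats.t.sf(abs(slope / se[1]), dof) if se[1] > 0 else np.nan
    p_icept = 2.0 * stats.t.sf(abs(icept / se[0]), dof) if se[0] > 0 else np.nan
    return MRFit(
        slope=slope, slope_se=float(se[1]), intercept=icept,
        intercept_se=float(se[0]), ci_low=slope - tq * se[1],
        ci_high=slope + tq * se[1], p_slope=float(p_slope),
        p_intercept=float(p_icept), n_instruments=k,
    )


def ddct_fold_change(
    ct: pd.DataFrame,
    reference_condition: str,
    housekeeping: str = "ACTB",
) -> pd.DataFrame:
    """Relative expression fold changes by the delta-delta-CT method.

    ``ct`` is long format (sample, gene, condition, CT).  Per sample and
    gene: dCT = CT_gene - CT_housekeeping; ddCT = dCT - mean dCT of the
    reference condition; fold change = 2^(-ddCT).  Returns per-sample fold
    changes plus a per-gene-per-condition mean and SD summary.
    """
    required = {"sample", "gene", "condition", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise ValueError("CT values must be positive and finite")
    house = ct[ct["gene"] == housekeeping].set_index(["condition", "sample"])["ct"]
    goi = ct[ct["gene"] != housekeeping].copy()
    keys = list(zip(goi["condition"], goi["sample"]))
    try:
        goi["dct"] = goi["ct"].to_numpy() - house.loc[keys].to_numpy()
    except KeyError as err:
        raise ValueError(f"housekeeping CT missing for {err}") from err
    ref_dct = (goi[goi["condition"] == reference_condition]
               .groupby("gene")["dct"].mean())
    if ref_dct.empty:
        raise ValueError(f"no samples in reference condition {reference_condition!r}")
    goi["ddct"] = goi["dct"] - ref_dct.loc[goi["gene"]].to_numpy()
    goi["fold_change"] = 2.0 ** (-goi["ddct"])
    summary = (goi.groupby(["gene", "condition"])["fold_change"]
               .agg(["mean", "std"]).reset_index())
    return goi.merge(summary, on=["gene", "condition"], suffixes=("", "_cond"))


def bonferroni_threshold(alpha: float, m_genes: int) -> float:
    """Family-wise p threshold alpha / m."""
    if m_genes <= 0:
        raise ValueError("m_genes must be positive")
    return alpha / m_genes


def de_call(log2fc, p, m_genes: int, alpha: float = 0.05,
            lfc_threshold: float = 1.0):
    """Differential-expression decision rule.

    A gene is 'up' ('down') when |log2 fold change| exceeds
    ``lfc_threshold`` and p is below the Bonferroni threshold
    alpha / m_genes; otherwise 'not_de'.  Vectorized over arrays.
    """
    thr = bonferroni_threshold(alpha, m_genes)
    lfc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    sig = (np.abs(lfc) > lfc_threshold) & (pv < thr)
    out = np.where(sig & (lfc > 0), "up", np.where(sig, "down", "not_de"))
    return out if out.ndim else str(out)
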