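"""Per-gene SNP-weight expression models: local baseline, MeTWAS, DePMA.

Three training routes produce a common :class:`ExpressionModel` of SNP
weights on the standardized-dosage scale:

* ``local`` — elastic net (mixing 0.5, penalty by inner 5-fold CV) or a
  ridge-equivalent mixed-model BLUP on cis-SNPs within 1 Mb of the gene.
* ``MeTWAS`` — mediators associated with the gene (FDR < 0.05 in the
  mediator-gene scan) get their own local SNP models; their in-sample
  imputed intensities enter the gene's regularized regression as fixed
  effects, and the final distal SNP weight is the chain-of-regressions
  product (mediator coefficient) x (SNP weight in that mediator's model).
* ``DePMA`` — distal-eQTLs (P < 1e-6) routed through at least one cis
  mediator-QTL (FDR < 0.05) are screened by a permutation test of their
  absolute total mediation effect (TME); surviving variants join the cis
  SNPs in the final regularized regression.

A model is admitted to TWAS only with heritability LR P < 0.05 and
fivefold McNemar-adjusted cross-validation R^2 >= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from . import heritability
from .qtl import residualize
from .simulate import GenotypeMatrix, OmicsMatrix

__all__ = [
    "ExpressionModel",
    "MediationResult",
    "adjusted_r2",
    "fit_local_model",
    "cross_validate",
    "metwas_train",
    "compute_tme",
    "depma_train",
    "train_gene",
]

CIS_WINDOW = 1_000_000
H2_P_GATE = 0.05
CV_R2_GATE = 0.01


@dataclass
class ExpressionModel:
    """Trained SNP-weight model of one gene's expression.

    ``weights`` is a table (variant, chrom, pos, a1, a2, weight, cls,
    mediator) with weights on the standardized-dosage scale; ``cls`` is
    ``local`` or ``distal`` and ``mediator`` records provenance of composed
    distal weights.  Predicted expression is
    ``intercept + Z_std @ weight`` plus, for MeTWAS, nothing else — the
    mediator stages are already composed into the SNP weights.
    """

    gene: str
    method: str
    weights: pd.DataFrame
    intercept: float = 0.0
    mediators: list = field(default_factory=list)
    cv_r2_adjusted: float = np.nan
    h2: float = np.nan
    h2_p: float = np.nan
    n_train: int = 0
    flag: str = ""

    @property
    def w_local(self) -> pd.Series:
        t = self.weights[self.weights["cls"] == "local"]
        return pd.Series(t["weight"].to_numpy(), index=t["variant"].to_numpy())

    @property
    def w_distal(self) -> pd.Series:
        t = self.weights[self.weights["cls"] == "distal"]
        return pd.Series(t["weight"].to_numpy(), index=t["variant"].to_numpy())

    @property
    def admitted(self) -> bool:
        """Inclusion gate: heritability P < 0.05 and CV adjusted R^2 >= 0.01."""
        return bool(self.h2_p < H2_P_GATE) and bool(self.cv_r2_adjusted >= CV_R2_GATE)

    def predict(self, z_std: np.ndarray, variant_ids: list[str]) -> np.ndarray:
        order = {v: i for i, v in enumerate(variant_ids)}
        pred = np.full(z_std.shape[0], self.intercept, dtype=float)
        for v, w in zip(self.weights["variant"], self.weights["weight"]):
            if v in order and w != 0:
                pred += w * z_std[:, order[v]]
        return pred


@dataclass
class MediationResult:
    """Total mediation effect of one distal variant with permutation p."""

    variant: str
    mediators: list[str]
    tme: float
    total_effect: float
    direct_effect: float
    p: float
    flag: str = ""


def adjusted_r2(r2: float, n: int, nu: int = 1) -> float:
    """McNemar-adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - nu - 1).

    ``nu`` is 1 because the R^2 is computed between observed and predicted
    expression only.
    """
    if n <= nu + 1:
        raise ValueError(f"n must exceed nu + 1 = {nu + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - nu - 1)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd


@dataclass
class LocalFit:
    weights: np.ndarray      # per standardized-dosage column
    intercept: float
    method: str
    null: bool = False       # all-zero weight vector


def fit_local_model(
    y: np.ndarray,
    X: np.ndarray,
    method: str = "elastic_net",
    seed: int = 0,
    n_alphas: int = 20,
    inner_folds: int = 5,
) -> LocalFit:
    """Sparse or ridge-equivalent SNP model of an intensity on cis dosages.

    ``elastic_net``: mixing fixed at 0.5, penalty chosen by inner CV.
    ``lmm``: best linear unbiased prediction from a single-GRM mixed model
    (h2 estimated by REML, weights from the ridge representation of BLUP).
    Weights are on the standardized-dosage scale.
    """
    y = np.asarray(y, dtype=float)
    Z, _, sd = _standardize(np.asarray(X, dtype=float))
    n, m = Z.shape
    if method == "elastic_net":
        cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        enet = ElasticNetCV(l1_ratio=0.5, alphas=n_alphas, cv=cv,
                            max_iter=5000, random_state=seed)
        with np.errstate(all="ignore"):
            enet.fit(Z, y)
        w = enet.coef_.copy()
        w[sd == 0] = 0.0
        return LocalFit(weights=w, intercept=float(enet.intercept_),
                        method=method, null=not np.any(w))
    if method == "lmm":
        W = Z / np.sqrt(max(m, 1))
        grm = heritability.GRM(loadings=[W], labels=["all"],
                               variant_ids=[[str(i) for i in range(m)]])
        yc = y - y.mean()
        sdy = yc.std(ddof=1)
        est = heritability.estimate_h2(yc, grm) if n >= 50 else None
        h2 = est.h2 if est is not None and est.flag == "" else 0.1
        h2 = min(max(h2, 1e-3), 1 - 1e-3)
        lam = m * (1 - h2) / h2
        w = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ yc)
        w[sd == 0] = 0.0
        return LocalFit(weights=w, intercept=float(y.mean()),
                        method=method, null=not np.any(w))
    raise ValueError(f"unknown method {method!r}")


def _corr_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def cross_validate(y: np.ndarray, trainer, folds: int = 5, seed: int = 0) -> float:
    """Fivefold McNemar-adjusted CV R^2 of a trainer.

    ``trainer(train_idx)`` must return a callable mapping ``test_idx`` to
    predictions.  Out-of-fold predictions are pooled, squared-correlation
    R^2 between observed and predicted is computed once, then adjusted.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros(n)
    for tr, te in kf.split(np.arange(n)):
        predict = trainer(tr)
        pred[te] = predict(te)
    return adjusted_r2(_corr_r2(y, pred), n)


# ---------------------------------------------------------------------------
# helpers shared by the trainers


def _cis_columns(genotypes: GenotypeMatrix, chrom: int, pos: int,
                 window: int = CIS_WINDOW) -> np.ndarray:
    v = genotypes.variants
    mask = (v["chrom"].to_numpy() == chrom) & (np.abs(v["pos"].to_numpy() - pos) <= window)
    return np.flatnonzero(mask)


def _weights_frame(genotypes: GenotypeMatrix, cols: np.ndarray, w: np.ndarray,
                   cls: str, mediator: str | None = None) -> pd.DataFrame:
    v = genotypes.variants.iloc[cols]
    return pd.DataFrame(
        {
            "variant": v["id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "a1": v["alt"].to_numpy(),
            "a2": v["ref"].to_numpy(),
            "weight": w,
            "cls": cls,
            "mediator": mediator if mediator is not None else "",
        }
    )


def _enet_fit(y, Z, seed):
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    enet = ElasticNetCV(l1_ratio=0.5, alphas=20, cv=cv, max_iter=5000,
                        random_state=seed)
    with np.errstate(all="ignore"):
        enet.fit(Z, y)
    return enet.coef_.copy(), float(enet.intercept_)


def _gene_h2(y, genotypes, cis_cols, extra_cols=None, covariates=None):
    cols = np.asarray(cis_cols, dtype=int)
    if extra_cols is not None and len(extra_cols):
        cols = np.unique(np.concatenate([cols, np.asarray(extra_cols, dtype=int)]))
    ids = genotypes.variants["id"].to_numpy()[cols].tolist()
    grm = heritability.build_grm(genotypes, variant_ids=ids)
    return heritability.estimate_h2(y, grm, covariates)


# ---------------------------------------------------------------------------
# local-only baseline


def train_local(
    gene: str,
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    chrom: int,
    pos: int,
    covariates: pd.DataFrame | None = None,
    method: str = "elastic_net",
    window: int = CIS_WINDOW,
    seed: int = 0,
    compute_h2: bool = True,
    cv_folds: int = 5,
) -> ExpressionModel:
    """Local-only baseline: regularized regression on cis-SNPs."""
    yr, _ = residualize(np.asarray(y, dtype=float), covariates, rescale=True)
    cis = _cis_columns(genotypes, chrom, pos, window)
    Zfull = genotypes.standardized()[:, cis]

    def trainer(tr):
        fit = fit_local_model(yr[tr], genotypes.dosages[np.ix_(tr, cis)],
                              method=method, seed=seed)
        mu = genotypes.dosages[np.ix_(tr, cis)].mean(axis=0)
        sd = genotypes.dosages[np.ix_(tr, cis)].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)

        def predict(te):
            Zte = (genotypes.dosages[np.ix_(te, cis)] - mu) / sd
            return fit.intercept + Zte @ fit.weights
        return predict

    cv = cross_validate(yr, trainer, folds=cv_folds, seed=seed)
    fit = fit_local_model(yr, genotypes.dosages[:, cis], method=method, seed=seed)
    wf = _weights_frame(genotypes, cis, fit.weights, "local")
    wf = wf[wf["weight"] != 0].reset_index(drop=True)
    model = ExpressionModel(
        gene=gene, method="local", weights=wf, intercept=fit.intercept,
        cv_r2_adjusted=cv, n_train=len(yr),
        flag="null_weights" if fit.null else "",
    )
    if compute_h2:
        est = _gene_h2(yr, genotypes, cis)
        model.h2, model.h2_p = est.h2, est.p
    return model


# ---------------------------------------------------------------------------
# MeTWAS


def metwas_train(
    gene: str,
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    mediators: OmicsMatrix,
    med_assoc: pd.DataFrame,
    chrom: int,
    pos: int,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
    max_mediators: int = 5,
    window: int = CIS_WINDOW,
    seed: int = 0,
    compute_h2: bool = True,
    cv_folds: int = 5,
) -> ExpressionModel:
    """Mediator-enriched two-stage expression model.

    Stage 1 trains local SNP models of each associated mediator (FDR <
    ``fdr`` in the mediator-gene scan, strongest first, at most
    ``max_mediators``); stage 2 regresses the gene on cis-SNPs plus the
    in-sample imputed mediator intensities, then composes a single
    SNP-level weight vector (distal weight = mediator coefficient x SNP
    weight in the mediator model).  With no passing mediator the model
    falls back to the local baseline, tagged ``local_fallback``.
    """
    yr, _ = residualize(np.asarray(y, dtype=float), covariates, rescale=True)
    cis = _cis_columns(genotypes, chrom, pos, window)
    zdos = genotypes.standardized()

    hits = med_assoc[(med_assoc["feature"] == gene) & (med_assoc["q"] < fdr)]
    hits = hits.sort_values("p").head(max_mediators)
    med_ids = [m for m in hits["variant"] if m != gene]

    feats = mediators.features.set_index("id")
    stage1 = []
    for mid in med_ids:
        mrow = feats.loc[mid]
        mcis = _cis_columns(genotypes, int(mrow["chrom"]), int(mrow["pos"]), window)
        # mediator cis-SNPs overlapping the gene's own cis window stay local
        mcis = np.setdiff1d(mcis, cis)
        if len(mcis) == 0:
            continue
        mres, _ = residualize(mediators.column(mid), covariates, rescale=True)
        fit = fit_local_model(mres, genotypes.dosages[:, mcis], seed=seed)
        if fit.null:
            continue
        stage1.append((mid, mcis, fit, mres))

    if not stage1:
        model = train_local(gene, y, genotypes, chrom, pos, covariates,
                            window=window, seed=seed, compute_h2=compute_h2,
                            cv_folds=cv_folds)
        model.method = "MeTWAS"
        model.flag = "local_fallback"
        return model

    def _stage1_refit(idx):
        """Refit stage-1 mediator models on samples ``idx`` only."""
        fits = []
        for mid, mcis, _, mres in stage1:
            f = fit_local_model(mres[idx], genotypes.dosages[np.ix_(idx, mcis)], seed=seed)
            fits.append((mid, mcis, f))
        return fits

    def trainer(tr):
        fits = _stage1_refit(tr)
        cols = [zdos[np.ix_(tr, cis)]]
        for mid, mcis, f in fits:
            mu = genotypes.dosages[np.ix_(tr, mcis)].mean(axis=0)
            sd = genotypes.dosages[np.ix_(tr, mcis)].std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            cols.append(((genotypes.dosages[np.ix_(tr, mcis)] - mu) / sd) @ f.weights)
        D = np.column_stack(cols)
        coef, icept = _enet_fit(yr[tr], D, seed)

        def predict(te):
            Zc = zdos[np.ix_(te, cis)]
            out = icept + Zc @ coef[: len(cis)]
            for j, (mid, mcis, f) in enumerate(fits):
                mu = genotypes.dosages[np.ix_(tr, mcis)].mean(axis=0)
                sd = genotypes.dosages[np.ix_(tr, mcis)].std(axis=0, ddof=1)
                sd = np.where(sd > 0, sd, 1.0)
                imput = ((genotypes.dosages[np.ix_(te, mcis)] - mu) / sd) @ f.weights
                out = out + coef[len(cis) + j] * imput
            return out
        return predict

    cv = cross_validate(yr, trainer, folds=cv_folds, seed=seed)

    # full-sample fit and weight composition
    Zc = zdos[:, cis]
    imputed = np.column_stack(
        [zdos[:, mcis] @ fit.weights for _, mcis, fit, _ in stage1]
    )
    D = np.column_stack([Zc, imputed])
    coef, icept = _enet_fit(yr, D, seed)
    w_local = coef[: len(cis)]
    frames = [_weights_frame(genotypes, cis, w_local, "local")]
    med_records = []
    for j, (mid, mcis, fit, _) in enumerate(stage1):
        c = coef[len(cis) + j]
        frames.append(_weights_frame(genotypes, mcis, c * fit.weights, "distal", mid))
        med_records.append(
            {"mediator": mid, "coef": float(c),
             "snp_weights": dict(zip(genotypes.variants["id"].to_numpy()[mcis],
                                     fit.weights))}
        )
    wf = pd.concat(frames, ignore_index=True)
    wf = wf[wf["weight"] != 0].reset_index(drop=True)
    model = ExpressionModel(
        gene=gene, method="MeTWAS", weights=wf, intercept=icept,
        mediators=med_records, cv_r2_adjusted=cv, n_train=len(yr),
    )
    if compute_h2:
        extra = np.concatenate([mcis for _, mcis, _, _ in stage1])
        est = _gene_h2(yr, genotypes, cis, extra)
        model.h2, model.h2_p = est.h2, est.p
    return model


# ---------------------------------------------------------------------------
# DePMA


def compute_tme(
    x: np.ndarray,
    y: np.ndarray,
    mediator_values: np.ndarray,
    covariates: pd.DataFrame | None = None,
    B: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Total mediation effect of a distal variant with a permutation test.

    TME = total effect - direct effect, where the direct effect of the
    variant on the gene conditions on the mediator set (equivalent to the
    product-of-coefficients estimator in linear models).  The null is built
    by permuting the mediator intensity rows ``B`` times; the p-value uses
    (1 + exceedances) / (B + 1) smoothing.
    """
    import warnings

    if B < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    rng = np.random.default_rng(seed)
    xr, _ = residualize(np.asarray(x, dtype=float), covariates, rescale=False)
    yr, _ = residualize(np.asarray(y, dtype=float), covariates, rescale=False)
    M = np.asarray(mediator_values, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    Mr, _ = residualize(M, covariates, rescale=False)
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    Mc = Mr - Mr.mean(axis=0)

    total = float((xc @ yc) / (xc @ xc))
    flag = ""
    gram = Mc.T @ Mc
    cond = np.linalg.cond(gram) if gram.size else 0.0
    ridge = 0.0
    if gram.size and cond > 1e10:
        ridge = 1e-6 * np.trace(gram) / gram.shape[0]
        flag = "ridge_stabilized"

    def _direct(Mmat):
        g = Mmat.T @ Mmat
        if ridge:
            g = g + ridge * np.eye(g.shape[0])
        coef = np.linalg.solve(g, Mmat.T @ xc)
        x_perp = xc - Mmat @ coef
        denom = float(x_perp @ x_perp)
        if denom < 1e-10 * float(xc @ xc):
            # variant fully explained by the mediator set: full mediation,
            # no identifiable direct path
            return 0.0
        return float((x_perp @ yc) / denom)

    direct = _direct(Mc)
    tme = total - direct
    perms = np.empty(B)
    for b in range(B):
        Mp = Mc[rng.permutation(n)]
        d = _direct(Mp)
        perms[b] = total - d
    p = (1.0 + np.sum(np.abs(perms) >= abs(tme))) / (B + 1.0)
    return MediationResult(variant="", mediators=[], tme=tme, total_effect=total,
                           direct_effect=direct, p=float(p), flag=flag)


def depma_train(
    gene: str,
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    mediators: OmicsMatrix,
    eqtl_scan: pd.DataFrame,
    mediator_qtl_scan: pd.DataFrame,
    chrom: int,
    pos: int,
    covariates: pd.DataFrame | None = None,
    distal_p: float = 1e-6,
    fdr: float = 0.05,
    tme_alpha: float = 0.05,
    B: int = 1000,
    max_candidates: int = 25,
    window: int = CIS_WINDOW,
    seed: int = 0,
    compute_h2: bool = True,
    cv_folds: int = 5,
) -> ExpressionModel:
    """Distal-eQTL prioritization via mediation analysis.

    Candidate distal-eQTLs of the gene (scan P < ``distal_p``) that are cis
    mediator-QTLs (FDR < ``fdr``) are tested for their absolute TME; those
    with permutation P < ``tme_alpha`` enter the final regularized
    regression alongside the cis-SNPs.  With no surviving distal variant
    the model equals the local baseline, tagged.
    """
    yr, _ = residualize(np.asarray(y, dtype=float), covariates, rescale=True)
    cis = _cis_columns(genotypes, chrom, pos, window)
    zdos = genotypes.standardized()
    order = {v: i for i, v in enumerate(genotypes.variants["id"])}
    feats = mediators.features.set_index("id")

    cand = eqtl_scan[
        (eqtl_scan["feature"] == gene)
        & (eqtl_scan["cls"] == "distal")
        & (eqtl_scan["p"] < distal_p)
    ].sort_values("p").head(max_candidates)

    mq_hits = mediator_qtl_scan[(mediator_qtl_scan["q"] < fdr)
                                & (mediator_qtl_scan["cls"] == "cis")]
    med_by_variant = mq_hits.groupby("variant")["feature"].agg(list)

    rng = np.random.default_rng(seed)
    selected_cols, mediation = [], []
    for _, row in cand.iterrows():
        v = row["variant"]
        meds = med_by_variant.get(v, [])
        meds = [m for m in meds if m != gene]
        if not meds:
            continue
        mcols = [int(np.flatnonzero(feats.index == m)[0]) for m in meds]
        res = compute_tme(
            genotypes.dosages[:, order[v]], yr, mediators.values[:, mcols],
            covariates=None, B=B, seed=int(rng.integers(2**31 - 1)),
        )
        res.variant = v
        res.mediators = meds
        mediation.append(res)
        if res.p < tme_alpha:
            selected_cols.append(order[v])

    if not selected_cols:
        model = train_local(gene, y, genotypes, chrom, pos, covariates,
                            window=window, seed=seed, compute_h2=compute_h2,
                            cv_folds=cv_folds)
        model.method = "DePMA"
        model.flag = "local_fallback"
        model.mediators = [vars(m) for m in mediation]
        return model

    selected_cols = np.asarray(sorted(set(selected_cols)), dtype=int)
    all_cols = np.concatenate([cis, selected_cols])

    def trainer(tr):
        fit = fit_local_model(yr[tr], genotypes.dosages[np.ix_(tr, all_cols)], seed=seed)
        mu = genotypes.dosages[np.ix_(tr, all_cols)].mean(axis=0)
        sd = genotypes.dosages[np.ix_(tr, all_cols)].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)

        def predict(te):
            Zte = (genotypes.dosages[np.ix_(te, all_cols)] - mu) / sd
            return fit.intercept + Zte @ fit.weights
        return predict

    cv = cross_validate(yr, trainer, folds=cv_folds, seed=seed)
    fit = fit_local_model(yr, genotypes.dosages[:, all_cols], seed=seed)
    wf_l = _weights_frame(genotypes, cis, fit.weights[: len(cis)], "local")
    wf_d = _weights_frame(genotypes, selected_cols, fit.weights[len(cis):], "distal")
    wf = pd.concat([wf_l, wf_d], ignore_index=True)
    wf = wf[wf["weight"] != 0].reset_index(drop=True)
    model = ExpressionModel(
        gene=gene, method="DePMA", weights=wf, intercept=fit.intercept,
        mediators=[vars(m) for m in mediation], cv_r2_adjusted=cv,
        n_train=len(yr),
    )
    if compute_h2:
        est = _gene_h2(yr, genotypes, cis, selected_cols)
        model.h2, model.h2_p = est.h2, est.p
    return model


def train_gene(method: str, *args, **kwargs) -> ExpressionModel:
    """Dispatch to :func:`train_local`, :func:`metwas_train` or :func:`depma_train`."""
    table = {"local": train_local, "metwas": metwas_train, "depma": depma_train}
    if method not in table:
        raise ValueError(f"method must be one of {sorted(table)}")
    return table[method](*args, **kwargs)
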