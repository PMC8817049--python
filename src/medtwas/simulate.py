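"""Synthetic multi-omic cohort generation.

Emulates the data a placental (or any bulk-tissue) mediator-enriched TWAS
needs: LD-block genotypes for an eQTL-training cohort, an independent GWAS
cohort and an LD reference panel; mediator intensities (regulatory-protein
gene expression, miRNA expression, CpG methylation M-values) with cis-QTLs;
gene expression with a local plus distally-mediated heritable architecture;
and GWAS summary statistics for a trait that loads on the genes' genetic
values.

The genotype model is a block-diagonal latent-Gaussian (AR(1) within block)
thresholded to Hardy-Weinberg dosages, so expected LD has a closed form and
blocks are exactly independent.  Each LD block lives on its own chromosome,
so any two features on different blocks are distal (trans) to each other and
all variants of a block are cis (<= 1 Mb) to a feature placed on it.

Every generator is a pure function of (config, seed): the same inputs give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigError",
    "AlignmentError",
    "SimConfig",
    "GenotypeMatrix",
    "OmicsMatrix",
    "TruthLedger",
    "simulate_genotypes",
    "simulate_mediators",
    "simulate_expression",
    "simulate_gwas",
    "simulate_cohort",
    "simulate_gene_zscores",
    "beta_value",
    "m_value",
    "make_covariates",
    "write_dosage_tsv",
    "write_features_tsv",
    "write_sumstats_tsv",
]

#: base-pair spacing between adjacent variants in a block
BP_SPACING = 1_000

MEDIATOR_KINDS = ("regulatory_protein", "mirna", "cpg")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class AlignmentError(ValueError):
    """Variant panels do not match between cohorts."""


@dataclass
class SimConfig:
    """Configuration of a synthetic multi-omic study.

    Defaults describe the study conditions the package is designed around:
    a small eQTL-training cohort (n=300, mirroring a birth-cohort study), a
    large independent GWAS cohort, and a reference panel of a few hundred
    samples for LD estimation (1000 Genomes-like).  Per-gene expression
    heritability defaults (0.2 local + 0.2 distally mediated) give a total
    of 0.4, in line with reported mean SNP-heritability of placental
    expression (~0.39).
    """

    n_train: int = 300
    n_gwas: int = 10_000
    n_ref: int = 500
    n_blocks: int | None = None          # default: one block per feature
    variants_per_block: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.7
    n_genes: int = 10
    n_mediators: int = 10
    h2_local: float = 0.2
    h2_distal: float = 0.2
    h2_mediator: float = 0.4
    mediation_fraction: float = 0.5
    qtl_per_mediator: tuple[int, int] = (1, 3)
    local_per_gene: tuple[int, int] = (1, 3)
    mediators_per_gene: int = 1
    trait_h2ge: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks is None:
            self.n_blocks = self.n_genes + self.n_mediators
        self.validate()

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for name in ("h2_local", "h2_distal", "h2_mediator", "mediation_fraction", "trait_h2ge"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.h2_local + self.h2_distal > 1.0:
            raise ConfigError("h2_local + h2_distal must be <= 1")
        if self.h2_distal > 0 and self.h2_mediator > 0 and \
                self.h2_local + self.h2_distal / self.h2_mediator > 1.0:
            raise ConfigError(
                "h2_distal / h2_mediator (variance routed through mediator "
                "intensity) plus h2_local exceeds 1; lower h2_distal or raise h2_mediator"
            )
        for name in ("n_train", "n_gwas", "n_ref", "n_blocks", "variants_per_block",
                     "n_genes", "n_mediators"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        # one block per gene and per mediator is required only when those
        # features are actually simulated; simulate_mediators checks it


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Dosages count copies of the alternate (minor at generation time) allele,
    in [0, 2].  ``variants`` carries id, chrom, pos (1-based), ref, alt and
    the allele frequency recomputed from the dosages.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (monomorphic columns set to 0)."""
        d = self.dosages
        mu = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        z = np.zeros_like(d, dtype=float)
        ok = sd > 0
        z[:, ok] = (d[:, ok] - mu[ok]) / sd[ok]
        return z

    def columns(self, variant_ids) -> np.ndarray:
        order = {v: i for i, v in enumerate(self.variants["id"])}
        cols = [order[v] for v in variant_ids]
        return self.dosages[:, cols]

    def validate(self) -> None:
        d = self.dosages
        if np.isnan(d).any():
            raise ValueError("missing dosages")
        if d.min() < 0 or d.max() > 2:
            raise ValueError("dosages outside [0, 2]")
        maf = d.mean(axis=0) / 2.0
        if not np.allclose(maf, self.variants["maf"].to_numpy(), atol=1e-12):
            raise ValueError("stored maf does not match dosages")
        for _, grp in self.variants.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions not increasing within chromosome")


@dataclass
class OmicsMatrix:
    """Samples x features intensity matrix (expression or methylation)."""

    values: np.ndarray
    features: pd.DataFrame  # id, kind, chrom, pos
    samples: list[str]
    scaled: bool = True

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature_id: str) -> np.ndarray:
        j = int(np.flatnonzero(self.features["id"].to_numpy() == feature_id)[0])
        return self.values[:, j]


@dataclass
class TruthLedger:
    """Ground truth of a simulated cohort, for recovery tests.

    ``mediators[id]`` records the cis-QTL variant ids, standardized effect
    sizes and realized cis-h2 of each mediator.  ``genes[id]`` records local
    causal variants/effects, mediator channels (mediator id -> intensity
    coefficient), the distal causal variants reachable through those
    mediators, realized variance components, and the gene-trait effect set
    by :func:`simulate_gwas`.
    """

    mediators: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)

    def distal_variants(self, gene: str) -> list[str]:
        out: list[str] = []
        for med in self.genes[gene]["mediators"]:
            out.extend(self.mediators[med]["qtl_ids"])
        return out

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        Path(path).write_text(json.dumps(_clean(dataclasses.asdict(self)), indent=1))


# ---------------------------------------------------------------------------
# genotypes


def _variant_table(config: SimConfig, dosages: np.ndarray) -> pd.DataFrame:
    rows = []
    for b in range(config.n_blocks):
        for v in range(config.variants_per_block):
            rows.append(
                (f"snp_{b}_{v}", b + 1, 1 + v * BP_SPACING, "A", "G")
            )
    tab = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    tab["maf"] = dosages.mean(axis=0) / 2.0
    return tab


def simulate_genotypes(config: SimConfig, n: int, seed: int | None = None) -> GenotypeMatrix:
    """Draw ``n`` samples of LD-block dosage genotypes.

    Within a block, each haplotype is an AR(1) latent Gaussian with adjacent
    correlation ``ld_rho``, thresholded at the Gaussian quantile of the
    variant's MAF; the dosage is the sum of two independent haplotypes, so
    variants are in Hardy-Weinberg equilibrium and blocks are independent.
    """
    config.validate()
    if n <= 0:
        raise ConfigError("n must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    B, V = config.n_blocks, config.variants_per_block
    rho = config.ld_rho
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=B * V)
    thresh = stats.norm.ppf(maf)

    dosages = np.empty((n, B * V))
    for b in range(B):
        hap_sum = np.zeros((n, V))
        for _ in range(2):
            latent = np.empty((n, V))
            latent[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, V - 1)) if V > 1 else None
            for v in range(1, V):
                latent[:, v] = rho * latent[:, v - 1] + np.sqrt(1 - rho**2) * innov[:, v - 1]
            hap_sum += latent < thresh[b * V : (b + 1) * V]
        dosages[:, b * V : (b + 1) * V] = hap_sum

    variants = _variant_table(config, dosages)
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# mediators and gene expression


def _block_cols(config: SimConfig, block: int) -> slice:
    V = config.variants_per_block
    return slice(block * V, (block + 1) * V)


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x) if target_var == 0 else x
    return x * np.sqrt(target_var) / sd


def simulate_mediators(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    seed: int | None = None,
    truth: TruthLedger | None = None,
) -> tuple[OmicsMatrix, TruthLedger]:
    """Simulate mediator intensities with cis-QTL architecture.

    Each mediator occupies its own LD block (blocks ``n_genes ...``), has
    1-3 cis-QTLs drawn from that block, and cis-heritability
    ``config.h2_mediator``.  Kinds cycle through regulatory-protein genes,
    miRNAs and CpG sites; CpG intensities are emitted directly on the
    M-value scale (the scale used for statistics), all scaled to zero mean
    and unit variance.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    truth = truth or TruthLedger()
    if config.n_blocks < config.n_genes + config.n_mediators:
        raise ConfigError("not enough LD blocks for requested mediators")

    n = genotypes.n_samples
    zdos = genotypes.standardized()
    values = np.empty((n, config.n_mediators))
    feats = []
    lo_q, hi_q = config.qtl_per_mediator
    for m in range(config.n_mediators):
        block = config.n_genes + m
        cols = np.arange(*_block_cols(config, block).indices(genotypes.n_variants))
        k = int(rng.integers(lo_q, hi_q + 1))
        qtl_cols = np.sort(rng.choice(cols, size=k, replace=False))
        effects = rng.standard_normal(k)
        g = _scale_to_var(zdos[:, qtl_cols] @ effects, config.h2_mediator)
        # rescale recorded effects to match the realized genetic component
        raw_sd = (zdos[:, qtl_cols] @ effects).std()
        scale = np.sqrt(config.h2_mediator) / raw_sd if raw_sd > 0 else 0.0
        e = rng.standard_normal(n)
        e = e - e.mean()
        e = _scale_to_var(e, 1.0 - config.h2_mediator)
        y = g - g.mean() + e
        sd_y = y.std()
        if sd_y > 0:
            y = y / sd_y
        values[:, m] = y
        kind = MEDIATOR_KINDS[m % len(MEDIATOR_KINDS)]
        mid = f"med_{m}"
        pos = 1 + (config.variants_per_block // 2) * BP_SPACING
        feats.append((mid, kind, block + 1, pos))
        qtl_ids = genotypes.variants["id"].to_numpy()[qtl_cols].tolist()
        truth.mediators[mid] = {
            "block": block,
            "kind": kind,
            "qtl_ids": qtl_ids,
            "effects": (effects * scale / (sd_y if sd_y > 0 else 1.0)).tolist(),
            "h2": float(np.var(g) / (np.var(g + e) or 1.0)),
        }
    features = pd.DataFrame(feats, columns=["id", "kind", "chrom", "pos"])
    om = OmicsMatrix(values=values, features=features, samples=list(genotypes.samples))
    return om, truth


def simulate_expression(
    genotypes: GenotypeMatrix,
    mediators: OmicsMatrix,
    config: SimConfig,
    truth: TruthLedger,
    seed: int | None = None,
) -> tuple[OmicsMatrix, TruthLedger]:
    """Simulate gene expression with local + distally mediated architecture.

    A gene's expression is: local-SNP effects (variance ``h2_local``) plus,
    for a ``mediation_fraction`` of genes, mediator-intensity effects sized
    so the *genetic* variance flowing through each mediator's cis-QTLs is
    ``h2_distal``, plus independent noise.  Distal genetic effects reach a
    mediated gene only through mediator intensities; non-mediated genes have
    purely local architecture.
    """
    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    if config.h2_local + config.h2_distal > 1.0:
        raise ConfigError("h2_local + h2_distal must be <= 1")
    n = genotypes.n_samples
    zdos = genotypes.standardized()
    med_ids = mediators.features["id"].tolist()
    values = np.empty((n, config.n_genes))
    feats = []
    lo_c, hi_c = config.local_per_gene
    n_mediated = int(round(config.mediation_fraction * config.n_genes))
    for g_i in range(config.n_genes):
        block = g_i
        cols = np.arange(*_block_cols(config, block).indices(genotypes.n_variants))
        k = int(rng.integers(lo_c, hi_c + 1))
        loc_cols = np.sort(rng.choice(cols, size=k, replace=False))
        eff = rng.standard_normal(k)
        g_loc_raw = zdos[:, loc_cols] @ eff
        g_loc = _scale_to_var(g_loc_raw - g_loc_raw.mean(), config.h2_local)
        loc_scale = (np.sqrt(config.h2_local) / g_loc_raw.std()) if g_loc_raw.std() > 0 else 0.0

        mediated = g_i < n_mediated and config.h2_distal > 0 and config.n_mediators > 0
        med_channels: dict[str, float] = {}
        med_part = np.zeros(n)
        if mediated:
            picks = rng.choice(config.n_mediators, size=min(config.mediators_per_gene,
                                                            config.n_mediators), replace=False)
            # variance routed through each mediator's genetic component is
            # h2_distal / n_channels; intensity coefficient gamma satisfies
            # gamma^2 * h2_mediator = that share (intensity has unit variance)
            share = config.h2_distal / len(picks)
            for p in picks:
                gamma = np.sqrt(share / config.h2_mediator) * rng.choice([-1.0, 1.0])
                med_channels[med_ids[p]] = float(gamma)
                med_part = med_part + gamma * mediators.values[:, p]

        resid_var = 1.0 - config.h2_local - (np.var(med_part) if mediated else 0.0)
        resid_var = max(resid_var, 0.0)
        e = rng.standard_normal(n)
        e = _scale_to_var(e - e.mean(), resid_var)
        y = g_loc + med_part + e
        var_y = np.var(y) or 1.0
        sd_y = np.sqrt(var_y)
        values[:, g_i] = (y - y.mean()) / sd_y

        gid = f"gene_{g_i}"
        pos = 1 + (config.variants_per_block // 2) * BP_SPACING
        feats.append((gid, "gene", block + 1, pos))
        truth.genes[gid] = {
            "block": block,
            "local_ids": genotypes.variants["id"].to_numpy()[loc_cols].tolist(),
            "local_effects": (eff * loc_scale / sd_y).tolist(),
            "mediators": {m: c / sd_y for m, c in med_channels.items()},
            "h2_local": float(np.var(g_loc) / var_y),
            "h2_distal": float(
                sum(
                    (c / sd_y) ** 2 * truth.mediators[m]["h2"]
                    for m, c in med_channels.items()
                )
            ),
            "trait_beta": 0.0,
        }
    features = pd.DataFrame(feats, columns=["id", "kind", "chrom", "pos"])
    om = OmicsMatrix(values=values, features=features, samples=list(genotypes.samples))
    return om, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics


def gene_genetic_values(
    genotypes: GenotypeMatrix, truth: TruthLedger
) -> tuple[np.ndarray, list[str]]:
    """Genetic value of each gene in an arbitrary cohort on the same panel.

    Local effects act directly; mediated effects act through the genetic
    component of each mediator channel (the mediator's environmental noise
    is cohort-specific and is not part of the gene's genetic value).
    """
    zdos = genotypes.standardized()
    vindex = {v: i for i, v in enumerate(genotypes.variants["id"])}
    genes = list(truth.genes)
    G = np.zeros((genotypes.n_samples, len(genes)))
    for j, gid in enumerate(genes):
        rec = truth.genes[gid]
        try:
            loc = [vindex[v] for v in rec["local_ids"]]
        except KeyError as err:
            raise AlignmentError(f"variant {err} absent from cohort panel") from err
        g = zdos[:, loc] @ np.asarray(rec["local_effects"])
        for med, gamma in rec["mediators"].items():
            mrec = truth.mediators[med]
            qtl = [vindex[v] for v in mrec["qtl_ids"]]
            g = g + gamma * (zdos[:, qtl] @ np.asarray(mrec["effects"]))
        G[:, j] = g
    return G, genes


def marginal_zscores(dosages: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Per-variant Wald Z from simple regression of trait on dosage."""
    n = dosages.shape[0]
    x = dosages - dosages.mean(axis=0)
    y = trait - trait.mean()
    sx = np.sqrt((x**2).sum(axis=0))
    sy = np.sqrt((y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ y) / (sx * sy)
    r = np.clip(np.nan_to_num(r), -0.999999, 0.999999)
    return r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)


def simulate_gwas(
    genotypes_gwas: GenotypeMatrix,
    truth: TruthLedger,
    config: SimConfig,
    seed: int | None = None,
    trait_h2ge: float | None = None,
    return_trait: bool = False,
):
    """Simulate a GWAS trait and per-variant summary statistics.

    The trait is a weighted sum of gene genetic values (weights drawn
    standard-normal and rescaled so the genetic values explain
    ``trait_h2ge`` of trait variance) plus Gaussian environment.  Marginal
    Z-scores come from per-variant simple regression; alleles and sample
    size are recorded for downstream harmonization.
    """
    rng = np.random.default_rng((config.seed + 3) if seed is None else seed)
    h2ge = config.trait_h2ge if trait_h2ge is None else trait_h2ge
    G, genes = gene_genetic_values(genotypes_gwas, truth)
    n = genotypes_gwas.n_samples
    alpha = rng.standard_normal(len(genes))
    genetic = G @ alpha
    genetic = _scale_to_var(genetic - genetic.mean(), h2ge)
    gsd = (G @ alpha).std()
    scale = np.sqrt(h2ge) / gsd if gsd > 0 else 0.0
    for gid, a in zip(genes, alpha):
        truth.genes[gid]["trait_beta"] = float(a * scale)
    env = rng.standard_normal(n)
    env = _scale_to_var(env - env.mean(), 1.0 - h2ge)
    trait = genetic + env

    z = marginal_zscores(genotypes_gwas.dosages, trait)
    ss = genotypes_gwas.variants[["id", "chrom", "pos"]].copy()
    ss["a1"] = genotypes_gwas.variants["alt"]
    ss["a2"] = genotypes_gwas.variants["ref"]
    ss["z"] = z
    ss["n"] = n
    ss = ss.rename(columns={"id": "snp"})
    if return_trait:
        return ss, trait
    return ss


# ---------------------------------------------------------------------------
# convenience bundle


def make_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Small covariate table (sex, maternal age, two genotype PC stand-ins).

    The covariates carry no true effect in the generative model; they are
    provided so scans and trainers exercise covariate adjustment.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n).astype(float),
            "maternal_age": rng.normal(30, 5, n),
            "pc1": rng.standard_normal(n),
            "pc2": rng.standard_normal(n),
        },
        index=[f"s{i}" for i in range(n)],
    )


@dataclass
class CohortBundle:
    """Everything a full pipeline run needs, from one config."""

    config: SimConfig
    genotypes: GenotypeMatrix
    mediators: OmicsMatrix
    expression: OmicsMatrix
    covariates: pd.DataFrame
    gwas_genotypes: GenotypeMatrix
    ref_genotypes: GenotypeMatrix
    sumstats: pd.DataFrame
    truth: TruthLedger


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate training cohort, GWAS summary statistics and LD reference."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)
    geno = simulate_genotypes(config, config.n_train, seed=int(seeds[0]))
    med, truth = simulate_mediators(geno, config, seed=int(seeds[1]))
    expr, truth = simulate_expression(geno, med, config, truth, seed=int(seeds[2]))
    covs = make_covariates(config.n_train, seed=int(seeds[3]))
    gwas_geno = simulate_genotypes(config, config.n_gwas, seed=int(seeds[4]))
    ref_geno = simulate_genotypes(config, config.n_ref, seed=int(seeds[5]))
    ss = simulate_gwas(gwas_geno, truth, config, seed=int(seeds[4]) + 1)
    return CohortBundle(config, geno, med, expr, covs, gwas_geno, ref_geno, ss, truth)


# ---------------------------------------------------------------------------
# gene-level summary statistics (for expression-mediated heritability work)


def simulate_gene_zscores(
    m_genes: int,
    n_gwas: int,
    h2ge: float,
    block: int = 10,
    rho: float = 0.5,
    shared_fraction: float | None = None,
    seed: int = 0,
):
    """Gene-level TWAS Z-scores under an LD-score regression model.

    Genes have a block-AR(1) predicted-expression correlation matrix R
    (blocks of ``block`` genes, neighbour correlation ``rho``); per-gene
    expression-trait effects are N(0, h2ge/M) so that
    E[Z_g^2] = 1 + (N * l_g / M) * h2ge with l_g the gene LD score.

    Returns ``(z, l, R)`` or, when ``shared_fraction`` is given, a second
    trait whose gene effects share that fraction of variance with the first
    (``(z1, z2, l, R)``); the true expression-level genetic correlation is
    then ``sqrt(shared_fraction)`` rescaled appropriately.
    """
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(m_genes / block))
    idx = np.arange(block)
    Rb = rho ** np.abs(idx[:, None] - idx[None, :])
    Lb = np.linalg.cholesky(Rb)
    l_block = (Rb**2).sum(axis=1)

    def draw(alpha):
        z = np.empty(m_genes)
        for b in range(n_blocks):
            s = slice(b * block, min((b + 1) * block, m_genes))
            k = s.stop - s.start
            noise = Lb[:k, :k] @ rng.standard_normal(k)
            z[s] = np.sqrt(n_gwas) * (Rb[:k, :k] @ alpha[s]) + noise
        return z

    l = np.tile(l_block, n_blocks)[:m_genes]
    sd_a = np.sqrt(h2ge / m_genes)
    a1 = rng.standard_normal(m_genes) * sd_a
    if shared_fraction is None:
        return draw(a1), l, Rb
    w = np.sqrt(shared_fraction)
    a2 = w * a1 + np.sqrt(1 - shared_fraction) * rng.standard_normal(m_genes) * sd_a
    return draw(a1), draw(a2), l, Rb


# ---------------------------------------------------------------------------
# methylation scale transforms


def beta_value(m_int, u_int):
    """Methylation beta-value M / (U + M + 100) from allele intensities."""
    m_arr = np.asarray(m_int, dtype=float)
    u_arr = np.asarray(u_int, dtype=float)
    if (m_arr < 0).any() or (u_arr < 0).any():
        raise ValueError("intensities must be non-negative")
    out = m_arr / (u_arr + m_arr + 100.0)
    return out if out.ndim else float(out)


def m_value(beta):
    """Base-2 logit transform of a beta-value: log2(beta / (1 - beta))."""
    b = np.asarray(beta, dtype=float)
    if (b <= 0).any() or (b >= 1).any():
        raise ValueError("beta must be in the open interval (0, 1)")
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# plain-text writers


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.dosages, index=genotypes.samples,
                      columns=genotypes.variants["id"])
    df.to_csv(path, sep="\t", index_label="sample")


def write_features_tsv(omics: OmicsMatrix, path_values, path_features) -> None:
    pd.DataFrame(omics.values, index=omics.samples,
                 columns=omics.features["id"]).to_csv(path_values, sep="\t",
                                                      index_label="sample")
    omics.features.to_csv(path_features, sep="\t", index=False)


def write_sumstats_tsv(sumstats: pd.DataFrame, path) -> None:
    cols = {"snp": "SNP", "chrom": "CHR", "pos": "POS",
            "a1": "A1", "a2": "A2", "z": "Z", "n": "N"}
    sumstats.rename(columns=cols)[list(cols.values())].to_csv(path, sep="\t", index=False)
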