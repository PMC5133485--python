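"""Synthetic genotype/phenotype generator and size/power harness.

The generator emulates the statistical structure of an unrelated-sample
exome study of two correlated, log-transformed blood-pressure phenotypes:
n = 1851 individuals, rare variants (MAF uniform on [0.001, 0.05], so many
singletons and doubletons appear at the lower end), age and sex covariates,
and a residual cross-phenotype correlation of 0.542.  Genotypes are
independent Binomial(2, MAF) draws — no linkage disequilibrium — which is
sufficient for size/power evaluation of the test statistics.

Phenotypes follow the generating model used by the tests themselves:

    Y_i = alpha_0 + (I_K (x) X_i') alpha + (I_K (x) G_i') beta + eps_i

with causal-variant effects drawn multivariate normal with common
cross-phenotype correlation ``effect_corr`` and residuals multivariate
normal with unit variances and correlation ``phenotype_corr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeBlock, VariantInfo
from . import preprocess
from .association import EffectCovarianceSpec, adjusted_min_p, murat_pvalue, skat_pvalue_from_fit
from .null_model import MultivariateLinearModel

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset", "size_power_harness"]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic data generator.

    Defaults are the structure of the motivating study: 1851 unrelated
    samples, two phenotypes on the natural-log blood-pressure scale with
    residual correlation 0.542, age ~ N(40, 10^2) and sex ~ Bernoulli(0.5)
    covariates, and rare variants with MAF uniform on [0.001, 0.05].
    Intercepts default to (ln 120, ln 75) — typical SBP/DBP on the log
    mmHg scale — and the covariate effects to +0.002/year of age and
    +0.03 for male sex on each log phenotype.
    """

    n_samples: int = 1851
    n_variants: int = 10
    maf_range: tuple[float, float] = (0.001, 0.05)
    K: int = 2
    phenotype_corr: float = 0.542
    causal_fraction: float = 0.0
    effect_size: float = 0.0  # sd of each causal variant's effect per phenotype
    effect_corr: float = 0.0  # rho_true: cross-phenotype effect correlation
    affected_phenotypes: tuple[int, ...] | None = None  # None = all K
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    age_mean: float = 40.0
    age_sd: float = 10.0
    intercepts: tuple[float, ...] = (4.787, 4.317)  # ln 120, ln 75
    age_effect: float = 0.002
    sex_effect: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if abs(self.phenotype_corr) >= 1:
            raise ValueError("phenotype_corr must lie in (-1, 1)")
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in [0, 1]")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a GenotypeMatrix: per-variant MAF uniform on ``maf_range``,
    genotypes Binomial(2, MAF), an optional fraction of entries missing."""
    rng = _rng(cfg, 1)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_variants)
    dos = rng.binomial(2, mafs[None, :], size=(cfg.n_samples, cfg.n_variants)).astype(float)
    if cfg.missing_fraction > 0:
        miss = rng.random(dos.shape) < cfg.missing_fraction
        # never blank out a whole variant
        for j in range(cfg.n_variants):
            if miss[:, j].all():
                miss[rng.integers(cfg.n_samples), j] = False
        dos[miss] = np.nan
    variants = []
    for j in range(cfg.n_variants):
        col = dos[:, j]
        variants.append(
            VariantInfo(
                chromosome="1",
                position=10_000 * (j + 1),
                variant_id=f"var_1_{10_000 * (j + 1)}",
                ref_allele="A",
                alt_allele="G",
                maf=preprocess.compute_maf(col),
                n_carriers=preprocess.count_carriers(col),
                n_missing=int(np.isnan(col).sum()),
            )
        )
    samples = [f"S{i+1:05d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dos)


def _covariates(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    age = rng.normal(cfg.age_mean, cfg.age_sd, cfg.n_samples)
    sex = rng.binomial(1, 0.5, cfg.n_samples).astype(float)
    return np.column_stack([age, sex])


def simulate_phenotypes(gm: GenotypeMatrix, cfg: SimConfig) -> PhenotypeBlock:
    """Assemble phenotypes from covariates, causal-variant effects and
    correlated residuals, exactly per the generating linear model."""
    rng = _rng(cfg, 2)
    K = cfg.K
    X = _covariates(cfg, rng)
    alpha0 = np.asarray(cfg.intercepts[:K], dtype=float)
    if alpha0.size < K:
        alpha0 = np.resize(alpha0, K)
    alpha = np.tile(np.array([[cfg.age_effect], [cfg.sex_effect]]), (1, K))

    G = np.nan_to_num(gm.dosages, nan=0.0)  # causal contribution uses observed dosages
    v = G.shape[1]
    beta = np.zeros((v, K))
    n_causal = int(round(cfg.causal_fraction * v))
    if n_causal and cfg.effect_size > 0:
        causal = rng.choice(v, size=n_causal, replace=False)
        if cfg.effect_corr == 1.0:
            # perfectly correlated effects: one draw shared across phenotypes
            shared = rng.standard_normal((n_causal, 1))
            draws = np.repeat(shared, K, axis=1)
        else:
            R_eff = (1 - cfg.effect_corr) * np.eye(K) + cfg.effect_corr * np.ones((K, K))
            draws = rng.standard_normal((n_causal, K)) @ np.linalg.cholesky(R_eff).T
        beta[causal] = cfg.effect_size * draws
        if cfg.affected_phenotypes is not None:
            off = [k for k in range(K) if k not in cfg.affected_phenotypes]
            beta[:, off] = 0.0

    R_eps = (1 - cfg.phenotype_corr) * np.eye(K) + cfg.phenotype_corr * np.ones((K, K))
    eps = cfg.noise_sd * (rng.standard_normal((cfg.n_samples, K)) @ np.linalg.cholesky(R_eps).T)

    Y = alpha0[None, :] + X @ alpha + G @ beta + eps
    names = ["logSBP", "logDBP"] + [f"y{k+1}" for k in range(2, K)]
    return PhenotypeBlock(
        samples=list(gm.samples),
        Y=Y,
        X=X,
        phenotype_names=names[:K],
        covariate_names=["age", "sex"],
    )


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeBlock]:
    """Genotypes and phenotypes for one replicate region."""
    gm = simulate_genotypes(cfg)
    return gm, simulate_phenotypes(gm, cfg)


def size_power_harness(
    cfg: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("murat", "skat_adjusted"),
    resamples: int = 500,
    min_carriers: int = 0,
    spec: EffectCovarianceSpec | None = None,
) -> pd.DataFrame:
    """Empirical rejection rate per method over seeded replicate regions.

    Returns a table with one row per method: the fraction of replicates
    with p <= alpha and its exact (Clopper-Pearson) 95% interval.  All
    replicates derive deterministically from ``cfg.seed``.
    """
    from statsmodels.stats.proportion import proportion_confint

    if n_reps < 100:
        raise ValueError("use at least 100 replicates")
    spec = spec or EffectCovarianceSpec()
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    import dataclasses

    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([cfg.seed, 1000 + rep]).generate_state(1)[0] % (2**31))
        rep_cfg = dataclasses.replace(cfg, seed=rep_seed)
        gm, block = simulate_dataset(rep_cfg)
        keep = [
            j for j in range(gm.n_variants)
            if gm.variants[j].maf > 0
            and (min_carriers == 0 or gm.variants[j].n_carriers >= min_carriers)
        ]
        if not keep:
            continue
        G = np.column_stack([preprocess.impute_missing(gm.dosages[:, j]) for j in keep])
        mafs = np.array([gm.variants[j].maf for j in keep])
        fit = MultivariateLinearModel.from_block(block).fit()
        skat_ps = [
            skat_pvalue_from_fit(fit, G, mafs, phenotype=k, spec=spec)
            for k in range(block.n_phenotypes)
        ]
        for m in methods:
            if m == "murat":
                res = murat_pvalue(fit, G, mafs, spec=spec, resamples=resamples, seed=rep_cfg.seed)
                pvals[m].append(res.final_p)
            elif m == "skat_adjusted":
                pvals[m].append(adjusted_min_p(skat_ps))
            elif m.startswith("skat_"):
                k = int(m.split("_")[1])
                pvals[m].append(skat_ps[k])
            else:
                raise ValueError(f"unknown method {m!r}")
    rows = []
    for m, ps in pvals.items():
        ps = np.asarray(ps)
        hits = int((ps <= alpha).sum())
        lo, hi = proportion_confint(hits, len(ps), alpha=0.05, method="beta")
        rows.append(
            {
                "method": m,
                "n_reps": len(ps),
                "alpha": alpha,
                "rejection_rate": hits / len(ps),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
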