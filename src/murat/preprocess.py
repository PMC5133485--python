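"""Phenotype transformation and genotype quality control.

Implements the preprocessing used before rare-variant association testing:
natural-log transformation of positive phenotypes, complete-case filtering
over phenotypes and covariates, minor allele frequency (MAF) computation,
MAF-preserving mean imputation of missing genotypes, and the minimum-carrier
variant filter.

Allele-frequency arithmetic is done internally in exact rational arithmetic
so that mean imputation provably leaves the stored-allele frequency unchanged
at the last bit.  When the stored (alt) allele is the minor allele — the case
of interest for rare variants — the MAF is therefore conserved bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .containers import PhenotypeBlock

logger = logging.getLogger(__name__)

__all__ = [
    "QcConfig",
    "log_transform_phenotypes",
    "drop_incomplete_samples",
    "phenotype_correlation",
    "alt_allele_frequency",
    "compute_maf",
    "count_carriers",
    "impute_missing",
    "carrier_filter",
]


@dataclass
class QcConfig:
    """Variant/sample QC settings.

    min_carriers
        Minimum number of individuals carrying at least one copy of the
        minor allele for a variant to be tested (default 4).
    maf_upper
        Upper MAF bound applied only when a rare-only region filter is
        requested (default 0.05, i.e. "rare" = MAF below 5%).
    log_transform
        Phenotype names to natural-log transform.
    """

    min_carriers: int = 4
    maf_upper: float = 0.05
    log_transform: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")
        if not (0.0 < self.maf_upper <= 0.5):
            raise ValueError("maf_upper must lie in (0, 0.5]")


def log_transform_phenotypes(block: PhenotypeBlock, which: list[str]) -> PhenotypeBlock:
    """Replace the named phenotype columns by their natural logarithm.

    Raises ValueError naming the first offending sample/phenotype if a
    selected value is not strictly positive (missing values pass through).
    """
    Y = block.Y.copy()
    for name in which:
        if name not in block.phenotype_names:
            raise KeyError(f"unknown phenotype {name!r}")
        j = block.phenotype_names.index(name)
        col = Y[:, j]
        bad = np.where(~np.isnan(col) & (col <= 0))[0]
        if bad.size:
            raise ValueError(
                f"non-positive value for phenotype {name!r} in sample "
                f"{block.samples[bad[0]]!r}: cannot log-transform"
            )
        Y[:, j] = np.log(col)
    return PhenotypeBlock(
        samples=list(block.samples),
        Y=Y,
        X=block.X.copy(),
        phenotype_names=list(block.phenotype_names),
        covariate_names=list(block.covariate_names),
    )


def drop_incomplete_samples(block: PhenotypeBlock) -> PhenotypeBlock:
    """Remove every sample with any missing phenotype or covariate.

    The complete-case rule covers covariates as well as phenotypes: the
    covariate-only null regression needs every retained sample to have a
    full design row.
    """
    keep = block.complete_mask()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d incomplete samples (of %d)", n_drop, len(keep))
    if not keep.any():
        raise ValueError("no samples remain after complete-case filtering")
    return PhenotypeBlock(
        samples=[s for s, k in zip(block.samples, keep) if k],
        Y=block.Y[keep],
        X=block.X[keep],
        phenotype_names=list(block.phenotype_names),
        covariate_names=list(block.covariate_names),
    )


def phenotype_correlation(block: PhenotypeBlock, a: str, b: str) -> float:
    """Pearson correlation between two phenotype columns."""
    ia = block.phenotype_names.index(a)
    ib = block.phenotype_names.index(b)
    x, y = block.Y[:, ia], block.Y[:, ib]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance column")
    return float(np.corrcoef(x, y)[0, 1])


def _exact_mean(dosages: np.ndarray) -> Fraction:
    """Exact rational mean of the observed (non-NaN) dosages.

    Every float64 is an exact rational, so grouping by distinct value and
    accumulating with Fractions yields the true mean with no rounding; the
    single rounding happens only when the caller converts to float.
    """
    obs = dosages[~np.isnan(dosages)]
    if obs.size == 0:
        raise ValueError("all dosage entries missing")
    vals, counts = np.unique(obs, return_counts=True)
    total = sum(Fraction(float(v)) * int(c) for v, c in zip(vals, counts))
    return total / int(obs.size)


def alt_allele_frequency(dosages: np.ndarray) -> float:
    """Frequency of the stored (alt) allele among observed genotypes."""
    return float(_exact_mean(np.asarray(dosages, dtype=float)) / 2)


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of a dosage column, in [0, 0.5].

    The allele frequency of the stored allele is computed in exact rational
    arithmetic and folded (min(f, 1-f)) before the single conversion to
    float, so repeated calls on mean-imputed data reproduce the original
    value exactly whenever the stored allele is the minor one.
    """
    f = _exact_mean(np.asarray(dosages, dtype=float)) / 2
    return float(min(f, 1 - f))


def count_carriers(dosages: np.ndarray) -> int:
    """Number of individuals with observed minor-allele dosage > 0.

    Counted on observed genotypes (pre-imputation); a homozygous carrier
    counts once.  If the alt allele is the major allele the minor allele is
    ref, and a carrier is anyone with dosage < 2.
    """
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        return 0
    if _exact_mean(d) / 2 <= Fraction(1, 2):
        return int((obs > 0).sum())
    return int((obs < 2).sum())


def impute_missing(dosages: np.ndarray, maf: float | None = None) -> np.ndarray:
    """Fill missing dosages with the expected dosage given the observed MAF.

    The fill value is ``2 * alt_allele_frequency`` of the observed entries
    (equal to ``2*maf`` on the minor-allele scale, folded back to the stored
    allele's scale when alt is major), so the allele frequency recomputed on
    the imputed column equals the pre-imputation frequency exactly.

    ``maf`` is accepted for interface symmetry and validated against the
    observed data when given.
    """
    d = np.asarray(dosages, dtype=float)
    miss = np.isnan(d)
    if not miss.any():
        return d.copy()
    f = _exact_mean(d) / 2
    if maf is not None:
        expected = float(min(f, 1 - f))
        if not np.isclose(maf, expected, rtol=0, atol=1e-12):
            raise ValueError(
                f"supplied maf {maf} does not match observed maf {expected}"
            )
    fill = 2.0 * float(f)
    out = d.copy()
    out[miss] = fill
    return out


def carrier_filter(dosages: np.ndarray, min_carriers: int) -> bool:
    """True iff the variant has at least ``min_carriers`` carriers."""
    return count_carriers(dosages) >= int(min_carriers)
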