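"""Scan orchestration: run MURAT + SKAT over a list of regions.

Produces one row per region with the per-phenotype SKAT p-values, the
Bonferroni-over-phenotypes adjusted minimum, and the MURAT final p-value,
together with the Bonferroni family-wise threshold for the scan and
Q-Q plot data for null-calibration checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import EffectCovarianceSpec, adjusted_min_p, murat_pvalue, skat_pvalue_from_fit
from .containers import GenotypeMatrix, PhenotypeBlock
from .null_model import MultivariateLinearModel
from .regions import RegionSet

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "ScanReport", "bonferroni_threshold", "run_scan", "qq_data"]


@dataclass
class ScanConfig:
    """Settings shared across a scan."""

    spec: EffectCovarianceSpec | None = None
    resamples: int = 1000
    seed: int = 0
    alpha: float = 0.05


@dataclass
class ScanReport:
    """Result table plus the multiple-testing summary for one scan."""

    rows: pd.DataFrame
    n_tests: int
    bonferroni_threshold: float
    alpha: float = 0.05


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def run_scan(
    gm: GenotypeMatrix,
    block: PhenotypeBlock,
    regions: list[RegionSet],
    config: ScanConfig | None = None,
) -> ScanReport:
    """Test every region with MURAT and per-phenotype SKAT.

    Inputs are assumed preprocessed: complete-case samples, identical
    sample order in ``gm`` and ``block``, missing genotypes imputed and
    carrier-filtered variants.  Regions whose genotype submatrix is
    degenerate after residualization are flagged (NaN p-values), not fatal.
    Rows are sorted by MURAT p ascending.
    """
    config = config or ScanConfig()
    if not regions:
        raise ValueError("empty region list: nothing to test")
    if gm.samples != block.samples:
        raise ValueError("genotype and phenotype samples differ; align first")
    spec = config.spec or EffectCovarianceSpec()

    fit = MultivariateLinearModel.from_block(block).fit()
    mafs = gm.mafs
    K = block.n_phenotypes
    rows = []
    for i, region in enumerate(regions):
        idx = region.variant_indices
        if not idx:
            raise ValueError(f"region {region.name} has no variants")
        G = gm.dosages[:, idx]
        m = mafs[list(idx)]
        row: dict = {
            "region": region.name,
            "chromosome": region.chromosome,
            "n_snps": len(idx),
        }
        if len(idx) == 1:
            row["maf"] = float(m[0])
        try:
            for k, name in enumerate(block.phenotype_names):
                row[f"p_skat_{name}"] = skat_pvalue_from_fit(fit, G, m, phenotype=k, spec=spec)
            row["p_skat_adjusted"] = adjusted_min_p(
                [row[f"p_skat_{name}"] for name in block.phenotype_names]
            )
            res = murat_pvalue(
                fit, G, m, spec=spec, resamples=config.resamples,
                seed=config.seed + i,
            )
            row["p_murat"] = res.final_p
            row["flags"] = ";".join(res.method_flags)
        except ValueError as exc:
            logger.warning("region %s skipped: %s", region.name, exc)
            for name in block.phenotype_names:
                row.setdefault(f"p_skat_{name}", np.nan)
            row.setdefault("p_skat_adjusted", np.nan)
            row["p_murat"] = np.nan
            row["flags"] = f"degenerate:{exc}"
        rows.append(row)

    df = pd.DataFrame(rows).sort_values("p_murat", kind="mergesort").reset_index(drop=True)
    n_tests = len(df)
    return ScanReport(
        rows=df,
        n_tests=n_tests,
        bonferroni_threshold=bonferroni_threshold(config.alpha, n_tests),
        alpha=config.alpha,
    )


def qq_data(p_values) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a Q-Q plot.

    Observed p-values are sorted ascending; the expected quantile for rank
    i of N is i/(N+1).
    """
    p = np.sort(np.asarray(list(p_values), dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return np.column_stack([-np.log10(expected), -np.log10(p)])
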