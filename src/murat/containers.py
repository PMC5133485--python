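"""In-memory containers shared across the package.

These are deliberately thin dataclasses around numpy arrays: a genotype
dosage matrix with per-variant metadata, an aligned phenotype/covariate
block, and a gene annotation record.  Missing genotypes are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VariantInfo", "GenotypeMatrix", "PhenotypeBlock", "GeneAnnotation"]

#: sentinel used in text formats for a missing value
MISSING = "NA"


@dataclass
class VariantInfo:
    """Per-variant metadata: location, alleles and observed-genotype summaries."""

    chromosome: str
    position: int
    variant_id: str
    ref_allele: str = "N"
    alt_allele: str = "N"
    maf: float = 0.0
    n_carriers: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant {self.variant_id}: position must be >= 1")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.variant_id}: maf {self.maf} outside [0, 0.5]")
        if self.n_carriers < 0 or self.n_missing < 0:
            raise ValueError(f"variant {self.variant_id}: negative count")


@dataclass
class GenotypeMatrix:
    """n samples x v variants alt-allele dosage matrix (NaN = missing)."""

    samples: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, v = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} dosage rows")
        if v != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {v} dosage columns")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in genotype matrix")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.variants], dtype=int)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([v.chromosome for v in self.variants], dtype=object)

    @property
    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants], dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """Row-subset (and reorder) to the given sample ids."""
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            dosages=self.dosages[rows],
        )


@dataclass
class PhenotypeBlock:
    """Aligned phenotype (n x K) and covariate (n x m) matrices."""

    samples: list[str]
    Y: np.ndarray
    X: np.ndarray
    phenotype_names: list[str]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.samples), 0)
        if self.Y.shape[0] != len(self.samples):
            raise ValueError("Y row count does not match sample count")
        if self.X.shape[0] != len(self.samples):
            raise ValueError("X row count does not match sample count")
        if self.Y.shape[1] != len(self.phenotype_names):
            raise ValueError("phenotype_names length does not match Y columns")
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names length does not match X columns")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_phenotypes(self) -> int:
        return self.Y.shape[1]

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of samples with every phenotype and covariate observed."""
        ok = ~np.isnan(self.Y).any(axis=1)
        if self.X.shape[1]:
            ok &= ~np.isnan(self.X).any(axis=1)
        return ok

    def subset_samples(self, sample_ids: list[str]) -> "PhenotypeBlock":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return PhenotypeBlock(
            samples=list(sample_ids),
            Y=self.Y[rows],
            X=self.X[rows],
            phenotype_names=list(self.phenotype_names),
            covariate_names=list(self.covariate_names),
        )


@dataclass
class GeneAnnotation:
    """One gene interval from a glist-format annotation (1-based, inclusive)."""

    chromosome: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")
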