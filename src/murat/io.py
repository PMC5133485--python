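"""Reading genotypes, phenotypes and gene annotations; writing scan results.

Supported formats
-----------------
* VCF (v4.x, via cyvcf2) — genotypes converted to alt-allele dosages 0/1/2,
  missing calls to NaN.  Multi-allelic records are rejected by default; pass
  ``split_multiallelic=True`` to expand them into one bi-allelic record per
  alt allele.
* Dosage TSV — first column the sample id, one column per variant, header
  row of variant ids; ``NA`` marks a missing genotype.  Variant ids of the
  form ``chr_pos``, ``var_chr_pos`` or ``chr:pos`` carry their own
  coordinates; anything else is placed at its 1-based column ordinal on a
  pseudo-chromosome ``"0"``.
* Phenotype/covariate table — tab-separated with a sample-id column.
* glist gene lists — whitespace-delimited ``chromosome start end name``.
* Results — tab-separated with p-values in scientific notation.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GeneAnnotation, GenotypeMatrix, PhenotypeBlock, VariantInfo
from . import preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "read_gene_list",
    "write_results",
    "write_dosage_tsv",
    "align_samples",
]

_ID_PATTERN = re.compile(r"^(?:var_)?(?:chr)?([0-9XYMT]+)[_:](\d+)(?:[_:].*)?$")


def _variant_info_from_column(vid: str, ordinal: int, dosages: np.ndarray) -> VariantInfo:
    m = _ID_PATTERN.match(vid)
    if m:
        chrom, pos = m.group(1), int(m.group(2))
    else:
        chrom, pos = "0", ordinal
    return VariantInfo(
        chromosome=chrom,
        position=pos,
        variant_id=vid,
        maf=preprocess.compute_maf(dosages),
        n_carriers=preprocess.count_carriers(dosages),
        n_missing=int(np.isnan(dosages).sum()),
    )


def _read_vcf(path: str | Path, split_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample id in VCF header")
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) > 1 and not split_multiallelic:
            raise ValueError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "pass split_multiallelic=True to expand"
            )
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        for ai, alt in enumerate(alts, start=1):
            dos = np.full(len(samples), np.nan)
            for i, g in enumerate(gts):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    continue
                dos[i] = float(sum(a == ai for a in alleles))
            vid = rec.ID or f"{rec.CHROM}_{rec.POS}"
            if len(alts) > 1:
                vid = f"{vid}_{alt}"
            variants.append(
                VariantInfo(
                    chromosome=str(rec.CHROM).removeprefix("chr"),
                    position=int(rec.POS),
                    variant_id=vid,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    maf=preprocess.compute_maf(dos),
                    n_carriers=preprocess.count_carriers(dos),
                    n_missing=int(np.isnan(dos).sum()),
                )
            )
            columns.append(dos)
    if not columns:
        raise ValueError(f"{path}: VCF contains no variant records")
    return GenotypeMatrix(samples=samples, variants=variants, dosages=np.column_stack(columns))


def _read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: failed to parse dosage TSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: dosage TSV needs a sample column and >= 1 variant column")
    samples = df.iloc[:, 0].astype(str).tolist()
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample id in dosage TSV")
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    variants = [
        _variant_info_from_column(str(vid), j + 1, dosages[:, j])
        for j, vid in enumerate(df.columns[1:])
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def read_genotypes(
    path: str | Path, format: str = "auto", split_multiallelic: bool = False
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or dosage TSV.

    ``format`` is one of ``vcf``, ``dosage_tsv`` or ``auto`` (by extension).
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".bcf", ".gz"} else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path, split_multiallelic)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_phenotypes(
    path: str | Path,
    phenotype_cols: list[str],
    covariate_cols: list[str] | None = None,
    sample_col: str | None = None,
) -> PhenotypeBlock:
    """Read a tab-separated phenotype/covariate table.

    ``sample_col`` defaults to the first column.  Rows with missing values
    are retained here (as NaN) and dropped by
    :func:`murat.preprocess.drop_incomplete_samples`.
    """
    covariate_cols = list(covariate_cols or [])
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    if sample_col is None:
        sample_col = df.columns[0]
    for col in [sample_col, *phenotype_cols, *covariate_cols]:
        if col not in df.columns:
            raise KeyError(f"{path}: required column {col!r} not in header")
    return PhenotypeBlock(
        samples=df[sample_col].astype(str).tolist(),
        Y=df[list(phenotype_cols)].to_numpy(dtype=float),
        X=df[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(df), 0)),
        phenotype_names=list(phenotype_cols),
        covariate_names=covariate_cols,
    )


def read_gene_list(path: str | Path, strip_chr_prefix: bool = True) -> list[GeneAnnotation]:
    """Read a glist-format gene list: ``chromosome start end name`` per line."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 'chrom start end name', got {line!r}")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            if strip_chr_prefix:
                chrom = chrom.removeprefix("chr")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer bound for gene {name!r}") from exc
            genes.append(GeneAnnotation(chromosome=chrom, start=start_i, end=end_i, name=name))
    return genes


def write_results(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write scan result records as a tab-separated table.

    Columns follow the single-variant / gene layouts (chr, id/gene, #SNPs,
    MAF where applicable, per-phenotype SKAT p, adjusted SKAT p, MURAT p);
    p-value columns are rendered in scientific notation.
    """
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    for col in df.columns:
        if col.startswith("p_") or col.endswith("_p"):
            df[col] = df[col].map(lambda p: "" if pd.isna(p) else f"{p:.3e}")
    df.to_csv(path, sep="\t", index=False)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix in the dosage TSV layout (round-trippable)."""
    df = pd.DataFrame(gm.dosages, columns=[v.variant_id for v in gm.variants])
    df.insert(0, "sample_id", gm.samples)
    # repr-round-trip float formatting keeps dosages bit-exact
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format=lambda x: repr(float(x)))


def align_samples(gm: GenotypeMatrix, block: PhenotypeBlock) -> tuple[GenotypeMatrix, PhenotypeBlock]:
    """Intersect genotype and phenotype samples, in genotype-file order."""
    pheno_ids = set(block.samples)
    shared = [s for s in gm.samples if s in pheno_ids]
    n_g, n_p = len(gm.samples), len(block.samples)
    if len(shared) < max(n_g, n_p):
        logger.info(
            "sample alignment: %d shared of %d genotyped / %d phenotyped",
            len(shared), n_g, n_p,
        )
    if not shared:
        raise ValueError("no samples shared between genotypes and phenotypes")
    return gm.subset_samples(shared), block.subset_samples(shared)
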