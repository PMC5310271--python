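"""Readers and writers for the tool's tabular formats.

Expression TSV: header ``isoform_id<TAB>gene_id<TAB><sample>...``, one row
per isoform.  Genotype TSV: header ``variant_id[<TAB>chrom<TAB>pos]<TAB>
<sample>...``, codes 0/1/2 or ``NA``.  VCF (v4.x) is read through cyvcf2;
only biallelic records are retained and the code is the alternate-allele
count.  Results TSV: one row per tested gene-variant pair with at least
12 significant digits so a write/read round-trip is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AssociationResult, ExpressionTable, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene_id", "variant_id", "df", "statistic", "p_value", "fdr"]


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a transcript-level expression TSV into an :class:`ExpressionTable`.

    Raises
    ------
    ValidationError
        On malformed numeric cells, missing cells, duplicate isoform ids,
        negative values, or an isoform mapped to more than one gene.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: need isoform id, gene id and >=1 sample column")
    iso_col, gene_col = df.columns[:2]
    sample_ids = [str(c) for c in df.columns[2:]]
    values = df.iloc[:, 2:].to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = _first_non_numeric(df.iloc[:, 2:])
        raise ValidationError(f"{path}: non-numeric expression cell at {bad}")
    if np.isnan(values.astype(float)).any():
        i, j = np.argwhere(np.isnan(values.astype(float)))[0]
        raise ValidationError(
            f"{path}: missing expression value at row {df.iloc[i, 0]!r}, "
            f"column {sample_ids[j]!r}"
        )
    isoform_ids = df[iso_col].astype(str).tolist()
    gene_ids = df[gene_col].astype(str).tolist()
    if len(set(isoform_ids)) != len(isoform_ids):
        dup = pd.Series(isoform_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValidationError(f"{path}: isoform {dup!r} appears on multiple rows")
    return ExpressionTable(
        isoform_ids=isoform_ids,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values.astype(float),
    )


def _first_non_numeric(frame: pd.DataFrame) -> str:
    for j, col in enumerate(frame.columns):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return f"row {i}, column {col!r}"
    return "unknown position"


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from TSV or VCF.

    ``fmt`` is ``"tsv"`` or ``"vcf"``; when None it is inferred from the
    file suffix (``.vcf``/``.vcf.gz`` -> VCF).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    cols = list(df.columns)
    has_pos = len(cols) >= 3 and cols[1].lower() in ("chrom", "chr") and cols[2].lower() == "pos"
    first_sample = 3 if has_pos else 1
    sample_ids = [str(c) for c in cols[first_sample:]]
    if not sample_ids:
        raise ValidationError(f"{path}: no sample columns")
    codes = df.iloc[:, first_sample:].to_numpy(dtype=float)
    positions = None
    if has_pos:
        positions = list(zip(df[cols[1]].astype(str), df[cols[2]].astype(int)))
    return GenotypeMatrix(
        variant_ids=df.iloc[:, 0].astype(str).tolist(),
        sample_ids=sample_ids,
        codes=codes,
        positions=positions,
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    n_badgt = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types, dtype=float)
        codes = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        n_badgt += int(np.isnan(codes).sum())
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variant_ids.append(vid)
        positions.append((rec.CHROM, rec.POS))
        rows.append(codes)
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF records", n_multi)
    if n_badgt:
        logger.warning("set %d unparseable/missing genotypes to NA", n_badgt)
    codes_mat = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    return GenotypeMatrix(
        variant_ids=variant_ids,
        sample_ids=sample_ids,
        codes=codes_mat,
        positions=positions,
    )


def align_samples(
    expr: ExpressionTable, geno: GenotypeMatrix
) -> tuple[ExpressionTable, GenotypeMatrix]:
    """Restrict both tables to shared samples, in identical order.

    The shared samples keep the order in which they occur in the
    expression table, making the operation idempotent.
    """
    shared = [s for s in expr.sample_ids if s in set(geno.sample_ids)]
    if not shared:
        raise ValidationError("expression and genotype tables share no samples")
    e_idx = np.asarray([expr.sample_ids.index(s) for s in shared])
    g_pos = {s: i for i, s in enumerate(geno.sample_ids)}
    g_idx = np.asarray([g_pos[s] for s in shared])
    dropped = (expr.n_samples - len(shared)) + (geno.n_samples - len(shared))
    if dropped:
        logger.info("align_samples: %d shared samples, %d columns dropped", len(shared), dropped)
    return expr.subset_samples(e_idx), geno.subset_samples(g_idx)


def write_results(results: list[AssociationResult] | pd.DataFrame, path: str | Path) -> None:
    """Write results TSV sorted by (gene_id, variant_id), 12+ significant digits."""
    if isinstance(results, pd.DataFrame):
        df = results.loc[:, RESULT_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "variant_id": r.variant_id,
                    "df": r.df,
                    "statistic": r.statistic_s,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                }
                for r in results
            ],
            columns=RESULT_COLUMNS,
        )
    df = df.sort_values(["gene_id", "variant_id"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "variant_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing result columns {missing}")
    return df
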