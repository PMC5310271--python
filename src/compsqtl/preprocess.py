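"""Splicing-ratio computation and the preprocessing filters.

Filter order in :func:`preprocess`: pseudocount -> ratios -> isoform/gene
activity filter -> splicing-variability filter -> per-gene sample filter
-> variant group-size filter.  Stage-by-stage survivor counts are logged
and returned so a run can be audited.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import (
    ExpressionTable,
    FilterConfig,
    GeneRatios,
    GenotypeMatrix,
    SplicingRatioSet,
)

logger = logging.getLogger(__name__)


def splicing_ratios(expr_gene: np.ndarray, pseudocount: float) -> np.ndarray:
    """Per-sample isoform proportions p_ij = (x_ij + c) / sum_i (x_ij + c).

    ``expr_gene`` is the (n_isoforms x n_samples) expression block of one
    gene; a pseudocount c > 0 keeps the denominator positive even when no
    isoform is expressed in a sample.
    """
    x = np.asarray(expr_gene, dtype=float) + pseudocount
    denom = x.sum(axis=0, keepdims=True)
    if (denom <= 0).any():
        raise ValueError("zero total expression with zero pseudocount")
    return x / denom


def filter_isoforms_and_genes(ratios: SplicingRatioSet, cfg: FilterConfig) -> SplicingRatioSet:
    """Keep active isoforms (mean ratio > threshold) and genes with >=2 of them.

    After dropping inactive isoforms each sample column is renormalized to
    sum to 1.  Activity is judged on the mean ratio across the gene's
    retained samples so the isoform set is identical for all samples.
    """
    out = SplicingRatioSet(sample_ids=list(ratios.sample_ids))
    for gene_id, g in ratios.genes.items():
        mean_ratio = g.ratios.mean(axis=1)
        active = mean_ratio > cfg.active_ratio_threshold
        if int(active.sum()) < 2:
            continue
        sub = g.ratios[active, :]
        sub = sub / sub.sum(axis=0, keepdims=True)
        out.genes[gene_id] = GeneRatios(
            gene_id=gene_id,
            isoform_ids=[iso for iso, a in zip(g.isoform_ids, active) if a],
            ratios=sub,
            sample_mask=g.sample_mask.copy(),
        )
    dropped = len(ratios.genes) - len(out.genes)
    if dropped:
        logger.info("activity filter removed %d genes", dropped)
    return out


def splicing_variability(ratios_gene: np.ndarray) -> float:
    """Mean squared Hellinger distance of samples to their Hellinger centroid.

    The centroid is the element-wise mean of the sqrt-ratio vectors,
    renormalized to unit length so it is itself a point on the ratio
    sphere.  The value is SS_T / l: invariant under column permutation
    and under replicating every sample.
    """
    q = np.sqrt(np.asarray(ratios_gene, dtype=float))
    c = q.mean(axis=1)
    norm = np.linalg.norm(c)
    if norm == 0:
        return 0.0
    c = c / norm
    d2 = ((q - c[:, None]) ** 2).sum(axis=0)
    return float(d2.mean())


def filter_samples_per_gene(expr_gene: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Boolean mask of samples whose total gene expression exceeds the floor.

    Gene expression per sample is the column sum of the gene's isoform
    expression; the comparison is strict.
    """
    totals = np.asarray(expr_gene, dtype=float).sum(axis=0)
    return totals > cfg.min_gene_expression


def filter_variants(geno: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Mask undersized genotype groups to NA and drop under-grouped variants.

    Per variant, genotype codes whose group has fewer than
    ``cfg.min_group_size`` samples are set to NA; variants with fewer than
    ``cfg.min_groups`` surviving groups are removed.
    """
    codes = geno.codes.copy()
    keep_rows = []
    for i in range(codes.shape[0]):
        row = codes[i]
        surviving = 0
        for code in (0.0, 1.0, 2.0):
            members = row == code
            size = int(members.sum())
            if size == 0:
                continue
            if size < cfg.min_group_size:
                row[members] = np.nan
            else:
                surviving += 1
        if surviving >= cfg.min_groups:
            keep_rows.append(i)
    dropped = codes.shape[0] - len(keep_rows)
    if dropped:
        logger.info("variant filter removed %d of %d variants", dropped, codes.shape[0])
    keep = np.asarray(keep_rows, dtype=int)
    return GenotypeMatrix(
        variant_ids=[geno.variant_ids[i] for i in keep],
        sample_ids=list(geno.sample_ids),
        codes=codes[keep, :],
        positions=None if geno.positions is None else [geno.positions[i] for i in keep],
    )


def preprocess(
    expr: ExpressionTable,
    geno: GenotypeMatrix,
    cfg: FilterConfig | None = None,
) -> tuple[SplicingRatioSet, GenotypeMatrix, dict[str, int]]:
    """Run the full preprocessing chain on aligned tables.

    Returns the filtered :class:`SplicingRatioSet`, the filtered
    :class:`GenotypeMatrix`, and a dict of survivor counts per stage.
    """
    cfg = cfg or FilterConfig()
    if expr.sample_ids != geno.sample_ids:
        raise ValueError("tables must be sample-aligned before preprocessing")
    n_samples = expr.n_samples
    gene_rows = expr.genes()
    counts = {
        "input_genes": len(gene_rows),
        "input_isoforms": expr.n_isoforms,
        "input_variants": geno.n_variants,
        "input_samples": n_samples,
    }

    # pseudocount + ratios over all aligned samples
    ratio_set = SplicingRatioSet(sample_ids=list(expr.sample_ids))
    for gene_id, rows in gene_rows.items():
        if len(rows) < 2:
            continue
        ratio_set.genes[gene_id] = GeneRatios(
            gene_id=gene_id,
            isoform_ids=[expr.isoform_ids[i] for i in rows],
            ratios=splicing_ratios(expr.values[rows, :], cfg.pseudocount),
            sample_mask=np.ones(n_samples, dtype=bool),
        )
    counts["genes_with_2plus_isoforms"] = len(ratio_set.genes)

    ratio_set = filter_isoforms_and_genes(ratio_set, cfg)
    counts["genes_after_activity_filter"] = len(ratio_set.genes)
    counts["isoforms_after_activity_filter"] = sum(
        g.n_isoforms for g in ratio_set.genes.values()
    )

    ratio_set.genes = {
        gid: g
        for gid, g in ratio_set.genes.items()
        if splicing_variability(g.ratios) >= cfg.min_splicing_variability
    }
    counts["genes_after_variability_filter"] = len(ratio_set.genes)

    # per-gene sample filter on the raw expression totals
    kept_genes: dict[str, GeneRatios] = {}
    for gene_id, g in ratio_set.genes.items():
        mask = filter_samples_per_gene(expr.values[gene_rows[gene_id], :], cfg)
        if int(mask.sum()) < 3:
            continue  # not enough samples to test anything
        kept_genes[gene_id] = GeneRatios(
            gene_id=gene_id,
            isoform_ids=list(g.isoform_ids),
            ratios=g.ratios[:, mask],
            sample_mask=mask,
        )
    ratio_set.genes = kept_genes
    counts["genes_after_sample_filter"] = len(ratio_set.genes)

    geno = filter_variants(geno, cfg)
    counts["variants_after_group_filter"] = geno.n_variants

    for stage, value in counts.items():
        logger.info("preprocess %s = %d", stage, value)
    ratio_set.validate()
    return ratio_set, geno, counts
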