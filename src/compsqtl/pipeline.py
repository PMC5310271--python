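"""End-to-end analysis: read -> align -> preprocess -> transform -> test ->
combine -> FDR, with chunked execution over variants.

Chunks are independent: statistics are identical whatever the chunk size,
and q-values are computed once on the pooled p-values (they depend on the
whole p distribution, so per-chunk FDR would be wrong).
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anderson import bartlett_homogeneity_p, permutation_p
from .combine import combine_pairs, compute_fdr
from .fasttest import DEFAULT_MIN_SHARED, test_components
from .io import align_samples, read_expression, read_genotypes, write_results
from .model import (
    ExpressionTable,
    FilterConfig,
    GenotypeMatrix,
    SplicingRatioSet,
    ValidationError,
)
from .preprocess import preprocess
from .sphere import build_component_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    expression_path: str | Path
    genotype_path: str | Path
    output_path: str | Path
    filters: FilterConfig = field(default_factory=FilterConfig)
    model: str = "anova"
    chunk_size: int = 1000
    min_shared_samples: int = DEFAULT_MIN_SHARED
    cis_window: int | None = None
    annotation_path: str | Path | None = None
    n_workers: int = 1
    seed: int = 0
    dump_components_path: str | Path | None = None  # debug TSV of the matrix

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.cis_window is not None and self.cis_window < 0:
            raise ValueError("cis_window must be >= 0")
        if self.cis_window is not None and self.annotation_path is None:
            raise ValueError("cis_window requires a gene annotation table")


def analyze(
    expr: ExpressionTable,
    geno: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    model: str = "anova",
    chunk_size: int = 1000,
    min_shared_samples: int = DEFAULT_MIN_SHARED,
    n_workers: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Library entry point: aligned-or-not tables in, pooled results out.

    Returns the result DataFrame (gene_id, variant_id, df, statistic,
    p_value, fdr; sorted by gene then variant) and the preprocessing
    survivor counts.
    """
    expr, geno = align_samples(expr, geno)
    ratio_set, geno, counts = preprocess(expr, geno, cfg)
    empty = pd.DataFrame(
        columns=["gene_id", "variant_id", "df", "statistic", "p_value", "fdr"]
    )
    if not ratio_set.genes:
        logger.warning("no genes survived preprocessing")
        return empty, counts
    if geno.n_variants == 0:
        logger.warning("no variants survived preprocessing")
        return empty, counts
    comp = build_component_matrix(ratio_set)

    starts = range(0, geno.n_variants, chunk_size)
    chunk_indices = [np.arange(s, min(s + chunk_size, geno.n_variants)) for s in starts]

    def run_chunk(idx: np.ndarray) -> pd.DataFrame:
        sub = geno.subset_variants(idx)
        stats_ = test_components(comp, sub, model=model, min_shared_samples=min_shared_samples)
        return combine_pairs(stats_, comp.row_index, sub.variant_ids)

    if n_workers > 1 and len(chunk_indices) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            partials = list(pool.map(run_chunk, chunk_indices))
    else:
        partials = [run_chunk(idx) for idx in chunk_indices]
    return merge_chunk_results(partials), counts


def merge_chunk_results(partials: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-chunk results, sort, and recompute FDR on the pool.

    The chunks must cover disjoint variant sets.
    """
    if not partials:
        raise ValueError("no chunk results to merge")
    seen: set[str] = set()
    for part in partials:
        variants = set(part["variant_id"].unique())
        if variants & seen:
            raise ValueError(f"overlapping variant sets across chunks: {variants & seen}")
        seen |= variants
    pooled = pd.concat(partials, ignore_index=True)
    pooled = pooled.sort_values(["gene_id", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )
    pooled["fdr"] = compute_fdr(pooled["p_value"].to_numpy())
    return pooled


def _apply_cis_window(
    results: pd.DataFrame,
    geno: GenotypeMatrix,
    annotation: pd.DataFrame,
    window: int,
) -> pd.DataFrame:
    """Keep pairs whose variant lies within `window` bp of the gene body."""
    if geno.positions is None:
        raise ValidationError("cis filtering needs variant positions")
    ann = annotation.set_index("gene_id")
    vpos = dict(zip(geno.variant_ids, geno.positions))
    keep = []
    for row in results.itertuples():
        if row.gene_id not in ann.index or row.variant_id not in vpos:
            keep.append(False)
            continue
        chrom, pos = vpos[row.variant_id]
        g = ann.loc[row.gene_id]
        keep.append(
            str(g["chrom"]) == str(chrom)
            and g["start"] - window <= pos <= g["end"] + window
        )
    out = results[np.asarray(keep, bool)].reset_index(drop=True)
    if len(out):
        out = out.copy()
        out["fdr"] = compute_fdr(out["p_value"].to_numpy())
    return out


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """File-to-file pipeline run; writes the results TSV and returns it."""
    try:
        expr = read_expression(config.expression_path)
        geno = read_genotypes(config.genotype_path)
    except Exception:
        logger.error("pipeline aborted at stage: read")
        raise
    if geno.n_variants == 0:
        logger.error("pipeline aborted at stage: read (empty variant table)")
        raise ValidationError("genotype table contains no variants")
    results, _counts = analyze(
        expr,
        geno,
        cfg=config.filters,
        model=config.model,
        chunk_size=config.chunk_size,
        min_shared_samples=config.min_shared_samples,
        n_workers=config.n_workers,
    )
    if config.dump_components_path is not None:
        expr_a, geno_a = align_samples(expr, geno)
        ratio_set, _, _ = preprocess(expr_a, geno_a, config.filters)
        comp = build_component_matrix(ratio_set)
        dump = pd.DataFrame(comp.values, columns=comp.sample_ids)
        dump.insert(0, "component", [f"{g}:{k}" for g, k in comp.row_index])
        dump.to_csv(config.dump_components_path, sep="\t", index=False, float_format="%.10g")
    if config.cis_window is not None:
        annotation = pd.read_csv(config.annotation_path, sep="\t", dtype={"gene_id": str})
        results = _apply_cis_window(results, geno, annotation, config.cis_window)
    write_results(results, config.output_path)
    logger.info("wrote %d gene-variant pairs to %s", len(results), config.output_path)
    return results


def validate_top_hits(
    results: pd.DataFrame,
    ratio_set: SplicingRatioSet,
    geno: GenotypeMatrix,
    top_k: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-test the top-K fast-path hits with the Anderson permutation oracle.

    Adds ``anderson_p`` (Hellinger PERMANOVA permutation p-value) and
    ``bartlett_p`` (group-dispersion homogeneity warning) columns.
    """
    hits = results.sort_values("p_value", kind="mergesort").head(top_k)
    vrow = {v: i for i, v in enumerate(geno.variant_ids)}
    rng = np.random.default_rng(seed)
    rows = []
    for hit in hits.itertuples():
        gene = ratio_set.genes.get(hit.gene_id)
        if gene is None or hit.variant_id not in vrow:
            continue
        codes = geno.codes[vrow[hit.variant_id], :]
        mask = gene.sample_mask & ~np.isnan(codes)
        ratios = gene.ratios[:, mask[gene.sample_mask]]
        groups = codes[mask]
        if np.unique(groups).size < 2:
            continue
        rows.append(
            {
                "gene_id": hit.gene_id,
                "variant_id": hit.variant_id,
                "p_value": hit.p_value,
                "anderson_p": permutation_p(ratios, groups, n_perm=n_perm, seed=rng),
                "bartlett_p": bartlett_homogeneity_p(ratios, groups),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "variant_id", "p_value", "anderson_p", "bartlett_p"]
    )
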