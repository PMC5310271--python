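"""Synthetic datasets with known composite-sQTL structure.

Genotypes are drawn i.i.d. under Hardy-Weinberg equilibrium at a
configurable allele frequency.  Each gene's splicing-ratio vector is
Dirichlet; for sQTL genes the Dirichlet concentration vector depends on
the sample's genotype at that gene's causal variant (opposite homozygote
groups favour opposite isoforms, heterozygotes sit in between), while
null genes use one concentration for everyone.  Total gene expression
is Gamma with configurable overdispersion, and isoform expression is
total times ratios — an RPKM-like table that feeds straight into the
normal input path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ExpressionTable, GenotypeMatrix

__all__ = [
    "SimScenario",
    "simulate_genotypes",
    "simulate_expression",
    "causal_pairs",
    "write_fixture",
]


@dataclass
class SimScenario:
    """Generative parameters of one synthetic dataset.

    ``concentration_ratio`` is the fold-change between the favoured and
    background Dirichlet concentrations in the homozygote groups; 1 means
    no effect.  ``noise_overdispersion`` is the squared coefficient of
    variation of total gene expression (Gamma shape = 1 / value).
    ``effects`` may override the per-gene genotype -> concentration map;
    when empty it is derived from the scalar knobs.
    """

    n_samples: int = 200
    n_genes: int = 20
    isoforms_per_gene: int | tuple[int, int] = 3
    allele_freq: float = 0.3
    n_sqtl_genes: int = 10
    concentration_ratio: float = 5.0
    base_concentration: float = 2.0
    gene_expression_scale: float = 10.0
    noise_overdispersion: float = 0.5
    n_null_variants: int = 1
    seed: int = 0
    effects: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be in (0, 1)")
        if self.noise_overdispersion <= 0 or self.gene_expression_scale <= 0:
            raise ValueError("scale and overdispersion must be positive")
        if self.n_sqtl_genes > self.n_genes:
            raise ValueError("n_sqtl_genes exceeds n_genes")

    @property
    def hwe_frequencies(self) -> np.ndarray:
        f = self.allele_freq
        return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def _structure(scenario: SimScenario):
    """Deterministic gene/variant layout shared by both simulators.

    Returns (gene_ids, isoform_counts, variant_ids, positions, effects)
    where effects maps gene_id -> {genotype: concentration vector}.
    """
    rng = np.random.default_rng([scenario.seed % (2**31), 0])
    width = max(4, len(str(scenario.n_genes)))
    gene_ids = [f"gene{i + 1:0{width}d}" for i in range(scenario.n_genes)]
    if isinstance(scenario.isoforms_per_gene, int):
        counts = np.full(scenario.n_genes, scenario.isoforms_per_gene, dtype=int)
    else:
        lo, hi = scenario.isoforms_per_gene
        counts = rng.integers(lo, hi + 1, size=scenario.n_genes)
    if (counts < 2).any():
        raise ValueError("every gene needs >=2 isoforms")

    effects: dict[str, dict[int, np.ndarray]] = {}
    for i, gid in enumerate(gene_ids):
        n = int(counts[i])
        if gid in scenario.effects:
            effects[gid] = {g: np.asarray(v, float) for g, v in scenario.effects[gid].items()}
            continue
        base = np.full(n, scenario.base_concentration)
        if i < scenario.n_sqtl_genes and scenario.concentration_ratio != 1.0:
            up = base.copy()
            up[0] *= scenario.concentration_ratio
            down = base.copy()
            down[-1] *= scenario.concentration_ratio
            effects[gid] = {0: up, 1: (up + down) / 2.0, 2: down}
        else:
            effects[gid] = {0: base, 1: base, 2: base}

    variant_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    pos = 1000
    for gid in gene_ids:
        variant_ids.append(f"{gid}_causal")
        positions.append(("1", pos))
        pos += 500
        for j in range(scenario.n_null_variants):
            variant_ids.append(f"{gid}_null{j + 1}")
            positions.append(("1", pos))
            pos += 500
    return gene_ids, counts, variant_ids, positions, effects


def simulate_genotypes(scenario: SimScenario) -> GenotypeMatrix:
    """Draw all variants i.i.d. under HWE at the scenario's allele frequency."""
    _, _, variant_ids, positions, _ = _structure(scenario)
    rng = np.random.default_rng([scenario.seed % (2**31), 1])
    codes = rng.choice(
        [0.0, 1.0, 2.0],
        size=(len(variant_ids), scenario.n_samples),
        p=scenario.hwe_frequencies,
    )
    sample_ids = [f"s{j + 1:04d}" for j in range(scenario.n_samples)]
    return GenotypeMatrix(
        variant_ids=variant_ids, sample_ids=sample_ids, codes=codes, positions=positions
    )


def simulate_expression(scenario: SimScenario, genotypes: GenotypeMatrix) -> ExpressionTable:
    """Dirichlet splicing ratios conditioned on the causal genotype, times
    Gamma-distributed total gene expression."""
    gene_ids, counts, _, _, effects = _structure(scenario)
    rng = np.random.default_rng([scenario.seed % (2**31), 2])
    vrow = {v: i for i, v in enumerate(genotypes.variant_ids)}
    shape = 1.0 / scenario.noise_overdispersion
    scale = scenario.gene_expression_scale * scenario.noise_overdispersion

    iso_ids: list[str] = []
    iso_genes: list[str] = []
    blocks: list[np.ndarray] = []
    for i, gid in enumerate(gene_ids):
        n = int(counts[i])
        g = genotypes.codes[vrow[f"{gid}_causal"], :]
        ratios = np.empty((n, scenario.n_samples))
        for code in (0, 1, 2):
            cols = np.flatnonzero(g == code)
            if cols.size:
                ratios[:, cols] = rng.dirichlet(effects[gid][code], size=cols.size).T
        totals = rng.gamma(shape, scale, size=scenario.n_samples)
        blocks.append(ratios * totals[None, :])
        iso_ids.extend(f"{gid}.iso{j + 1}" for j in range(n))
        iso_genes.extend([gid] * n)
    return ExpressionTable(
        isoform_ids=iso_ids,
        gene_ids=iso_genes,
        sample_ids=list(genotypes.sample_ids),
        values=np.vstack(blocks),
    )


def causal_pairs(scenario: SimScenario) -> pd.DataFrame:
    """Ground truth: the (gene, variant) pairs carrying a genotype effect."""
    gene_ids, _, _, _, effects = _structure(scenario)
    rows = [
        {"gene_id": gid, "variant_id": f"{gid}_causal"}
        for gid in gene_ids
        if not all(
            np.array_equal(effects[gid][0], effects[gid][g]) for g in (1, 2)
        )
    ]
    return pd.DataFrame(rows, columns=["gene_id", "variant_id"])


def write_fixture(scenario: SimScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write expression.tsv, genotypes.tsv and truth.tsv; byte-deterministic."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(scenario)
    expr = simulate_expression(scenario, geno)

    expr_path = out_dir / "expression.tsv"
    edf = pd.DataFrame(expr.values, columns=expr.sample_ids)
    edf.insert(0, "gene_id", expr.gene_ids)
    edf.insert(0, "isoform_id", expr.isoform_ids)
    edf.to_csv(expr_path, sep="\t", index=False, float_format="%.10g")

    geno_path = out_dir / "genotypes.tsv"
    gdf = pd.DataFrame(geno.codes, columns=geno.sample_ids)
    gdf = gdf.astype(object).where(pd.notna(gdf), "NA")
    gdf.insert(0, "pos", [p for _, p in geno.positions])
    gdf.insert(0, "chrom", [c for c, _ in geno.positions])
    gdf.insert(0, "variant_id", geno.variant_ids)
    for col in geno.sample_ids:
        gdf[col] = gdf[col].map(lambda v: v if v == "NA" else str(int(v)))
    gdf.to_csv(geno_path, sep="\t", index=False)

    truth_path = out_dir / "truth.tsv"
    causal_pairs(scenario).to_csv(truth_path, sep="\t", index=False)
    return {"expression": expr_path, "genotypes": geno_path, "truth": truth_path}
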