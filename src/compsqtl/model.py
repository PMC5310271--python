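"""Shared data model: expression, genotypes, splicing ratios, components, results.

Conventions used throughout the package:

* expression values are non-negative, RPKM-like, isoforms x samples;
* genotypes are hard calls 0/1/2 coded as floats with ``nan`` for missing;
* after :func:`compsqtl.io.align_samples` the sample axes of the two
  tables are identical and in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclass
class ExpressionTable:
    """Transcript-level expression: one row per isoform, one column per sample.

    Attributes
    ----------
    isoform_ids : list of str
        Unique isoform identifiers, parallel to the rows of ``values``.
    gene_ids : list of str
        Gene identifier for each isoform row (many isoforms per gene).
    sample_ids : list of str
    values : ndarray, shape (n_isoforms, n_samples)
        Non-negative expression in RPKM-like units.  NaN is rejected.
    """

    isoform_ids: list[str]
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_iso, n_smp = self.values.shape
        if len(self.isoform_ids) != n_iso or len(self.gene_ids) != n_iso:
            raise ValidationError("isoform/gene id lists must match value rows")
        if len(self.sample_ids) != n_smp:
            raise ValidationError("sample id list must match value columns")
        if len(set(self.isoform_ids)) != n_iso:
            raise ValidationError("duplicate isoform ids")
        if np.isnan(self.values).any():
            raise ValidationError("expression values contain NaN")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression at isoform {self.isoform_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_isoforms(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes(self) -> dict[str, np.ndarray]:
        """Map gene id -> integer row indices of its isoforms (input order)."""
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.gene_ids):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(rows, dtype=int) for g, rows in out.items()}

    def subset_samples(self, indices: np.ndarray) -> "ExpressionTable":
        return ExpressionTable(
            isoform_ids=list(self.isoform_ids),
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in indices],
            values=self.values[:, indices],
        )


@dataclass
class GenotypeMatrix:
    """Hard-call genotypes: one row per variant, one column per sample.

    ``codes`` holds alternate-allele counts 0/1/2 as floats, ``nan`` = missing.
    ``positions`` optionally carries (chrom, pos) per variant, 1-based.
    """

    variant_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray
    positions: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_var, n_smp = self.codes.shape
        if len(self.variant_ids) != n_var:
            raise ValidationError("variant id list must match code rows")
        if len(self.sample_ids) != n_smp:
            raise ValidationError("sample id list must match code columns")
        if self.positions is not None and len(self.positions) != n_var:
            raise ValidationError("positions must match variant rows")
        finite = self.codes[~np.isnan(self.codes)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("genotype codes must be 0, 1, 2 or NA")

    @property
    def n_variants(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def subset_samples(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variant_ids=list(self.variant_ids),
            sample_ids=[self.sample_ids[i] for i in indices],
            codes=self.codes[:, indices],
            positions=None if self.positions is None else list(self.positions),
        )

    def subset_variants(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variant_ids=[self.variant_ids[i] for i in indices],
            sample_ids=list(self.sample_ids),
            codes=self.codes[indices, :],
            positions=None
            if self.positions is None
            else [self.positions[i] for i in indices],
        )


@dataclass
class GeneRatios:
    """Splicing ratios of one gene over its retained samples.

    ``ratios`` has shape (n_isoforms, n_retained_samples); every column sums
    to 1.  ``sample_mask`` marks, over the globally aligned sample list,
    which samples this gene retains.
    """

    gene_id: str
    isoform_ids: list[str]
    ratios: np.ndarray
    sample_mask: np.ndarray  # boolean over the global aligned sample axis

    @property
    def n_isoforms(self) -> int:
        return self.ratios.shape[0]


@dataclass
class SplicingRatioSet:
    """Post-filter splicing ratios of all surviving genes.

    ``sample_ids`` is the global aligned sample list; each gene carries its
    own retained-sample mask over that list.
    """

    sample_ids: list[str]
    genes: dict[str, GeneRatios] = field(default_factory=dict)

    def validate(self, atol: float = 1e-9) -> None:
        for g in self.genes.values():
            if g.n_isoforms < 2:
                raise ValidationError(f"gene {g.gene_id} has <2 isoforms")
            if g.ratios.shape[1] != int(g.sample_mask.sum()):
                raise ValidationError(f"gene {g.gene_id}: ratio/mask mismatch")
            if (g.ratios < -atol).any() or (g.ratios > 1 + atol).any():
                raise ValidationError(f"gene {g.gene_id}: ratios outside [0,1]")
            if g.ratios.size and not np.allclose(g.ratios.sum(axis=0), 1.0, atol=atol):
                raise ValidationError(f"gene {g.gene_id}: columns do not sum to 1")


@dataclass
class ComponentMatrix:
    """Stacked converted splicing components of all genes.

    ``values`` is t x l where t = sum over genes of (n_isoforms - 1) and l is
    the number of aligned samples; entries are angles in [0, pi/2], NaN where
    a gene does not retain a sample.  ``row_index`` holds (gene_id, rank)
    per row with rank in 1..n-1; ``gene_df`` maps gene -> n-1.
    """

    values: np.ndarray
    row_index: list[tuple[str, int]]
    gene_df: dict[str, int]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationResult:
    """Composite test result for one gene-variant pair."""

    gene_id: str
    variant_id: str
    statistic_s: float
    df: int
    p_value: float
    fdr: float = float("nan")
    reduced_df: bool = False  # some components skipped (zero variance)


@dataclass
class FilterConfig:
    """Thresholds of the preprocessing filters.

    pseudocount
        Added to every expression value before forming ratios so the
        denominator is never zero (expression units).
    active_ratio_threshold
        An isoform is active iff its mean splicing ratio across samples
        exceeds this; genes need >=2 active isoforms.
    min_splicing_variability
        Genes whose splicing variability (mean squared Hellinger distance
        to the centroid) falls below this are dropped.
    min_gene_expression
        Per gene, samples whose total gene expression (summed isoform
        RPKM) is at or below this are dropped for that gene.
    min_group_size, min_groups
        A genotype group smaller than ``min_group_size`` is masked to NA;
        variants with fewer than ``min_groups`` surviving groups are dropped.
    """

    pseudocount: float = 1e-2
    active_ratio_threshold: float = 0.05
    min_splicing_variability: float = 0.01
    min_gene_expression: float = 0.01
    min_group_size: int = 5
    min_groups: int = 2

    def __post_init__(self) -> None:
        for name in (
            "pseudocount",
            "active_ratio_threshold",
            "min_splicing_variability",
            "min_gene_expression",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.min_group_size < 1:
            raise ValidationError("min_group_size must be >= 1")
        if self.min_groups < 1:
            raise ValidationError("min_groups must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FilterConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        return cls(**kwargs)
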