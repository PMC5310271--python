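# compsqtl

Fast composite splicing-QTL mapping: find genetic variants associated with
the **whole vector of a gene's isoform splicing ratios**, at a scale where
every gene can be tested against every variant.

## The problem

Alternative splicing distributes a gene's output over several isoforms.
For many regulatory questions the phenotype of interest is not any single
isoform's expression but the *composition* — the splicing ratios
p_i = x_i / Σ_j x_j of the n isoforms, a point on the simplex.  A variant
whose genotype groups (g = 0, 1, 2 copies of the alternate allele) show
different splicing-ratio distributions is a composite splicing QTL (sQTL).

Distance-based tests (Hellinger-distance PERMANOVA on each gene-variant
pair) detect such associations but cost O(N²) per pair, which confines
them to small cis windows.  `compsqtl` instead:

1. **Transforms** each gene's ratio vector to unconstrained coordinates.
   With q_i = √p_i the sample lies on the unit n-sphere (Σ q_i² = 1), and
   the n−1 polar angles

       φ_k = arccos( q_k / √(q_k² + … + q_n²) ),   k = 1..n−1

   ("converted splicing components") are free coordinates in [0, π/2].
   Isoforms are ordered once per gene, largest mean √-ratio first.
2. **Tests in bulk**: all components of all genes are stacked into one
   matrix Φ (t × l, t = #isoforms − #genes), rows of Φ and of the genotype
   matrix are standardized to mean 0 / unit sum of squares, and every
   component-variant statistic comes from the single product Φ·Vᵀ
   (the Matrix-eQTL strategy).  Genotype is treated as categorical
   (one-way ANOVA F, default) or as a 0/1/2 dose (t-test).
3. **Combines** the n−1 component statistics of one gene-variant pair:
   component p-values map to z = Φ⁻¹(1−p), and s = Σ z_i² ~ χ²_{n−1}
   under the null gives the composite p-value; q-values (Storey FDR)
   are computed over the whole run.

A slow, exact Hellinger-distance Anderson permutation test is included as
an independent oracle (`compsqtl validate`) for re-checking top hits, and
a Dirichlet simulator generates datasets with known sQTL structure.

## Worked example

```bash
compsqtl simulate --out fix --seed 11      # 20 genes (10 sQTL), 200 samples
compsqtl run --expression fix/expression.tsv --genotypes fix/genotypes.tsv \
             --out results.tsv
```

Top of `results.tsv` (sorted by p-value):

```
 gene_id      variant_id  df  statistic      p_value          fdr
gene0004 gene0004_causal   2 338.135350 3.757004e-74 1.951006e-71
gene0008 gene0008_causal   2 337.579647 4.960335e-74 1.951006e-71
gene0006 gene0006_causal   2 336.802392 7.316273e-74 1.951006e-71
gene0001 gene0001_causal   2 330.692271 1.552694e-72 3.105388e-70
gene0003 gene0003_causal   2 329.237802 3.213066e-72 5.140905e-70
gene0010 gene0010_causal   2 293.867601 1.539789e-64 2.053052e-62
```

800 gene-variant pairs were tested; the 10 simulated causal pairs occupy
the top ranks with χ²₂ statistics around 300 (each gene here has three
isoforms, hence df = n−1 = 2), while null pairs get near-uniform
p-values.  `fdr` is the Storey q-value over all 800 tests.

Re-test the strongest hits with the permutation oracle:

```bash
compsqtl validate --expression fix/expression.tsv --genotypes fix/genotypes.tsv \
                  --results results.tsv --out validated.tsv --top-k 10
```

Input formats: expression TSV (`isoform_id`, `gene_id`, then one column
per sample, RPKM-like units); genotypes TSV (`variant_id`, optional
`chrom`/`pos`, then samples; codes 0/1/2 or `NA`) or a biallelic VCF.
All preprocessing thresholds (pseudocount, isoform activity, splicing
variability, gene-expression floor, genotype group sizes) are flags or
YAML config keys; see `compsqtl run --help`.

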