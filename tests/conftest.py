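import numpy as np
import pytest

from compsqtl import ExpressionTable, GenotypeMatrix, SimScenario
from compsqtl.simulate import simulate_expression, simulate_genotypes


@pytest.fixture
def toy_expression() -> ExpressionTable:
    """3 isoforms (2 genes), 4 samples."""
    return ExpressionTable(
        isoform_ids=["isoA1", "isoA2", "isoB1"],
        gene_ids=["geneA", "geneA", "geneB"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[2.0, 1.0, 0.0, 5.0], [1.0, 3.0, 4.0, 5.0], [1.0, 1.0, 1.0, 1.0]]
        ),
    )


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    return GenotypeMatrix(
        variant_ids=["v1", "v2"],
        sample_ids=["s1", "s2", "s3", "s4"],
        codes=np.array([[0.0, 1.0, 2.0, 1.0], [0.0, 0.0, np.nan, 1.0]]),
    )


@pytest.fixture(scope="session")
def sim_scenario() -> SimScenario:
    """Small dataset with genuine sQTL structure, shared across tests."""
    return SimScenario(
        n_samples=150,
        n_genes=10,
        isoforms_per_gene=(2, 4),
        n_sqtl_genes=5,
        concentration_ratio=5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def sim_data(sim_scenario):
    geno = simulate_genotypes(sim_scenario)
    expr = simulate_expression(sim_scenario, geno)
    return expr, geno
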