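import numpy as np
import pytest
import scipy.sparse as sp

from celltyper import (
    ClusterAssignment,
    ClusterProfile,
    CountMatrix,
    MarkerRecord,
    MarkerTable,
)


def make_profile(values: dict[str, float], cluster_id: int = 0,
                 n_cells: int = 10) -> ClusterProfile:
    return ClusterProfile(cluster_id=cluster_id, n_cells=n_cells,
                          median_expression=dict(values))


def make_matrix(dense, genes=None, cells=None, assay="umi_counts") -> CountMatrix:
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{j:03d}" for j in range(dense.shape[1])]
    return CountMatrix(genes=genes, cells=cells,
                       counts=sp.csc_matrix(dense), assay=assay)


@pytest.fixture
def tiny_table() -> MarkerTable:
    """Three cell types; Gene3 is shared between Alpha and Beta (f=2)."""
    return MarkerTable([
        MarkerRecord(species="Mm", gene_symbol="Gene1", cell_type="Alpha",
                     aliases=("G1a",)),
        MarkerRecord(species="Mm", gene_symbol="Gene2", cell_type="Alpha"),
        MarkerRecord(species="Mm", gene_symbol="Gene3", cell_type="Alpha"),
        MarkerRecord(species="Mm", gene_symbol="Gene3", cell_type="Beta"),
        MarkerRecord(species="Mm", gene_symbol="Gene4", cell_type="Beta"),
        MarkerRecord(species="Hs", gene_symbol="Gene5", cell_type="Gamma"),
        MarkerRecord(species="both", gene_symbol="Gene6", cell_type="Gamma"),
    ])
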