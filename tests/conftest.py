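from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ambint.expr_io import CountMatrix, GeneModel, GeneModelSet, to_log1p_cpm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """4 cells x 3 genes with simple integer counts."""
    return CountMatrix(
        cell_ids=["c1", "c2", "c3", "c4"],
        gene_ids=["gA", "gB", "gC"],
        counts=np.array([[1, 1, 2], [0, 0, 0], [5, 0, 5], [2, 2, 0]]),
    )


@pytest.fixture
def two_exon_gene():
    """+ strand gene: exons (100, 200) and (300, 400), one intron (200, 300)."""
    return GeneModel(
        gene_id="gX", chrom="chr1", strand="+", start=100, end=400,
        exons=((100, 200), (300, 400)),
    )


@pytest.fixture
def toy_models(two_exon_gene):
    minus = GeneModel(
        gene_id="gY", chrom="chr1", strand="-", start=1000, end=1500,
        exons=((1000, 1150), (1300, 1500)),
    )
    return GeneModelSet([two_exon_gene, minus])


@pytest.fixture
def annotated_matrix(rng):
    """30 cells x 40 genes: gene 0..4 exclusive to 'parenchyma' cells."""
    n_par, n_tgt, n_genes = 12, 18, 40
    counts = rng.poisson(5.0, size=(n_par + n_tgt, n_genes))
    counts[:n_par, :5] += 200
    counts[n_par:, :5] = 0
    cells = [f"p{i}" for i in range(n_par)] + [f"t{i}" for i in range(n_tgt)]
    m = CountMatrix(cells, [f"g{i:03d}" for i in range(n_genes)], counts)
    ann = pd.DataFrame(
        {
            "cell_id": cells,
            "cell_type": ["parenchyma"] * n_par + ["target"] * n_tgt,
            "tissue": "toy",
        }
    )
    return m, ann


@pytest.fixture
def annotated_norm(annotated_matrix):
    m, ann = annotated_matrix
    return to_log1p_cpm(m), ann
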