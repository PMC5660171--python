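import numpy as np
import pandas as pd
import pytest

from nx1seq.matrix import DigitalExpressionMatrix
from nx1seq.synthetic import (
    default_barnyard_spec,
    emit_fastq_pairs,
    make_toy_transcriptome,
    simulate_cells,
)


@pytest.fixture(scope="session")
def barnyard_transcriptome():
    """100 human + 100 mouse random transcripts, no shared 25-mers."""
    return make_toy_transcriptome(100, species=("human", "mouse"), seed=11)


@pytest.fixture(scope="session")
def barnyard_truth():
    spec = default_barnyard_spec(n_cells=60, doublet_rate=0.0, n_genes_per_species=100)
    return simulate_cells(spec, seed=12)


@pytest.fixture(scope="session")
def errorfree_run(tmp_path_factory, barnyard_transcriptome, barnyard_truth):
    """Error-free paired FASTQ for the 60-cell two-species population."""
    d = tmp_path_factory.mktemp("fastq")
    r1, r2 = d / "reads_1.fastq", d / "reads_2.fastq"
    n_pairs = emit_fastq_pairs(barnyard_truth, barnyard_transcriptome, r1, r2,
                               error_rate=0.0, seed=13)
    return {"read1": r1, "read2": r2, "n_pairs": n_pairs}


def make_matrix(rows, barcodes=None, genes=None, **kwargs) -> DigitalExpressionMatrix:
    arr = np.asarray(rows)
    barcodes = barcodes or [f"BC{i:03d}" for i in range(arr.shape[0])]
    genes = genes or [f"g{j:03d}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=barcodes, columns=genes)
    return DigitalExpressionMatrix(df, **kwargs)
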