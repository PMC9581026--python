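import numpy as np
import pytest

from diffint.io import ExpressionDataset


@pytest.fixture
def tiny_ds():
    """3 genes x 4 samples, 2 normal + 2 tumor."""
    return ExpressionDataset(
        gene_ids=["A", "B", "C"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 5.0, 5.0, 5.0],
                [2.0, 8.0, 1.0, 9.0],
            ]
        ),
        phenotype=["normal", "normal", "tumor", "tumor"],
    )


@pytest.fixture
def tiny_matrix_tsv(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text(
        "gene\ts1\ts2\ts3\ts4\n"
        "A\t1.0\t2.0\t3.0\t4.0\n"
        "B\t5.0\t5.0\t5.0\t5.0\n"
        "C\t2.0\t8.0\t1.0\t9.0\n"
    )
    return p


@pytest.fixture
def tiny_labels_tsv(tmp_path):
    p = tmp_path / "labels.tsv"
    p.write_text("s1\tnormal\ns2\tnormal\ns3\ttumor\ns4\ttumor\n")
    return p
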