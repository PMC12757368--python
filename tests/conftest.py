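import numpy as np
import pandas as pd
import pytest

from cflmd.io_formats import CASE, CONTROL, BetaMatrix, CpGCountTable, ProbeAnnotation


@pytest.fixture
def tiny_beta():
    """2 probes x 4 samples, 2 per group, no missing values."""
    values = pd.DataFrame(
        [[0.10, 0.20, 0.80, 0.90], [0.30, 0.40, 0.35, 0.45]],
        index=["cgA", "cgB"],
        columns=["c1", "c2", "d1", "d2"],
    )
    groups = pd.Series([CONTROL, CONTROL, CASE, CASE], index=values.columns)
    return BetaMatrix(values=values, groups=groups)


@pytest.fixture
def count_table_factory():
    def make(rows, sample_id="s", group=CASE):
        rec = pd.DataFrame(rows, columns=["chrom", "pos", "n_total", "n_meth"])
        return CpGCountTable(records=rec, sample_id=sample_id, group=group)

    return make


@pytest.fixture
def simple_annotation():
    ent = pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p4"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 150, 5000, 100],
            "gene": ["GENEA", "GENEA", "GENEB", ""],
            "region_class": ["promoter", "body", "body", "intergenic"],
        }
    ).set_index("probe_id")
    return ProbeAnnotation(entries=ent)
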