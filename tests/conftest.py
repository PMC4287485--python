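import numpy as np
import pandas as pd
import pytest

from methylseg.io import MethylomeTable, SamplePool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(rows, sample_id="s", replicate_id="r1"):
    """Build a MethylomeTable from (chrom, pos, strand, ctx, meth, total) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
    )
    df["qual_ok"] = True
    return MethylomeTable(df, sample_id=sample_id, replicate_id=replicate_id)


def make_pool(acc_id, tables):
    return SamplePool(accession_id=acc_id, replicates=list(tables))


@pytest.fixture
def simple_table():
    rows = [
        ("chr1", p, "+", ctx, m, t)
        for p, ctx, m, t in [
            (10, "CG", 8, 10),
            (20, "CHG", 5, 10),
            (30, "CHH", 1, 10),
            (45, "CG", 0, 12),
            (60, "CG", 12, 12),
        ]
    ]
    return make_table(rows)
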