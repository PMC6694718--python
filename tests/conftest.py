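import numpy as np
import pandas as pd
import pytest

from mrkit import GwasRecord, GwasSummaryTable
from mrkit.harmonise import HarmonisedDataset


def make_table(rows, **meta) -> GwasSummaryTable:
    """Build a GwasSummaryTable from (snp, ea, oa, beta, se[, eaf[, pval[, n]]]) tuples."""
    records = []
    for row in rows:
        row = list(row) + [None] * (8 - len(row))
        records.append(GwasRecord(*row))
    return GwasSummaryTable.from_records(records, **meta)


def make_dataset(bx, sx, by, sy, **meta) -> HarmonisedDataset:
    return HarmonisedDataset.from_arrays(bx, sx, by, sy, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """10 valid instruments, true slope 0.5, modest outcome noise."""
    L = 10
    bx = rng.uniform(0.05, 0.2, L)
    sx = np.full(L, 0.005)
    sy = rng.uniform(0.01, 0.05, L)
    by = 0.5 * bx + rng.normal(0, sy)
    return make_dataset(bx, sx, by, sy)


@pytest.fixture
def tsv_writer(tmp_path):
    def write(name, header, rows, sep="\t"):
        path = tmp_path / name
        lines = [sep.join(header)]
        lines += [sep.join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path
    return write
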