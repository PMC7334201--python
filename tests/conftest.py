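import numpy as np
import pandas as pd
import pytest

from reelscreen import (
    CountMatrix,
    LibraryDefinition,
    SnpRecord,
)


@pytest.fixture
def small_lib() -> LibraryDefinition:
    """Three SNPs: two biallelic and one tri-allelic."""
    return LibraryDefinition(
        records=[
            SnpRecord("rs1", "FGFR2", ("C", "T"), "C", "A" * 15, "G" * 15),
            SnpRecord("rs2", "MAP3K1", ("A", "G"), "G", "T" * 15, "C" * 15),
            SnpRecord("rs3", "BABAM1", ("A", "C", "G"), "A", "AC" * 7 + "A", "GT" * 7 + "G"),
        ]
    )


def build_count_matrix(rows, cycles=(1, 4, 7, 10), conditions=("control", "sample"),
                       replicates=(1, 2, 3, 4, 5), fill=10):
    """CountMatrix with constant `fill` unless overridden via a dict
    {(snp, allele, cycle, condition, replicate): count}."""
    overrides = {}
    if isinstance(rows, dict):
        overrides = rows
        rows = sorted({(s, a) for (s, a, *_ ) in rows})
    idx = pd.MultiIndex.from_tuples(rows, names=["snp_id", "allele"])
    cols = pd.MultiIndex.from_product(
        [cycles, conditions, replicates], names=["cycle", "condition", "replicate"]
    )
    df = pd.DataFrame(fill, index=idx, columns=cols, dtype=float)
    for (s, a, c, cond, r), v in overrides.items():
        df.loc[(s, a), (c, cond, r)] = v
    return CountMatrix(df=df)


@pytest.fixture
def uniform_cm(small_lib):
    rows = small_lib.sequence_index()
    return build_count_matrix(rows, fill=10)
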