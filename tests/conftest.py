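import numpy as np
import pandas as pd
import pytest

from uniparent.sequence_io import HaploidAlignment, SampleTable


def make_alignment(rows: dict[str, str], marker: str = "mtDNA",
                   positions=None) -> HaploidAlignment:
    """Build an alignment from {sample_id: sequence string}."""
    ids = list(rows)
    matrix = np.array([list(s) for s in rows.values()], dtype="U1")
    if positions is None:
        positions = np.arange(1, matrix.shape[1] + 1)
    return HaploidAlignment(ids, np.asarray(positions), matrix, marker)


def make_table(sample_ids, groups, marker: str = "mtDNA") -> SampleTable:
    """Metadata table from 'Country:Route' group labels."""
    country = [g.split(":")[0] for g in groups]
    route = [g.split(":")[1] if ":" in g else g for g in groups]
    return SampleTable(pd.DataFrame({
        "sample_id": list(sample_ids),
        "marker": marker,
        "country": country,
        "route": route,
    }))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_alignment(rng, n, L, alphabet="ACGT", marker="mtDNA") -> HaploidAlignment:
    mat = rng.choice(list(alphabet), size=(n, L))
    ids = [f"s{i}" for i in range(n)]
    return HaploidAlignment(ids, np.arange(1, L + 1), mat.astype("U1"), marker)
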