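import numpy as np
import pandas as pd
import pytest

from micronet.phylo_metrics import parse_newick
from micronet.sample_io import ReadMatrix, SampleRecord


def make_matrix(rows, taxa=None, carrier="tick", biotope="forest"):
    """Build a ReadMatrix from {sample_id: {taxon: count}} dicts."""
    records = []
    for sid, spec in rows.items():
        meta = spec.pop("_meta", {})
        records.append(
            SampleRecord(
                sample_id=sid,
                carrier=meta.get("carrier", carrier),
                biotope=meta.get("biotope", biotope),
                sex=meta.get("sex", "F"),
                counts=spec,
            )
        )
    return ReadMatrix.from_records(records, taxa=taxa)


@pytest.fixture
def tiny_matrix():
    return make_matrix(
        {
            "s1": {"a": 5, "b": 2},
            "s2": {"a": 7, "b": 1},
            "s3": {"a": 3, "c": 9},
        },
        taxa=["a", "b", "c"],
    )


@pytest.fixture
def balanced_tree4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
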