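import numpy as np
import pandas as pd
import pytest

from ibdscape import Cohort, GenomeMap, IBDSegment


@pytest.fixture
def small_genome():
    """Two short chromosomes so censoring effects are exercised."""
    return GenomeMap({"1": 1.0, "2": 0.6})


@pytest.fixture
def tiny_cohort():
    table = pd.DataFrame(
        {
            "group": ["AFR", "AFR", "AFR", "EUR", "EUR"],
            "region_residence": ["South", "South", "North", "South", "North"],
            "region_birth": ["South", "South", "South", "South", "North"],
            "x": [0.0, 10.0, 300.0, 5.0, 305.0],
            "y": [0.0, 0.0, 400.0, 0.0, 400.0],
        },
        index=pd.Index(["a1", "a2", "a3", "e1", "e2"], name="id"),
    )
    return Cohort(table)


def make_segment(id_a="a1", id_b="a2", chrom="1", start=0.0, length=20.0):
    return IBDSegment(
        id_a=id_a, id_b=id_b, chrom=chrom,
        start=start, end=start + length, length=length,
    )


@pytest.fixture
def seg_factory():
    return make_segment
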