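import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from quadscreen.screens import CountMatrix, LibraryAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    counts = pd.DataFrame(
        {"T0": [100, 400, 250], "T14_rep1": [50, 800, 250], "T14_rep2": [60, 700, 240]},
        index=pd.Index(["c1", "c2", "c3"], name="construct_id"),
    )
    meta = pd.DataFrame(
        {
            "role": ["T0", "endpoint", "endpoint"],
            "timepoint": ["T0", "T14", "T14"],
            "replicate": ["T0", "rep1", "rep2"],
        },
        index=["T0", "T14_rep1", "T14_rep2"],
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture
def pair_library():
    """Two-spacer paralog library: singletons both ways + pair constructs."""
    dr = "TAATTTCTACTATTGTAGAT"
    records = []

    def add(cid, targets, cls, orientation, s):
        records.append(
            dict(construct_id=cid, spacers=s, drs=(dr,), targets=targets,
                 construct_class=cls, control_type="none", orientation=orientation)
        )

    add("A_N_0", ("KRAS",), "single", "gene_N", ("ACGTACGTACGTACGTACGA", "CCGGCCGGCCGGCCGGCCGG"))
    add("N_A_0", ("KRAS",), "single", "N_gene", ("GGCCGGCCGGCCGGCCGGCC", "ACGTACGTACGTACGTACGA"))
    add("A_B_0", ("KRAS", "NRAS"), "pair", "A_B", ("ACGTACGTACGTACGTACGA", "TGCATGCATGCATGCATGCA"))
    return LibraryAnnotation.from_records(records)
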