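import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import reinfiso as rf
from reinfiso.trial_io import Behavior, Context, Sex, StreamBehaviorCount, Target

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_like():
    """Study-condition synthetic dataset, fixed seed."""
    return rf.make_paper_like_dataset(1)


@pytest.fixture(scope="session")
def sop_recs(paper_like):
    return rf.sop_records(paper_like.trials)


def make_counts(rows):
    """rows: (replicate, population, context, species, behavior, target, count)."""
    return [
        StreamBehaviorCount(r, p, Context(c), s, Behavior(b), Target(t), n)
        for (r, p, c, s, b, t, n) in rows
    ]


@pytest.fixture()
def single_group_counts():
    """One population x species, 3 replicates of one behavior:
    conspecific {40, 44, 49} (mean 44.33), heterospecific {0, 6, 12} (mean 6)."""
    rows = []
    for i, (c, h) in enumerate([(40, 0), (44, 6), (49, 12)], start=1):
        rows.append((f"R{i}", "LC", "sympatric", "E. zonale", "chase_mf", "conspecific", c))
        rows.append((f"R{i}", "LC", "sympatric", "E. zonale", "chase_mf", "heterospecific", h))
    return make_counts(rows)
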