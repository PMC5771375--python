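import numpy as np
import pandas as pd
import pytest

from magdiff.wiener import DiffusionParams


#: Control-group symbolic-task parameter set used throughout as a realistic
#: operating point (high accuracy, ~1 s median RT).
CON_SYMBOLIC = DiffusionParams(a=1.5, v=2.44, t0=0.73, st0=0.23)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def con_symbolic():
    return CON_SYMBOLIC


def make_trials(
    subject_id="s1",
    group="con",
    task="symbolic",
    rts=(0.5, 1.0, 1.5),
    correct=None,
    item_start=1,
):
    """Small hand-built trial table in the standard schema."""
    rts = list(rts)
    if correct is None:
        correct = [1] * len(rts)
    n = len(rts)
    return pd.DataFrame(
        {
            "subject_id": [subject_id] * n,
            "group": [group] * n,
            "task": [task] * n,
            "item_index": list(range(item_start, item_start + n)),
            "left_value": [3] * n,
            "right_value": [7] * n,
            "n1": [np.nan] * n,
            "n2": [np.nan] * n,
            "ratio_bin": [np.nan] * n,
            "size_control": [np.nan] * n,
            "correct": list(correct),
            "rt_s": rts,
        }
    )
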