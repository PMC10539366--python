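import numpy as np
import pandas as pd
import pytest

from immffl.cohort import ExpressionCohort


@pytest.fixture
def tiny_cohort():
    """4 features x 6 samples of raw counts, two groups, two batches."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.poisson(50, size=(4, 6)),
        index=[f"G{i}" for i in range(4)],
        columns=[f"S{i}" for i in range(6)],
    )
    annot = pd.DataFrame(
        {
            "group": ["tumor"] * 3 + ["normal"] * 3,
            "batch": [1, 2, 1, 2, 1, 2],
        },
        index=values.columns,
    )
    return ExpressionCohort(values, annot)


def make_cohort(values, groups, batches=None):
    values = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"G{i}" for i in range(len(values))],
        columns=[f"S{i}" for i in range(len(groups))],
    )
    annot = pd.DataFrame({"group": list(groups)}, index=values.columns)
    if batches is not None:
        annot["batch"] = list(batches)
    return ExpressionCohort(values, annot)
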