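import numpy as np
import pandas as pd
import pytest

from cnvtract.penetrance import assign_scores


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cohort(n_carriers_labels=None, n_controls=8, seed=0):
    """Small synthetic cohort table with covariates and scores."""
    if n_carriers_labels is None:
        n_carriers_labels = ["22q11.2 deletion"] * 3 + ["1q21.1 deletion"] * 3 \
            + ["3q29 deletion"] * 2
    rng = np.random.default_rng(seed)
    labels = list(n_carriers_labels) + ["control"] * n_controls
    df = pd.DataFrame({
        "cnv_label": labels,
        "age": rng.normal(38, 10, len(labels)).clip(18, 65),
        "gender": rng.choice(["M", "F"], len(labels)),
        "total_brain_volume": rng.normal(1.1e6, 1e5, len(labels)),
        "motion_index": np.abs(rng.normal(0, 1, len(labels))),
    }, index=pd.Index([f"sub-{i:03d}" for i in range(len(labels))],
                      name="subject"))
    return assign_scores(df)


@pytest.fixture
def small_cohort():
    return make_cohort()
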