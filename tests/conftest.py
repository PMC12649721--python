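import numpy as np
import pandas as pd
import pytest

import devnorm as dn


def make_table(ages, values, sex=0, hand=0, parameter="param"):
    """Small long-format cohort slice for direct fitting tests."""
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    return pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "age": ages,
        "sex": np.broadcast_to(sex, n).astype(int),
        "hand": np.broadcast_to(hand, n).astype(int),
        "parameter": parameter,
        "value": np.asarray(values, dtype=float),
    })


@pytest.fixture(scope="session")
def rt_cohort():
    """Study-conditions cohort: 288 participants, both hands, reaction-time truth."""
    skel = dn.generate_cohort(dn.study_demographics(seed=11))
    return dn.simulate_parameter(skel, dn.STUDY_TRUTHS["reaction_time"],
                                 "reaction_time", seed=12)


@pytest.fixture(scope="session")
def rt_result(rt_cohort):
    return dn.run_pipeline(rt_cohort, "reaction_time", dn.PipelineConfig(seed=13))
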