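import numpy as np
import pandas as pd
import pytest

from nof1steps.design import TrialDesign
from nof1steps.simulate import SimulationParams


@pytest.fixture
def design():
    return TrialDesign()


@pytest.fixture
def quiet_params():
    """No covariate effects, no treatment effects, no day noise, full wear."""
    return SimulationParams(
        weekday_log_effect=0.0,
        temp_log_effect=0.0,
        treatment_daily_effect={"YOGA": 0.0, "MASSAGE": 0.0},
        ar1_rho=0.0,
        daily_sd=0.0,
        wear_prob_profile=np.ones(1440),
        carry_prob=0.0,
    )


def make_classified(day_minute_value):
    """Classified-minute frame from {(day, minute): resolved_steps} (NaN = MISSING)."""
    rows = []
    for (day, minute), value in day_minute_value.items():
        rows.append(
            {
                "participant_id": "P001",
                "day_index": day,
                "minute": minute,
                "resolved_steps": value,
                "wear": "MISSING" if np.isnan(value) else "WORN",
            }
        )
    return pd.DataFrame(rows)


def make_covariates(days, weekday=None, temperature=None):
    days = list(days)
    return pd.DataFrame(
        {
            "day_index": days,
            "weekday": weekday if weekday is not None else [1] * len(days),
            "temperature_f": temperature if temperature is not None else [60.0] * len(days),
        }
    )
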