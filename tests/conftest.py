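import numpy as np
import pandas as pd
import pytest

from perfusim import ProcessParameters
from perfusim.monte_carlo import IterationTrace


@pytest.fixture
def short_params():
    """Small, fast configuration sharing the reference study geometry."""
    return ProcessParameters(duration=2.0, n_iterations=3, seed=11)


@pytest.fixture
def fc_short(short_params):
    from dataclasses import replace

    return replace(short_params, controller="FC")


def make_trace(t, x, params=None, **columns):
    """Fabricate a minimal IterationTrace for analytics-level tests."""
    params = params or ProcessParameters()
    n = len(t)
    frame = pd.DataFrame(
        {
            "t_days": np.asarray(t, dtype=float),
            "X_MVCml": np.asarray(x, dtype=float),
            "c_gL": columns.get("c", np.full(n, 0.4)),
            "P_vvd": np.full(n, 2.0),
            "B_vvd": np.full(n, 0.2),
            "H_vvd": np.full(n, 1.8),
            "b_m_Lday": np.full(n, 2.0),
            "f_vol_Lday": np.full(n, 20.0),
            "h_vol_Lday": np.full(n, 18.0),
            "h_flow_mLmin": np.full(n, 12.5),
            "mu_draw": np.full(n, 0.2),
            "qp_draw": np.full(n, 20.0),
            "e_MVCml": 40.0 - np.asarray(x, dtype=float),
            "X_pred_MVCml": np.nan,
            "X_diff_MVCml": np.nan,
            "J_cost": np.nan,
        }
    )
    return IterationTrace(frame=frame, params=params, seed_entropy=0)
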