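import numpy as np
import pandas as pd
import pytest

import riskychoice as rc


def make_trials(records) -> pd.DataFrame:
    """Build a trials table from per-trial dicts, filling derived columns."""
    df = pd.DataFrame(records)
    df["trial_index"] = np.arange(len(df))
    df["n_flashes_risky"] = np.rint(10 * df["risky_prob"]).astype(int)
    safe_right = df["safe_side"] == "right"
    df["click_rate_left"] = np.where(safe_right, df["risky_volume"], df["safe_volume"])
    df["click_rate_right"] = np.where(safe_right, df["safe_volume"], df["risky_volume"])
    df["chose_safe"] = df["choice_side"] == df["safe_side"]
    df["reward_volume"] = np.where(
        df["rewarded"],
        np.where(df["chose_safe"], df["safe_volume"], df["risky_volume"]), 0.0)
    if "laser_epoch" not in df:
        df["laser_epoch"] = "none"
    if "iti_s" not in df:
        df["iti_s"] = 3.0
    return df


@pytest.fixture
def six_trial_fixture() -> pd.DataFrame:
    """Hand-constructed 6-trial session.

    Post-risky-reward current trials: t1, t3 is NOT (t2 unrewarded) -- the two
    post-risky-reward trials are t1 and t2, both choosing risky (0/2 safe);
    the two post-safe-reward trials are t4 and t5, both choosing safe (2/2).
    Risky win-stay value is therefore exactly 1.0.
    """
    rows = [
        # t0: risky right, rewarded
        dict(safe_side="left", safe_volume=12, risky_volume=48, risky_prob=0.5,
             choice_side="right", rewarded=True),
        # t1: post-risky-reward, chose risky (left), rewarded
        dict(safe_side="right", safe_volume=12, risky_volume=24, risky_prob=0.8,
             choice_side="left", rewarded=True),
        # t2: post-risky-reward, chose risky (right), unrewarded
        dict(safe_side="left", safe_volume=12, risky_volume=48, risky_prob=0.5,
             choice_side="right", rewarded=False),
        # t3: post-risky-unrewarded (excluded), chose safe (left)
        dict(safe_side="left", safe_volume=12, risky_volume=6, risky_prob=0.2,
             choice_side="left", rewarded=True),
        # t4: post-safe-reward, chose safe (right)
        dict(safe_side="right", safe_volume=12, risky_volume=12, risky_prob=0.5,
             choice_side="right", rewarded=True),
        # t5: post-safe-reward, chose safe (left)
        dict(safe_side="left", safe_volume=12, risky_volume=6, risky_prob=0.1,
             choice_side="left", rewarded=True),
    ]
    return make_trials(rows)


@pytest.fixture
def winstay_fixture() -> pd.DataFrame:
    """9 risky-only trials: repeat after every reward, switch after every
    non-reward, rewards alternating; overall repeat rate 0.5 by construction,
    so spatial win-stay = lose-switch = 0.5 exactly."""
    sides = ["left", "left", "right", "right", "left", "left", "right",
             "right", "left"]
    rewards = [True, False, True, False, True, False, True, False, True]
    rows = [
        dict(safe_side="right" if s == "left" else "left", safe_volume=12,
             risky_volume=24, risky_prob=0.5, choice_side=s, rewarded=r)
        for s, r in zip(sides, rewards)
    ]
    return make_trials(rows)


@pytest.fixture
def biased_agent() -> rc.AgentParams:
    return rc.AgentParams(w_ev=0.1, w_rs_hyst=0.3, w_risky_winstay=0.8,
                          w_lr_hyst=0.4, w_lr_bias=-0.2)
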