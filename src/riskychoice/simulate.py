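"""Synthetic task, agent, spiking-population, and waveform-drift generators.

Everything downstream of this module (bias estimators, choice models, the d'
machinery, tensor decomposition, unit tracking) is exercised on data produced
here, with planted ground truth returned alongside so recovery can be checked.
All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .choice_model import expected_values, history_regressors
from .config import (
    AgentParams,
    ConfigurationError,
    NeuralConfig,
    TaskConfig,
    WaveformSimConfig,
)

logger = logging.getLogger(__name__)

TRIALS_COLUMNS = [
    "trial_index", "safe_side", "safe_volume", "risky_volume", "risky_prob",
    "n_flashes_risky", "click_rate_left", "click_rate_right", "choice_side",
    "chose_safe", "rewarded", "reward_volume", "laser_epoch", "iti_s",
]


def generate_offers(n_trials: int, config: TaskConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a session of safe-versus-risky offers (choices unset).

    Volumes are sampled uniformly and independently from ``config.volumes`` for
    each side; the risky probability is uniform on ``config.prob_grid``; the
    safe side is Bernoulli(``p_safe_side_right``). The flash count is
    ``round(flash_max * p)`` and each side's click rate numerically equals its
    volume in uL.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)

    volumes = np.asarray(config.volumes, float)
    probs = np.asarray(config.prob_grid, float)
    safe_volume = rng.choice(volumes, size=n_trials)
    risky_volume = rng.choice(volumes, size=n_trials)
    risky_prob = rng.choice(probs, size=n_trials)
    safe_right = rng.random(n_trials) < config.p_safe_side_right

    df = pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "safe_side": np.where(safe_right, "right", "left"),
        "safe_volume": safe_volume,
        "risky_volume": risky_volume,
        "risky_prob": risky_prob,
        "n_flashes_risky": np.rint(config.flash_max * risky_prob).astype(int),
        "click_rate_left": np.where(safe_right, risky_volume, safe_volume),
        "click_rate_right": np.where(safe_right, safe_volume, risky_volume),
        "choice_side": "",
        "chose_safe": False,
        "rewarded": False,
        "reward_volume": 0.0,
        "laser_epoch": "none",
        "iti_s": np.nan,
    })
    df.attrs["task_config"] = config
    return df


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_agent(offers: pd.DataFrame, params: AgentParams, seed: int = 0,
                   config: TaskConfig | None = None) -> pd.DataFrame:
    """Simulate the biased agent's choices, outcomes, laser epochs and ITIs.

    The choice rule is the generative counterpart of the fitted logistic model:
    p(choose right) = lapse/2 + (1 - lapse) * logistic(w . x), with the
    regressor coding shared with :func:`build_design_matrix`. Risky choices pay
    the risky volume with the offered probability; safe choices always pay the
    safe volume. Laser epochs are assigned independently per trial at the
    configured fractions; inter-trial intervals are log-normal, floored at
    ``laser_min_iti`` after a choice-report-laser trial.
    """
    config = config or offers.attrs.get("task_config") or TaskConfig()
    rng = np.random.default_rng(seed)
    n = len(offers)

    # laser epoch assignment
    u = rng.random(n)
    laser = np.where(
        u < config.laser_frac_cue, "cue",
        np.where(u < config.laser_frac_cue + config.laser_frac_choice,
                 "choice_report", "none"),
    )
    iti = np.exp(rng.normal(np.log(config.iti_median_s), config.iti_sigma, size=n))
    iti = np.where(laser == "choice_report", np.maximum(iti, config.laser_min_iti), iti)

    ev_left, ev_right = expected_values(offers)
    safe_right = offers["safe_side"].to_numpy() == "right"
    risky_prob = offers["risky_prob"].to_numpy(float)
    safe_volume = offers["safe_volume"].to_numpy(float)
    risky_volume = offers["risky_volume"].to_numpy(float)

    choice_right = np.zeros(n, dtype=bool)
    chose_safe = np.zeros(n, dtype=bool)
    rewarded = np.zeros(n, dtype=bool)
    reward_volume = np.zeros(n)

    choice_noise = rng.random(n)
    lapse_roll = rng.random(n)
    lapse_side = rng.random(n)
    reward_roll = rng.random(n)

    for k in range(n):
        if k == 0:
            x_lr = x_rs = x_rws = 0.0
        else:
            x_lr, x_rs, x_rws = history_regressors(
                choice_right[k - 1], chose_safe[k - 1], rewarded[k - 1],
                safe_right[k],
            )
            x_lr, x_rs, x_rws = float(x_lr), float(x_rs), float(x_rws)
            if params.lr_hyst_iti_tau is not None:
                x_lr *= np.exp(-iti[k - 1] / params.lr_hyst_iti_tau)

        w_rws = params.w_risky_winstay
        if k > 0 and x_rws != 0.0:
            if (params.w_risky_winstay_post_laser is not None
                    and laser[k - 1] == "choice_report"):
                w_rws = params.w_risky_winstay_post_laser
            w_rws = w_rws + params.w_rws_prob_slope * (1.0 - risky_prob[k - 1])

        eta = (params.w_ev * (ev_right[k] - ev_left[k])
               + params.w_rs_hyst * x_rs
               + w_rws * x_rws
               + params.w_lr_hyst * x_lr
               + params.w_lr_bias)
        if lapse_roll[k] < params.lapse:
            right = lapse_side[k] < 0.5
        else:
            right = choice_noise[k] < _logistic(eta)
        choice_right[k] = right
        chose_safe[k] = right == safe_right[k]
        if chose_safe[k]:
            rewarded[k] = True
            reward_volume[k] = safe_volume[k]
        else:
            rewarded[k] = reward_roll[k] < risky_prob[k]
            reward_volume[k] = risky_volume[k] if rewarded[k] else 0.0

    out = offers.copy()
    out["choice_side"] = np.where(choice_right, "right", "left")
    out["chose_safe"] = chose_safe
    out["rewarded"] = rewarded
    out["reward_volume"] = reward_volume
    out["laser_epoch"] = laser
    out["iti_s"] = iti
    out.attrs["task_config"] = config
    out.attrs["agent_params"] = params
    return out


def simulate_session(n_trials: int, params: AgentParams,
                     config: TaskConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Offers plus agent choices in one call (independent sub-seeds)."""
    ss = np.random.SeedSequence(seed).spawn(2)
    offers = generate_offers(n_trials, config, seed=ss[0])
    return simulate_agent(offers, params, seed=ss[1], config=config)


# ---------------------------------------------------------------------------
# Poisson population
# ---------------------------------------------------------------------------

@dataclass
class PopulationRecording:
    """Synthetic spikes with alignment events and planted ground truth.

    ``spikes`` has columns (unit_id, session_id, time_s); ``events`` has
    columns (trial_index, event, time_s) with events ``trial_init`` and
    ``center_exit``; ``truth`` maps each unit to its planted selectivity
    labels; ``trial_gain`` is the planted across-trial gain vector g_k.
    """

    spikes: pd.DataFrame
    events: pd.DataFrame
    trials: pd.DataFrame
    truth: dict
    trial_gain: np.ndarray
    session_id: int = 0


def _transient(t: np.ndarray) -> np.ndarray:
    """Unit-amplitude trial-initiation transient (Gaussian bump at 250 ms)."""
    return np.exp(-0.5 * ((t - 0.25) / 0.15) ** 2)


def simulate_population(behavior: pd.DataFrame, config: NeuralConfig | None = None,
                        seed: int = 0, dt: float = 0.002,
                        session_id: int = 0) -> PopulationRecording:
    """Simulate an inhomogeneous-Poisson population over one behavioral session.

    Rate model per unit and trial k (time t relative to trial initiation):
    ``g_k * [baseline + A * transient(t) * (1 + h * 1{prev unrewarded}) +
    S * 1{selectivity condition} * bump(t - t_exit)]`` where
    ``g_k = 1 - gamma * 1{prev rewarded} + noise`` is a planted rank-1
    across-trial gain shared by all units. Negative instantaneous rates are
    clipped to zero and logged.
    """
    if len(behavior) == 0:
        raise ValueError("behavior must contain at least one trial")
    config = config or NeuralConfig()
    rng = np.random.default_rng(seed)
    n_trials = len(behavior)

    # per-trial alignment events; cue period 2.6-3.35 s, report 0.5 s, then ITI
    cue_dur = rng.uniform(2.6, 3.35, size=n_trials)
    iti = behavior["iti_s"].to_numpy(float)
    iti = np.where(np.isfinite(iti), iti, 3.0)
    t_init = np.concatenate([[1.0], 1.0 + np.cumsum(cue_dur + 0.5 + iti)[:-1]])
    t_exit = t_init + cue_dur

    events = pd.DataFrame({
        "trial_index": np.repeat(np.arange(n_trials), 2),
        "event": ["trial_init", "center_exit"] * n_trials,
        "time_s": np.column_stack([t_init, t_exit]).ravel(),
    })

    prev_rewarded = np.concatenate([[False], behavior["rewarded"].to_numpy(bool)[:-1]])
    chose_right = behavior["choice_side"].to_numpy() == "right"
    chose_safe = behavior["chose_safe"].to_numpy(bool)
    rewarded = behavior["rewarded"].to_numpy(bool)

    g = 1.0 - config.trial_gain_gamma * prev_rewarded.astype(float)
    g = g + rng.normal(0.0, config.gain_noise_sd, size=n_trials)

    # unit property assignment
    nu = config.n_units
    has_history = rng.random(nu) < config.frac_history
    has_side = rng.random(nu) < config.frac_side
    has_risk = rng.random(nu) < config.frac_risk
    has_reward = rng.random(nu) < config.frac_reward
    silent = rng.random(nu) < config.frac_silent
    side_pref = np.where(rng.random(nu) < 0.5, "right", "left")
    risk_pref = np.where(rng.random(nu) < 0.5, "risky", "safe")
    reward_pref = np.where(rng.random(nu) < 0.5, "rewarded", "unrewarded")

    truth = {
        int(u): {
            "has_history": bool(has_history[u]),
            "has_side": bool(has_side[u]), "side_pref": str(side_pref[u]),
            "has_risk": bool(has_risk[u]), "risk_pref": str(risk_pref[u]),
            "has_reward": bool(has_reward[u]), "reward_pref": str(reward_pref[u]),
            "silent": bool(silent[u]),
        }
        for u in range(nu)
    }

    window_lo, window_hi = -1.0, 2.0  # around init and after exit, resp.
    n_clipped = 0
    unit_ids, times = [], []
    for u in range(nu):
        if silent[u]:
            continue
        for k in range(n_trials):
            # simulate from 1 s before init to 2 s after center exit
            t0, t1 = t_init[k] + window_lo, t_exit[k] + window_hi
            tt = np.arange(t0, t1, dt)
            rel_init = tt - t_init[k]
            rel_exit = tt - t_exit[k]

            amp = config.transient_amp_hz
            if has_history[u]:
                amp = amp * (1.0 + config.history_gain * (not prev_rewarded[k]))
            rate = config.baseline_hz + amp * _transient(rel_init)

            sel = 0.0
            if has_side[u] and (chose_right[k] == (side_pref[u] == "right")):
                sel += config.selectivity_amp_hz
            if has_risk[u] and rewarded[k] and \
                    ((not chose_safe[k]) == (risk_pref[u] == "risky")):
                sel += config.selectivity_amp_hz
            if has_reward[u] and (rewarded[k] == (reward_pref[u] == "rewarded")):
                sel += config.selectivity_amp_hz
            if sel:
                rate = rate + sel * np.exp(-0.5 * ((rel_exit - 0.4) / 0.25) ** 2)

            rate = rate * g[k]
            neg = rate < 0
            if neg.any():
                n_clipped += int(neg.sum())
                rate = np.clip(rate, 0.0, None)

            counts = rng.poisson(rate * dt)
            spike_bins = np.nonzero(counts)[0]
            for b in spike_bins:
                for _ in range(counts[b]):
                    unit_ids.append(u)
                    times.append(tt[b] + rng.uniform(0, dt))
    if n_clipped:
        logger.info("clipped %d negative-rate samples to 0", n_clipped)

    spikes = pd.DataFrame({
        "unit_id": np.asarray(unit_ids, int),
        "session_id": session_id,
        "time_s": np.asarray(times, float),
    }).sort_values(["unit_id", "time_s"], kind="stable").reset_index(drop=True)
    return PopulationRecording(spikes=spikes, events=events, trials=behavior,
                               truth=truth, trial_gain=g, session_id=session_id)


# ---------------------------------------------------------------------------
# Tetrode waveforms
# ---------------------------------------------------------------------------

def make_base_template(config: WaveformSimConfig | None = None, seed: int = 0
                       ) -> np.ndarray:
    """Random spike-like 4-channel template (trough plus after-hyperpolarization).

    Channel amplitudes are log-normal; the trough width and the relative
    after-hump vary per unit so that templates of different units differ in
    shape, not only in amplitude.
    """
    config = config or WaveformSimConfig()
    rng = np.random.default_rng(seed)
    s = np.arange(config.n_samples)
    trough = config.n_samples * rng.uniform(0.28, 0.42)
    width = config.n_samples * rng.uniform(0.05, 0.12)
    hump_amp = rng.uniform(0.2, 0.5)
    hump_pos = trough + width * rng.uniform(2.0, 3.5)
    shape = (-np.exp(-0.5 * ((s - trough) / width) ** 2)
             + hump_amp * np.exp(-0.5 * ((s - hump_pos) / (2.0 * width)) ** 2))
    amps = np.exp(rng.normal(0.0, 0.6, size=4))
    return amps[:, None] * shape[None, :]


def simulate_waveform_drift(base: np.ndarray, n_sessions: int,
                            config: WaveformSimConfig | None = None,
                            seed: int = 0) -> list[np.ndarray]:
    """Per-session templates of one unit under amplitude drift and shape noise.

    Session s template = per-channel scale ``exp(N(0, amp_drift_sd))`` times the
    base template, plus i.i.d. Gaussian shape noise. Session 0 is the base.
    """
    base = np.asarray(base, float)
    if base.shape[0] != 4:
        raise ValueError("waveform template must have exactly 4 channels")
    config = config or WaveformSimConfig()
    rng = np.random.default_rng(seed)
    out = [base.copy()]
    for _ in range(1, n_sessions):
        scales = np.exp(rng.normal(0.0, config.amp_drift_sd, size=4))
        noisy = scales[:, None] * base + rng.normal(
            0.0, config.shape_jitter_sd, size=base.shape)
        out.append(noisy)
    return out


# ---------------------------------------------------------------------------
# Writers (external interface: plain CSV/JSON)
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.loc[:, TRIALS_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["chose_safe"] = df["chose_safe"].astype(bool)
    df["rewarded"] = df["rewarded"].astype(bool)
    return df


def write_recording(rec: PopulationRecording, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec.spikes.to_csv(outdir / "spikes.csv", index=False)
    rec.events.to_csv(outdir / "events.csv", index=False)
    write_trials(rec.trials, outdir / "trials.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"units": rec.truth,
                   "trial_gain": rec.trial_gain.tolist()}, fh, indent=1)


def write_waveforms(templates: dict[tuple[int, int], np.ndarray],
                    path: str | Path) -> None:
    """Write templates keyed by (unit_id, session_id) in long CSV form."""
    rows = []
    for (unit, session), wf in templates.items():
        wf = np.asarray(wf)
        for ch in range(wf.shape[0]):
            for i, v in enumerate(wf[ch]):
                rows.append((unit, session, ch, i, v))
    pd.DataFrame(rows, columns=["unit_id", "session_id", "channel",
                                "sample_index", "amplitude"]).to_csv(path, index=False)


def read_waveforms(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    df = pd.read_csv(path)
    out: dict[tuple[int, int], np.ndarray] = {}
    for (unit, session), grp in df.groupby(["unit_id", "session_id"]):
        n_ch = grp["channel"].max() + 1
        n_s = grp["sample_index"].max() + 1
        wf = np.zeros((n_ch, n_s))
        wf[grp["channel"], grp["sample_index"]] = grp["amplitude"]
        out[(int(unit), int(session))] = wf
    return out
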