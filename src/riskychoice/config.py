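"""Configuration dataclasses for the task, the agent, and the synthetic recordings.

The task is a cued safe-versus-risky choice: on every trial one side port offers a
guaranteed ("safe") water reward and the other a probabilistic ("risky") one.
Flashes convey the risky probability (0-10 flashes for p = 0 .. 1 in steps of 0.1)
and auditory click rates convey the water volume on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


DEFAULT_VOLUMES = (6.0, 12.0, 24.0, 48.0)
DEFAULT_PROB_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the safe-versus-risky offer generator.

    Parameters
    ----------
    volumes
        Reward volumes (uL) sampled independently for each side.
    prob_grid
        Allowed risky reward probabilities; must be a subset of 0.0, 0.1, ..., 1.0.
    p_safe_side_right
        Probability that the safe port is the right one.
    flash_max
        Maximum flash count; the flash count is ``round(flash_max * p)``.
    click_rate_range
        (lo, hi) Hz. By convention the click rate in Hz numerically equals the
        offered volume in uL (both span 6-48); this field records the range.
    laser_frac_cue, laser_frac_choice
        Fractions of trials receiving cue-period / choice-report laser illumination.
    iti_median_s, iti_sigma
        Log-normal inter-trial-interval parameters (median seconds, log-sd).
    laser_min_iti
        Minimum ITI (s) enforced after a choice-report-laser trial, because the
        laser persists into the inter-trial interval.
    """

    volumes: tuple[float, ...] = DEFAULT_VOLUMES
    prob_grid: tuple[float, ...] = DEFAULT_PROB_GRID
    p_safe_side_right: float = 0.5
    flash_max: int = 10
    click_rate_range: tuple[float, float] = (6.0, 48.0)
    laser_frac_cue: float = 0.0
    laser_frac_choice: float = 0.0
    iti_median_s: float = 3.0
    iti_sigma: float = 0.5
    laser_min_iti: float = 4.0

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ConfigurationError("volumes must be non-empty")
        if not self.prob_grid:
            raise ConfigurationError("prob_grid must be non-empty")
        allowed = set(DEFAULT_PROB_GRID)
        if not set(self.prob_grid) <= allowed:
            raise ConfigurationError(
                "prob_grid must be a subset of {0.0, 0.1, ..., 1.0}"
            )
        if not 0.0 <= self.p_safe_side_right <= 1.0:
            raise ConfigurationError("p_safe_side_right must lie in [0, 1]")
        for frac in (self.laser_frac_cue, self.laser_frac_choice):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("laser fractions must lie in [0, 1]")
        if self.laser_frac_cue + self.laser_frac_choice > 1.0:
            raise ConfigurationError("laser fractions must sum to at most 1")
        if self.laser_min_iti < 0:
            raise ConfigurationError("laser_min_iti must be >= 0")


@dataclass(frozen=True)
class AgentParams:
    """Weights of the generative logistic choice rule.

    The agent chooses right with probability
    ``lapse/2 + (1 - lapse) * logistic(w_ev*dEV + w_rs_hyst*x_rs +
    w_risky_winstay*x_rws + w_lr_hyst*x_lr + w_lr_bias)`` where the regressors
    use the same coding as :func:`riskychoice.choice_model.build_design_matrix`.
    Positive weights mean "choose right / repeat".

    The last three fields are simulation-only hooks, all off by default:
    ``w_risky_winstay_post_laser`` replaces the risky win-stay weight on trials
    following a choice-report-laser trial (planted opto ablation);
    ``w_rws_prob_slope`` adds ``slope * (1 - p_prev)`` to the risky win-stay
    weight, planting a graded dependence on the won gamble's probability;
    ``lr_hyst_iti_tau`` makes side hysteresis decay as ``exp(-iti/tau)`` with the
    inter-trial interval preceding the current trial.
    """

    w_ev: float = 0.0
    w_rs_hyst: float = 0.0
    w_risky_winstay: float = 0.0
    w_lr_hyst: float = 0.0
    w_lr_bias: float = 0.0
    lapse: float = 0.0
    w_risky_winstay_post_laser: float | None = None
    w_rws_prob_slope: float = 0.0
    lr_hyst_iti_tau: float | None = None

    def __post_init__(self) -> None:
        import math

        if not 0.0 <= self.lapse <= 0.5:
            raise ConfigurationError("lapse must lie in [0, 0.5]")
        for name in ("w_ev", "w_rs_hyst", "w_risky_winstay", "w_lr_hyst", "w_lr_bias"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass(frozen=True)
class NeuralConfig:
    """Parameters of the synthetic Poisson population.

    Each unit's instantaneous rate is
    ``g_k * [baseline + transient(t) * (1 + history_gain * 1{prev unrewarded})
    + selectivity terms at choice report]`` with an across-trial gain
    ``g_k = 1 - trial_gain_gamma * 1{prev rewarded} + N(0, gain_noise_sd)``.
    Fractions assign which units carry reward-history modulation and which are
    side-, risk- or reward-selective at the choice report.
    """

    n_units: int = 40
    baseline_hz: float = 5.0
    transient_amp_hz: float = 10.0
    frac_history: float = 0.35
    history_gain: float = 0.5
    frac_side: float = 0.35
    frac_risk: float = 0.2
    frac_reward: float = 0.35
    selectivity_amp_hz: float = 8.0
    trial_gain_gamma: float = 0.15
    gain_noise_sd: float = 0.05
    frac_silent: float = 0.0

    def __post_init__(self) -> None:
        for name in ("frac_history", "frac_side", "frac_risk", "frac_reward", "frac_silent"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("baseline_hz", "transient_amp_hz", "selectivity_amp_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WaveformSimConfig:
    """Parameters of cross-session tetrode-waveform drift.

    A session's template is the base template scaled per channel by
    ``exp(N(0, amp_drift_sd))`` plus i.i.d. shape noise of s.d.
    ``shape_jitter_sd`` (in the same arbitrary units as the template).
    """

    n_samples: int = 32
    amp_drift_sd: float = 0.1
    shape_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ConfigurationError("n_samples must be >= 8")
        if self.amp_drift_sd < 0 or self.shape_jitter_sd < 0:
            raise ConfigurationError("drift standard deviations must be >= 0")
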