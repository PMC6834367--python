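"""Behavioral metrics: choice efficiency, sequential biases, laser comparisons.

Efficiency normalizes the expected value a subject earns per trial between a
random chooser (0.5) and an expected-value maximizer (1.0). Sequential biases
are conditional-probability differences keyed on the previous trial: the risky
win-stay bias (more gambling after a rewarded gamble), and spatial win-stay /
lose-switch biases (repeating a port after reward, switching after no reward).
95% confidence intervals use the normal approximation for a difference of two
binomial proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .choice_model import expected_values

#: 97.5% standard-normal quantile, 5 significant digits (95% two-sided CI).
Z95 = 1.9600


class UndefinedEstimateError(ValueError):
    """A conditional estimator has an empty conditioning set."""


@dataclass
class EfficiencySummary:
    """Per-session expected-value accounting behind the efficiency score."""

    rat_ev_per_trial: float
    rand_ev_per_trial: float
    max_ev_per_trial: float
    efficiency: float
    n_trials: int


@dataclass
class BiasEstimate:
    """A conditional-probability difference with counts and a 95% CI.

    ``value = p1 - p2``; ``delta1``/``delta2`` are each conditional minus the
    unconditional baseline, for bias-versus-baseline style summaries.
    """

    label: str
    p1: float
    n1: int
    p2: float
    n2: int
    value: float
    ci95: float
    baseline: float | None = None

    @property
    def delta1(self) -> float:
        return self.p1 - self.baseline if self.baseline is not None else np.nan

    @property
    def delta2(self) -> float:
        return self.p2 - self.baseline if self.baseline is not None else np.nan

    def __str__(self) -> str:
        base = "" if self.baseline is None else f"  baseline={self.baseline:.3f}"
        return (f"{self.label}: {self.value:+.4f} +/- {self.ci95:.4f} "
                f"(p1={self.p1:.3f} n1={self.n1}, p2={self.p2:.3f} n2={self.n2}){base}")


@dataclass
class GradedBias:
    """Risky win-stay bias per gamble probability with its regression slope."""

    probs: np.ndarray
    estimates: list[BiasEstimate]
    slope: float
    intercept: float


def efficiency_from_evs(rat_ev: float, rand_ev: float, max_ev: float) -> float:
    """efficiency = 0.5 * (ratEV - randEV) / (maxEV - randEV) + 0.5."""
    denom = max_ev - rand_ev
    if denom <= 0:
        raise ValueError(
            "efficiency undefined: the maximizer and the random agent earn the "
            "same expected value (all offers identical across sides)"
        )
    return 0.5 * (rat_ev - rand_ev) / denom + 0.5


def compute_efficiency(trials: pd.DataFrame) -> EfficiencySummary:
    """Session efficiency: chosen EV normalized between random and maximizer.

    ratEV is the mean expected value of the chosen option, randEV the mean of
    the two offers' average, maxEV the mean of the larger offer.
    """
    ev_left, ev_right = expected_values(trials)
    chose_right = trials["choice_side"].to_numpy() == "right"
    rat_ev = float(np.mean(np.where(chose_right, ev_right, ev_left)))
    rand_ev = float(np.mean((ev_left + ev_right) / 2.0))
    max_ev = float(np.mean(np.maximum(ev_left, ev_right)))
    eff = efficiency_from_evs(rat_ev, rand_ev, max_ev)
    return EfficiencySummary(rat_ev, rand_ev, max_ev, eff, len(trials))


def criterion_threshold(session_efficiencies) -> float:
    """Training criterion: median of all sessions minus 1.5 x the IQR of the
    second half of sessions (linear-interpolation quartiles)."""
    eff = np.asarray(session_efficiencies, float)
    if eff.size < 2:
        raise ValueError("criterion threshold requires at least 2 sessions")
    second_half = eff[eff.size // 2:]
    q75, q25 = np.percentile(second_half, [75, 25])
    return float(np.median(eff) - 1.5 * (q75 - q25))


def flag_below_criterion(session_efficiencies) -> np.ndarray:
    """Boolean mask of sessions excluded for falling below the criterion."""
    thr = criterion_threshold(session_efficiencies)
    return np.asarray(session_efficiencies, float) < thr


def binomial_ci(p1: float, n1: int, p2: float, n2: int, z: float = Z95) -> float:
    """Normal-approximation 95% CI half-width for a difference of proportions:
    z * sqrt(p1(1-p1)/n1 + p2(1-p2)/n2)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("binomial_ci requires n1, n2 >= 1")
    return float(z * np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2))


def _prev(arr: np.ndarray) -> np.ndarray:
    """Previous-trial view aligned to current trials (first trial invalid)."""
    out = np.empty_like(arr)
    out[1:] = arr[:-1]
    out[0] = arr[0]
    return out


def _valid_mask(trials: pd.DataFrame, mask) -> np.ndarray:
    """Trials eligible for conditional estimators: not the session's first
    trial, intersected with the caller's mask."""
    m = np.ones(len(trials), dtype=bool) if mask is None else np.asarray(mask, bool)
    m = m.copy()
    m[0] = False
    return m


def _cond_prob(outcome: np.ndarray, cond: np.ndarray) -> tuple[float, int]:
    n = int(cond.sum())
    if n == 0:
        raise UndefinedEstimateError("empty conditioning set")
    return float(outcome[cond].mean()), n


def risky_winstay_bias(trials: pd.DataFrame, mask=None,
                       label: str = "risky_winstay") -> BiasEstimate:
    """P(choose safe | previous rewarded safe) - P(choose safe | previous
    rewarded risky). Negative values mean more gambling after risky wins."""
    m = _valid_mask(trials, mask)
    chose_safe = trials["chose_safe"].to_numpy(bool)
    prev_safe = _prev(chose_safe)
    prev_rew = _prev(trials["rewarded"].to_numpy(bool))

    post_safe_rew = m & prev_safe & prev_rew
    post_risky_rew = m & ~prev_safe & prev_rew
    p1, n1 = _cond_prob(chose_safe, post_safe_rew)
    p2, n2 = _cond_prob(chose_safe, post_risky_rew)
    baseline = float(chose_safe[m].mean())
    return BiasEstimate(label=label, p1=p1, n1=n1, p2=p2, n2=n2,
                        value=p1 - p2, ci95=binomial_ci(p1, n1, p2, n2),
                        baseline=baseline)


def spatial_winstay_lose_switch(trials: pd.DataFrame, mask=None
                                ) -> tuple[BiasEstimate, BiasEstimate]:
    """Win-stay: P(repeat side | prev rewarded) minus the overall repeat rate.
    Lose-switch: P(switch | prev unrewarded) minus the overall switch rate."""
    m = _valid_mask(trials, mask)
    side = trials["choice_side"].to_numpy()
    repeat = side == _prev(side)
    prev_rew = _prev(trials["rewarded"].to_numpy(bool))

    p_rep_base, n_base = _cond_prob(repeat, m)
    p_rep_win, n_win = _cond_prob(repeat, m & prev_rew)
    win_stay = BiasEstimate(
        label="spatial_winstay", p1=p_rep_win, n1=n_win,
        p2=p_rep_base, n2=n_base, value=p_rep_win - p_rep_base,
        ci95=binomial_ci(p_rep_win, n_win, p_rep_base, n_base),
        baseline=p_rep_base,
    )
    p_sw_lose, n_lose = _cond_prob(~repeat, m & ~prev_rew)
    lose_switch = BiasEstimate(
        label="spatial_loseswitch", p1=p_sw_lose, n1=n_lose,
        p2=1.0 - p_rep_base, n2=n_base, value=p_sw_lose - (1.0 - p_rep_base),
        ci95=binomial_ci(p_sw_lose, n_lose, 1.0 - p_rep_base, n_base),
        baseline=1.0 - p_rep_base,
    )
    return win_stay, lose_switch


def graded_winstay_by_prob(trials: pd.DataFrame, mask=None) -> GradedBias:
    """Post-risky-win gambling rate (relative to baseline) per gamble
    probability, with the least-squares slope across probability levels.

    Only probabilities > 0 can yield a risky win, so bins are the positive
    levels present in the data; each bin's value is P(gamble | previous trial
    a rewarded gamble at that probability) minus the overall gambling rate.
    """
    m = _valid_mask(trials, mask)
    chose_safe = trials["chose_safe"].to_numpy(bool)
    gamble = ~chose_safe
    prev_gamble_rew = _prev(gamble) & _prev(trials["rewarded"].to_numpy(bool))
    prev_prob = _prev(trials["risky_prob"].to_numpy(float))
    baseline = float(gamble[m].mean())
    n_base = int(m.sum())

    estimates, probs = [], []
    for p in sorted(set(np.round(prev_prob[m & prev_gamble_rew], 10))):
        if p <= 0:
            continue
        cond = m & prev_gamble_rew & (np.round(prev_prob, 10) == p)
        try:
            p1, n1 = _cond_prob(gamble, cond)
        except UndefinedEstimateError:
            continue
        estimates.append(BiasEstimate(
            label=f"post_risky_win_p={p:g}", p1=p1, n1=n1,
            p2=baseline, n2=n_base, value=p1 - baseline,
            ci95=binomial_ci(p1, n1, baseline, n_base), baseline=baseline,
        ))
        probs.append(p)
    if len(estimates) < 2:
        raise UndefinedEstimateError(
            "graded bias needs at least 2 populated probability bins"
        )
    x = np.asarray(probs)
    y = np.asarray([e.value for e in estimates])
    slope, intercept = np.polyfit(x, y, 1)
    return GradedBias(probs=x, estimates=estimates,
                      slope=float(slope), intercept=float(intercept))


@dataclass
class LaserComparison:
    """Matched bias estimates on post-control versus post-laser trials."""

    epoch: str
    iti_matched: bool
    control: dict[str, BiasEstimate]
    laser: dict[str, BiasEstimate]

    def summary(self) -> str:
        lines = [f"Laser comparison (epoch={self.epoch}, "
                 f"iti_matched={self.iti_matched})"]
        for key in self.control:
            lines.append(f"  control  {self.control[key]}")
            lines.append(f"  laser    {self.laser[key]}")
        return "\n".join(lines)


def laser_comparison(trials: pd.DataFrame, epoch: str = "choice_report",
                     iti_matched: bool = False,
                     min_iti: float = 4.0) -> LaserComparison:
    """Sequential biases on trials following laser versus control trials.

    Trials are grouped by the PREVIOUS trial's laser epoch, because the
    hypotheses concern effects of the perturbation on the next choice. With
    ``iti_matched``, control trials are restricted to those whose previous
    trial's ITI was at least ``min_iti`` seconds, matching the minimum ITI
    imposed after choice-report laser trials.
    """
    if epoch not in ("cue", "choice_report"):
        raise ValueError("epoch must be 'cue' or 'choice_report'")
    prev_epoch = _prev(trials["laser_epoch"].to_numpy())
    if not (prev_epoch == epoch).any():
        raise UndefinedEstimateError(f"no trials with previous laser epoch {epoch!r}")
    laser_mask = prev_epoch == epoch
    control_mask = prev_epoch == "none"
    if iti_matched:
        control_mask = control_mask & (_prev(trials["iti_s"].to_numpy(float)) >= min_iti)

    def _all_biases(mask) -> dict[str, BiasEstimate]:
        ws, ls = spatial_winstay_lose_switch(trials, mask)
        return {"risky_winstay": risky_winstay_bias(trials, mask),
                "spatial_winstay": ws, "spatial_loseswitch": ls}

    return LaserComparison(epoch=epoch, iti_matched=iti_matched,
                           control=_all_biases(control_mask),
                           laser=_all_biases(laser_mask))


def biases_to_frame(estimates: list[BiasEstimate]) -> pd.DataFrame:
    """Long-format table of bias estimates (one row each) for biases.csv."""
    return pd.DataFrame([{
        "label": e.label, "p1": e.p1, "n1": e.n1, "p2": e.p2, "n2": e.n2,
        "value": e.value, "ci95": e.ci95, "baseline": e.baseline,
    } for e in estimates])
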