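"""Single-unit screening, binning/smoothing, and shuffle-corrected d'.

Firing rates are computed in 50 ms bins and smoothed with a 5-point moving
mean. Discriminability between two trial conditions is
|mu1 - mu2| / sqrt((sigma1^2 + sigma2^2) / 2) per time bin; because the
absolute difference is positively biased, the mean of the same statistic over
label shuffles (default 15) is subtracted. Selectivity for a task variable is
assessed with an unpaired t-test on per-trial spike counts in an analysis
window, and population summaries count significant units split by their
preferred condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Analysis windows (s) relative to the alignment event, by variable class.
HISTORY_WINDOW = (0.0, 1.0)   # after trial initiation
REPORT_WINDOW = (0.0, 1.0)    # after center-port exit


@dataclass
class AlignedRates:
    """Trials x time-bins smoothed firing rates for one unit and alignment.

    ``rates`` is in Hz; ``counts`` holds the raw (pre-smoothing) per-bin spike
    counts, whose row sums equal the number of events in the window.
    """

    unit_id: int
    alignment: str
    bin_width: float
    window: tuple[float, float]
    rates: np.ndarray
    counts: np.ndarray
    bin_centers: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]


@dataclass
class SelectivityResult:
    """Outcome of a two-condition selectivity screen for one unit."""

    unit_id: int
    variable: str
    p_value: float
    preferred: str
    mean_rates: dict[str, float]
    dprime_timecourse: np.ndarray
    bin_centers: np.ndarray
    analysis_window: tuple[float, float]

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def matlab_smooth(x: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving mean with shrinking symmetric windows at the edges.

    Matches the convention of shrinking the window near the ends so the first
    and last samples are unchanged: y[0] = x[0], y[1] = mean(x[0:3]), ...
    """
    x = np.asarray(x, float)
    if span <= 1:
        return x.copy()
    if span % 2 == 0:
        span -= 1
    n = x.shape[-1]
    out = np.empty_like(x)
    half = span // 2
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)],
                          axis=-1)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[..., i] = (csum[..., i + h + 1] - csum[..., i - h]) / (2 * h + 1)
    return out


def bin_and_smooth(spike_times: np.ndarray, alignment_events: np.ndarray,
                   window: tuple[float, float], bin_width: float = 0.05,
                   smooth_span: int = 5, unit_id: int = -1,
                   alignment: str = "trial_init") -> AlignedRates:
    """Bin one unit's spikes around per-trial events and smooth to rates.

    Counts per ``bin_width`` bin are converted to Hz then smoothed with a
    centered moving mean of ``smooth_span`` bins.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty analysis window")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        raise ValueError("window shorter than one bin")
    spike_times = np.asarray(spike_times, float)
    events = np.asarray(alignment_events, float)
    counts = np.empty((len(events), len(edges) - 1))
    for k, t0 in enumerate(events):
        counts[k] = np.histogram(spike_times - t0, bins=edges)[0]
    rates = matlab_smooth(counts / bin_width, smooth_span)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AlignedRates(unit_id=unit_id, alignment=alignment,
                        bin_width=bin_width, window=window, rates=rates,
                        counts=counts, bin_centers=centers)


def trial_spike_counts(spike_times: np.ndarray, starts: np.ndarray,
                       stops: np.ndarray) -> np.ndarray:
    """Spike count of one unit in each [start, stop) trial window."""
    spike_times = np.sort(np.asarray(spike_times, float))
    return (np.searchsorted(spike_times, stops)
            - np.searchsorted(spike_times, starts))


def inclusion_filter(spikes: pd.DataFrame, trial_starts: np.ndarray,
                     trial_stops: np.ndarray, min_spikes: int = 2,
                     min_frac: float = 0.5) -> list[int]:
    """Units firing more than ``min_spikes`` spikes on at least ``min_frac`` of
    trials (full-trial windows). Strictly more: a unit with exactly 2 spikes
    per trial is excluded."""
    kept = []
    for unit, grp in spikes.groupby("unit_id"):
        counts = trial_spike_counts(grp["time_s"].to_numpy(), trial_starts,
                                    trial_stops)
        if np.mean(counts > min_spikes) >= min_frac:
            kept.append(int(unit))
    return kept


def selectivity_test(counts: np.ndarray, labels: np.ndarray,
                     condition_names: tuple[str, str] | None = None
                     ) -> tuple[float, str]:
    """Unpaired two-sample t-test on per-trial counts; preferred condition is
    the one with the higher mean."""
    labels = np.asarray(labels)
    conds = condition_names or tuple(sorted(set(labels.tolist())))
    if len(conds) != 2:
        raise ValueError("selectivity_test needs exactly two conditions")
    a = counts[labels == conds[0]]
    b = counts[labels == conds[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs at least 2 trials")
    _, p = stats.ttest_ind(a, b)
    preferred = conds[0] if a.mean() >= b.mean() else conds[1]
    return float(p), str(preferred)


def dprime(rates_a: np.ndarray, rates_b: np.ndarray) -> np.ndarray:
    """Per-bin |mu1 - mu2| / sqrt((var1 + var2)/2); 0 where both vars are 0."""
    mu = np.abs(rates_a.mean(axis=0) - rates_b.mean(axis=0))
    pooled = 0.5 * (rates_a.var(axis=0, ddof=0) + rates_b.var(axis=0, ddof=0))
    out = np.zeros_like(mu)
    nz = pooled > 0
    out[nz] = mu[nz] / np.sqrt(pooled[nz])
    return out


def dprime_timecourse(aligned: AlignedRates, labels: np.ndarray,
                      n_shuffles: int = 15, seed: int = 0) -> np.ndarray:
    """Shuffle-corrected per-bin |d'| between two trial conditions.

    The mean |d'| over ``n_shuffles`` random label permutations is subtracted;
    corrected values may be negative and are not clipped.
    """
    labels = np.asarray(labels)
    conds = sorted(set(labels.tolist()))
    if len(conds) != 2:
        raise ValueError("dprime_timecourse needs exactly two conditions")
    m = labels == conds[0]
    if m.sum() < 2 or (~m).sum() < 2:
        raise ValueError("each condition needs at least 2 trials")
    raw = dprime(aligned.rates[m], aligned.rates[~m])
    rng = np.random.default_rng(seed)
    shuf = np.zeros_like(raw)
    for _ in range(n_shuffles):
        perm = rng.permutation(m)
        shuf += dprime(aligned.rates[perm], aligned.rates[~perm])
    return raw - shuf / n_shuffles


# ---------------------------------------------------------------------------
# Per-variable screening over a population
# ---------------------------------------------------------------------------

def _variable_labels(trials: pd.DataFrame, variable: str
                     ) -> tuple[np.ndarray, np.ndarray, str]:
    """(trial mask, per-trial labels, alignment event) for a screen variable.

    reward_history uses all trials after the first, aligned to trial
    initiation; side/reward use all trials at the choice report;
    risk_choice uses rewarded trials only.
    """
    rewarded = trials["rewarded"].to_numpy(bool)
    chose_safe = trials["chose_safe"].to_numpy(bool)
    side = trials["choice_side"].to_numpy()
    n = len(trials)
    if variable == "reward_history":
        mask = np.ones(n, bool)
        mask[0] = False
        prev_rew = np.empty(n, bool)
        prev_rew[1:] = rewarded[:-1]
        prev_rew[0] = False
        labels = np.where(prev_rew, "prev_rewarded", "prev_unrewarded")
        return mask, labels, "trial_init"
    if variable == "side":
        return np.ones(n, bool), side.astype(str), "center_exit"
    if variable == "reward":
        labels = np.where(rewarded, "rewarded", "unrewarded")
        return np.ones(n, bool), labels, "center_exit"
    if variable == "risk_choice":
        labels = np.where(chose_safe, "safe", "risky")
        return rewarded.copy(), labels, "center_exit"
    raise ValueError(f"unknown selectivity variable {variable!r}")


def screen_selectivity(spikes: pd.DataFrame, events: pd.DataFrame,
                       trials: pd.DataFrame, variable: str,
                       window: tuple[float, float] | None = None,
                       bin_width: float = 0.05, smooth_span: int = 5,
                       n_shuffles: int = 15, seed: int = 0,
                       units: list[int] | None = None
                       ) -> list[SelectivityResult]:
    """Selectivity t-test plus shuffle-corrected d' timecourse for each unit."""
    mask, labels, align = _variable_labels(trials, variable)
    window = window or (HISTORY_WINDOW if align == "trial_init" else REPORT_WINDOW)
    ev = events[events["event"] == align].sort_values("trial_index")
    event_times = ev["time_s"].to_numpy()[mask]
    labels = labels[mask]

    results = []
    unit_ids = units if units is not None else sorted(spikes["unit_id"].unique())
    grouped = dict(tuple(spikes.groupby("unit_id")))
    for u in unit_ids:
        times = grouped[u]["time_s"].to_numpy() if u in grouped else np.array([])
        aligned = bin_and_smooth(times, event_times, window, bin_width,
                                 smooth_span, unit_id=u, alignment=align)
        counts = aligned.counts.sum(axis=1)
        conds = tuple(sorted(set(labels.tolist())))
        try:
            p, pref = selectivity_test(counts, labels, conds)
        except ValueError:
            continue
        dp = dprime_timecourse(aligned, labels, n_shuffles=n_shuffles,
                               seed=seed + u)
        results.append(SelectivityResult(
            unit_id=u, variable=variable, p_value=p, preferred=pref,
            mean_rates={c: float(counts[labels == c].mean())
                        for c in conds},
            dprime_timecourse=dp, bin_centers=aligned.bin_centers,
            analysis_window=window,
        ))
    return results


@dataclass
class PreferenceFractions:
    """Counts of significant units per variable, split by preferred condition."""

    variable: str
    n_units: int
    n_significant: int
    by_preference: dict[str, int]

    @property
    def frac_significant(self) -> float:
        return self.n_significant / self.n_units if self.n_units else np.nan


def preference_fractions(results: list[SelectivityResult],
                         alpha: float = 0.05) -> PreferenceFractions:
    """Fraction of units significant at ``alpha`` and their preference split."""
    if not results:
        raise ValueError("no selectivity results")
    variable = results[0].variable
    sig = [r for r in results if r.p_value < alpha]
    by_pref: dict[str, int] = {}
    for r in sig:
        by_pref[r.preferred] = by_pref.get(r.preferred, 0) + 1
    return PreferenceFractions(variable=variable, n_units=len(results),
                               n_significant=len(sig), by_preference=by_pref)


def overlap_table(results_a: list[SelectivityResult],
                  results_b: list[SelectivityResult],
                  alpha: float = 0.05) -> pd.DataFrame:
    """2x2 significant/not-significant contingency table for two variables
    (e.g. side x reward), over units screened for both."""
    sig_a = {r.unit_id: r.p_value < alpha for r in results_a}
    sig_b = {r.unit_id: r.p_value < alpha for r in results_b}
    common = sorted(set(sig_a) & set(sig_b))
    tab = np.zeros((2, 2), int)
    for u in common:
        tab[int(sig_a[u]), int(sig_b[u])] += 1
    va = results_a[0].variable if results_a else "a"
    vb = results_b[0].variable if results_b else "b"
    return pd.DataFrame(tab,
                        index=[f"{va}:ns", f"{va}:sig"],
                        columns=[f"{vb}:ns", f"{vb}:sig"])


def selectivity_to_frame(results: list[SelectivityResult]) -> pd.DataFrame:
    """Long-format selectivity table (one row per unit) for selectivity.csv."""
    return pd.DataFrame([{
        "unit_id": r.unit_id, "variable": r.variable, "p_value": r.p_value,
        "preferred": r.preferred, "significant": r.significant,
    } for r in results])


def dprime_to_frame(results: list[SelectivityResult]) -> pd.DataFrame:
    """Long-format d' table (unit, bin_time, value) for dprime.csv."""
    rows = []
    for r in results:
        for t, v in zip(r.bin_centers, r.dprime_timecourse):
            rows.append({"unit_id": r.unit_id, "variable": r.variable,
                         "bin_time": t, "value": v})
    return pd.DataFrame(rows)
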