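"""Cross-session unit identity from tetrode waveforms.

Whether a unit recorded on consecutive sessions on the same tetrode is the
same neuron is decided from its 4-channel mean spike waveform. The session-1
waveform on each channel is scaled by the least-squares factor alpha that best
matches the session-2 waveform; d1 sums the normalized residual distances over
the four channels (shape change), and d2 summarizes how much and how unevenly
the per-channel amplitudes changed: max |log alpha| plus the largest spread of
log alpha across channel pairs. Pairs below both thresholds (d1 < 0.8,
d2 < 1 by default, calibrated against a cross-animal null) that also show a
significant positive correlation of their trial-aligned PSTHs are matched
one-to-one, greedily by ascending d1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

D1_THRESHOLD = 0.8
D2_THRESHOLD = 1.0


@dataclass
class MatchDecision:
    """Waveform and PSTH evidence for one cross-session unit pair.

    ``alpha`` holds the four per-channel least-squares scales; ``is_match``
    is set only after the one-to-one assignment in :func:`match_units`.
    ``psth_discordant`` flags pairs whose PSTHs correlate poorly despite
    passing the waveform criteria (candidates for manual review).
    """

    unit_a: int
    unit_b: int
    alpha: np.ndarray
    d1: float
    d2: float
    psth_r: float
    psth_p: float
    is_match: bool = False
    psth_discordant: bool = False

    @property
    def passes_waveform(self) -> bool:
        return self.d1 < D1_THRESHOLD and self.d2 < D2_THRESHOLD


def optimal_scale(x: np.ndarray, y: np.ndarray) -> float:
    """alpha = argmin ||alpha x - y||^2 = (x . y) / (x . x), closed form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("waveforms must have equal length")
    xx = float(x @ x)
    if xx == 0:
        raise ValueError("zero-norm waveform has no defined scale")
    return float(x @ y) / xx


def d1(x: np.ndarray, y: np.ndarray) -> float:
    """Shape distance: sum over the 4 channels of ||alpha_i x_i - y_i|| / ||y_i||."""
    x, y = _check_pair(x, y)
    total = 0.0
    for i in range(4):
        ny = np.linalg.norm(y[i])
        if ny == 0:
            raise ValueError(f"zero-norm channel {i} in reference waveform")
        a = optimal_scale(x[i], y[i])
        total += np.linalg.norm(a * x[i] - y[i]) / ny
    return float(total)


def d2(x: np.ndarray, y: np.ndarray) -> float:
    """Amplitude-change distance: max_i |log alpha_i| + max_{i,j} |log alpha_i -
    log alpha_j|. A non-positive alpha (inverted waveform) yields +inf (an
    automatic non-match)."""
    x, y = _check_pair(x, y)
    alphas = np.array([optimal_scale(x[i], y[i]) for i in range(4)])
    if (alphas <= 0).any():
        logger.info("non-positive channel scale %s: declaring non-match", alphas)
        return float("inf")
    la = np.log(alphas)
    return float(np.max(np.abs(la)) + np.max(la) - np.min(la))


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("templates must have identical shapes")
    if x.shape[0] != 4:
        raise ValueError("templates must have exactly 4 channels")
    return x, y


def channel_scales(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """The four per-channel least-squares scales alpha_i."""
    x, y = _check_pair(x, y)
    return np.array([optimal_scale(x[i], y[i]) for i in range(4)])


def psth_correlation(psth_a: np.ndarray, psth_b: np.ndarray
                     ) -> tuple[float, float]:
    """Pearson correlation of two trial-start-aligned mean firing rates."""
    a = np.asarray(psth_a, float)
    b = np.asarray(psth_b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def match_units(templates_a: dict[int, np.ndarray],
                templates_b: dict[int, np.ndarray],
                psths_a: dict[int, np.ndarray] | None = None,
                psths_b: dict[int, np.ndarray] | None = None,
                d1_threshold: float = D1_THRESHOLD,
                d2_threshold: float = D2_THRESHOLD,
                psth_alpha: float = 0.05) -> list[MatchDecision]:
    """Match units across two consecutive sessions on one tetrode.

    Every session-1 x session-2 pair is scored; candidates must satisfy
    d1 < ``d1_threshold``, d2 < ``d2_threshold`` and, when PSTHs are supplied,
    a positive Pearson correlation with p < ``psth_alpha``. Candidates are then
    assigned one-to-one greedily by ascending d1. Session-1 templates are
    scaled onto session-2 (the comparison is directional). Returns decisions
    for all pairs, with ``is_match`` set on the assigned ones.
    """
    decisions: list[MatchDecision] = []
    for ua, wa in templates_a.items():
        for ub, wb in templates_b.items():
            if psths_a is not None and psths_b is not None:
                r, p = psth_correlation(psths_a[ua], psths_b[ub])
            else:
                r, p = 1.0, 0.0  # no PSTH evidence supplied: waveform only
            dec = MatchDecision(
                unit_a=ua, unit_b=ub, alpha=channel_scales(wa, wb),
                d1=d1(wa, wb), d2=d2(wa, wb), psth_r=r, psth_p=p,
            )
            dec.psth_discordant = dec.passes_waveform and not (r > 0 and p < psth_alpha)
            decisions.append(dec)

    candidates = [d for d in decisions
                  if d.d1 < d1_threshold and d.d2 < d2_threshold
                  and d.psth_r > 0 and d.psth_p < psth_alpha]
    used_a: set[int] = set()
    used_b: set[int] = set()
    for dec in sorted(candidates, key=lambda d: d.d1):
        if dec.unit_a in used_a or dec.unit_b in used_b:
            continue
        dec.is_match = True
        used_a.add(dec.unit_a)
        used_b.add(dec.unit_b)
    return decisions


@dataclass
class NullCalibration:
    """Empirical d1/d2 null distributions from cross-animal template pairs."""

    d1_values: np.ndarray
    d2_values: np.ndarray
    fpr: float
    suggested_d1: float
    suggested_d2: float
    default_d1: float = D1_THRESHOLD
    default_d2: float = D2_THRESHOLD

    def summary(self) -> str:
        return (f"Null calibration on {len(self.d1_values)} cross-animal pairs\n"
                f"  d1: 5th/50th pct = {np.percentile(self.d1_values, 5):.3f}/"
                f"{np.percentile(self.d1_values, 50):.3f}; "
                f"suggested threshold (fpr={self.fpr}) = {self.suggested_d1:.3f} "
                f"(default {self.default_d1})\n"
                f"  d2: 5th/50th pct = {np.percentile(self.d2_values, 5):.3f}/"
                f"{np.percentile(self.d2_values, 50):.3f}; "
                f"suggested threshold (fpr={self.fpr}) = {self.suggested_d2:.3f} "
                f"(default {self.default_d2})")


def null_threshold_calibration(pairs: list[tuple[np.ndarray, np.ndarray]],
                               fpr: float = 0.05) -> NullCalibration:
    """Empirical null distributions of d1/d2 from pairs of templates that
    cannot be the same neuron (different animals); suggested thresholds are
    the ``fpr`` quantiles of the null. Defaults (0.8, 1) are kept as the
    operating thresholds; the suggestion is diagnostic."""
    if len(pairs) < 100:
        raise ValueError("null calibration needs at least 100 template pairs")
    d1s = np.array([d1(x, y) for x, y in pairs])
    d2s = np.array([d2(x, y) for x, y in pairs])
    finite2 = d2s[np.isfinite(d2s)]
    if np.median(d1s) < 1e-6:
        raise ValueError(
            "degenerate null: template pairs are near-identical, d1 collapses at 0"
        )
    return NullCalibration(
        d1_values=d1s, d2_values=d2s, fpr=fpr,
        suggested_d1=float(np.quantile(d1s, fpr)),
        suggested_d2=float(np.quantile(finite2, fpr)) if len(finite2) else float("inf"),
    )


def matches_to_frame(decisions: list[MatchDecision]) -> pd.DataFrame:
    """Long-format matches table (one row per scored pair) for matches.csv."""
    return pd.DataFrame([{
        "unit_a": d.unit_a, "unit_b": d.unit_b, "d1": d.d1, "d2": d.d2,
        "psth_r": d.psth_r, "psth_p": d.psth_p, "is_match": d.is_match,
        "psth_discordant": d.psth_discordant,
    } for d in decisions])
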