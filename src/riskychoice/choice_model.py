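"""Trial-history logistic choice model and psychometric sigmoid.

The choice model parameterizes the probability of choosing the right port as a
logistic function of five terms: the right-minus-left expected value (dEV), a
risky/safe hysteresis term (repeat the previous risk category), a risky win-stay
term (gamble again after a rewarded gamble), a left/right hysteresis term
(repeat the previous side), and a constant side bias. The same regressor coding
is used by the generative agent in :mod:`riskychoice.simulate`, so fitting the
model to its own simulated choices recovers the planted weights.

The psychometric model fits a 4-parameter sigmoid to the probability of
choosing the safe option as a function of the safe-minus-risky expected value,
binned into 11 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

PARAM_NAMES = ["w_ev", "w_rs_hyst", "w_risky_winstay", "w_lr_hyst", "w_lr_bias"]


# ---------------------------------------------------------------------------
# Shared regressor coding (single definition used by fitter and simulator)
# ---------------------------------------------------------------------------

def expected_values(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial expected value (volume x probability, uL) of left and right offers."""
    safe_right = (trials["safe_side"].to_numpy() == "right")
    ev_safe = trials["safe_volume"].to_numpy(float)
    ev_risky = trials["risky_volume"].to_numpy(float) * trials["risky_prob"].to_numpy(float)
    ev_right = np.where(safe_right, ev_safe, ev_risky)
    ev_left = np.where(safe_right, ev_risky, ev_safe)
    return ev_left, ev_right


def history_regressors(prev_choice_right, prev_chose_safe, prev_rewarded,
                       safe_side_right_now):
    """History regressors for the choice model; scalar or array inputs.

    Coding (positive weight = choose right):
      x_lr  = +1 if the previous choice was right, -1 if left.
      x_rs  = (+1 if previous choice was safe else -1) x (+1 if safe is right
              now else -1): repeating the previous risk category means choosing
              right when the sign is positive.
      x_rws = 1{previous trial was a rewarded risky choice} x (+1 if the risky
              side is right now else -1).
    """
    prev_choice_right = np.asarray(prev_choice_right, dtype=bool)
    prev_chose_safe = np.asarray(prev_chose_safe, dtype=bool)
    prev_rewarded = np.asarray(prev_rewarded, dtype=bool)
    safe_right = np.asarray(safe_side_right_now, dtype=bool)

    x_lr = np.where(prev_choice_right, 1.0, -1.0)
    x_rs = np.where(prev_chose_safe, 1.0, -1.0) * np.where(safe_right, 1.0, -1.0)
    risky_right_sign = np.where(safe_right, -1.0, 1.0)
    x_rws = np.where(prev_rewarded & ~prev_chose_safe, 1.0, 0.0) * risky_right_sign
    return x_lr, x_rs, x_rws


def build_design_matrix(trials: pd.DataFrame, zscore_ev: bool = False
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Build the 5-column design matrix and the chose-right response.

    The first trial of the session carries no history and is dropped.
    ``zscore_ev`` optionally standardizes the dEV column (off by default; dEV
    is in uL).
    """
    ev_left, ev_right = expected_values(trials)
    dev = ev_right - ev_left

    choice_right = (trials["choice_side"].to_numpy() == "right")
    chose_safe = trials["chose_safe"].to_numpy(bool)
    rewarded = trials["rewarded"].to_numpy(bool)
    safe_right = (trials["safe_side"].to_numpy() == "right")

    x_lr, x_rs, x_rws = history_regressors(
        choice_right[:-1], chose_safe[:-1], rewarded[:-1], safe_right[1:]
    )
    dev = dev[1:]
    if zscore_ev:
        dev = (dev - dev.mean()) / dev.std()

    X = pd.DataFrame(
        {
            "w_ev": dev,
            "w_rs_hyst": x_rs,
            "w_risky_winstay": x_rws,
            "w_lr_hyst": x_lr,
            "w_lr_bias": 1.0,
        },
        index=trials.index[1:],
    )
    y = pd.Series(choice_right[1:].astype(float), index=trials.index[1:],
                  name="chose_right")
    return X, y


# ---------------------------------------------------------------------------
# Logistic choice model
# ---------------------------------------------------------------------------

class ChoiceModel:
    """Maximum-likelihood logistic model of trial-by-trial choices.

    Parameters
    ----------
    endog
        Binary chose-right indicator per trial.
    exog
        Design matrix with the five named regressor columns.

    Use :meth:`from_trials` to construct both from an ordered trials table.
    """

    def __init__(self, endog: pd.Series, exog: pd.DataFrame):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = pd.DataFrame(exog)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, zscore_ev: bool = False) -> "ChoiceModel":
        X, y = build_design_matrix(trials, zscore_ev=zscore_ev)
        return cls(y, X)

    def fit(self, ridge: float | None = None) -> "ChoiceModelResults":
        """Fit by maximum likelihood; on perfect separation fall back to ridge.

        ``ridge`` forces an L2-penalized fit with the given penalty weight.
        """
        if ridge is None:
            try:
                with np.errstate(all="ignore"):
                    res = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=200)
                ok = (np.isfinite(res.params).all()
                      and np.isfinite(res.bse).all()
                      and res.mle_retvals.get("converged", True)
                      and np.abs(res.params).max() < 1e2)  # separation blow-up
                if ok:
                    return ChoiceModelResults(
                        model=self,
                        params=pd.Series(res.params, index=self.exog.columns),
                        bse=pd.Series(res.bse, index=self.exog.columns),
                        llf=float(res.llf),
                        converged=bool(res.mle_retvals.get("converged", True)),
                        separable=False,
                    )
            except Exception:
                pass
            ridge = 1.0  # separation fallback
        glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        res = glm.fit_regularized(alpha=ridge / len(self.endog), L1_wt=0.0)
        params = pd.Series(np.asarray(res.params), index=self.exog.columns)
        return ChoiceModelResults(
            model=self, params=params,
            bse=pd.Series(np.nan, index=self.exog.columns),
            llf=float(self._loglike(params.to_numpy())),
            converged=True, separable=True,
        )

    def _loglike(self, beta: np.ndarray) -> float:
        eta = self.exog.to_numpy() @ beta
        return float(np.sum(self.endog * eta - np.log1p(np.exp(eta))))


@dataclass
class ChoiceModelResults:
    """Fitted choice-model weights with standard errors and diagnostics."""

    model: ChoiceModel
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    separable: bool

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def predict(self, exog: pd.DataFrame | None = None) -> np.ndarray:
        X = self.model.exog if exog is None else pd.DataFrame(exog)
        eta = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = ["Trial-history logistic choice model",
                 f"  n trials: {len(self.model.endog)}   log-likelihood: {self.llf:.2f}",
                 f"  converged: {self.converged}   separation fallback: {self.separable}",
                 f"  {'param':<18}{'coef':>10}{'std err':>10}{'z':>8}"]
        for name in self.params.index:
            z = self.params[name] / self.bse[name] if np.isfinite(self.bse[name]) else np.nan
            lines.append(f"  {name:<18}{self.params[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}{z:>8.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": {k: (None if not np.isfinite(v) else v) for k, v in self.bse.items()},
            "llf": self.llf,
            "converged": self.converged,
            "separable": self.separable,
        }


# ---------------------------------------------------------------------------
# Psychometric sigmoid
# ---------------------------------------------------------------------------

def psychometric_sigmoid(x, y0, a, b, x0):
    """p(choose safe) = y0 + (1 - 2a) / (1 + exp(-b (x - x0))), x = VS - VR."""
    with np.errstate(over="ignore"):  # exp overflow saturates correctly
        return y0 + (1.0 - 2.0 * a) / (1.0 + np.exp(-b * (np.asarray(x, float) - x0)))


@dataclass
class PsychometricResults:
    """Fitted 4-parameter sigmoid with the binned data it was fitted to."""

    y0: float
    a: float
    b: float
    x0: float
    mse: float
    bin_centers: np.ndarray
    bin_proportions: np.ndarray
    bin_counts: np.ndarray
    n_starts: int

    @property
    def params(self) -> dict:
        return {"y0": self.y0, "a": self.a, "b": self.b, "x0": self.x0}

    def predict(self, x) -> np.ndarray:
        return psychometric_sigmoid(x, self.y0, self.a, self.b, self.x0)

    def summary(self) -> str:
        return ("Psychometric sigmoid p(safe) = y0 + (1-2a)/(1+exp(-b(VS-VR-x0)))\n"
                f"  y0={self.y0:.4f}  a={self.a:.4f}  b={self.b:.4f}  "
                f"x0={self.x0:.4f}  mse={self.mse:.3e}  "
                f"(best of {self.n_starts} starts, "
                f"{int(self.bin_counts.sum())} trials in "
                f"{np.count_nonzero(self.bin_counts)} populated bins)")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bin_centers, self.bin_proportions, "ko", label="data")
        xs = np.linspace(self.bin_centers.min(), self.bin_centers.max(), 200)
        ax.plot(xs, self.predict(xs), "r-", label="fit")
        ax.set_xlabel("EV(safe) - EV(risky)  (uL)")
        ax.set_ylabel("p(choose safe)")
        ax.legend()
        return ax


class PsychometricModel:
    """4-parameter sigmoid of safe-choice probability versus VS - VR.

    Trials where both sides offer certain rewards (risky probability 1) are
    excluded; the remaining trials are binned into ``n_bins`` equal-width bins
    of the safe-minus-risky expected-value difference, and the sigmoid is fit
    by minimizing the mean squared error between the binned safe-choice
    proportions and the curve, under box constraints y0 in [0, 0.5],
    a in [0, 0.5], b >= 0.
    """

    N_BINS = 11

    def __init__(self, x: np.ndarray, chose_safe: np.ndarray, n_bins: int = N_BINS):
        self.x = np.asarray(x, float)
        self.chose_safe = np.asarray(chose_safe, bool)
        self.n_bins = n_bins
        edges = np.linspace(self.x.min(), self.x.max(), n_bins + 1)
        edges[-1] += 1e-9
        idx = np.digitize(self.x, edges) - 1
        self.bin_centers = 0.5 * (edges[:-1] + edges[1:])
        self.bin_counts = np.array([(idx == i).sum() for i in range(n_bins)])
        with np.errstate(invalid="ignore"):
            self.bin_proportions = np.array([
                self.chose_safe[idx == i].mean() if (idx == i).any() else np.nan
                for i in range(n_bins)
            ])

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, n_bins: int = N_BINS) -> "PsychometricModel":
        keep = trials["risky_prob"].to_numpy(float) < 1.0
        t = trials.loc[keep]
        vs = t["safe_volume"].to_numpy(float)
        vr = t["risky_volume"].to_numpy(float) * t["risky_prob"].to_numpy(float)
        return cls(vs - vr, t["chose_safe"].to_numpy(bool), n_bins=n_bins)

    def _mse(self, theta: np.ndarray) -> float:
        ok = ~np.isnan(self.bin_proportions)
        pred = psychometric_sigmoid(self.bin_centers[ok], *theta)
        return float(np.mean((pred - self.bin_proportions[ok]) ** 2))

    def fit(self, n_starts: int = 20, seed: int = 0, tol: float = 1e-9
            ) -> PsychometricResults:
        """Multi-start constrained quasi-Newton minimization of the binned MSE."""
        populated = int(np.count_nonzero(~np.isnan(self.bin_proportions)))
        if populated < 4:
            raise ValueError(
                f"psychometric fit underdetermined: {populated} populated bins < 4"
            )
        rng = np.random.default_rng(seed)
        span = self.x.max() - self.x.min()
        bounds = [(0.0, 0.5), (0.0, 0.5), (0.0, 100.0 / max(span, 1e-9)),
                  (self.x.min(), self.x.max())]
        best = None
        for _ in range(n_starts):
            theta0 = np.array([
                rng.uniform(0.0, 0.2), rng.uniform(0.0, 0.2),
                rng.uniform(0.05, 5.0) / max(span / 10.0, 1e-9),
                rng.uniform(self.x.min(), self.x.max()),
            ])
            res = minimize(self._mse, theta0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": tol, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        y0, a, b, x0 = best.x
        return PsychometricResults(
            y0=float(y0), a=float(a), b=float(b), x0=float(x0),
            mse=float(best.fun), bin_centers=self.bin_centers,
            bin_proportions=self.bin_proportions, bin_counts=self.bin_counts,
            n_starts=n_starts,
        )
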