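"""Rank-1 (and rank-R) CP decomposition of neuron x time x trial tensors.

A session's simultaneously recorded units form a third-order tensor
X[n, t, k] (neurons x within-trial time bins x trials). CP/PARAFAC
approximates it by a sum of R outer products w_r (x) b_r (x) a_r of a neuron
factor, a temporal factor, and an across-trial factor. The trial factor a acts
as a per-trial population gain, and its dependence on reward history is probed
with shuffle-corrected reward-triggered averages and a Pearson correlation
against the previous trial's outcome.

Rank is selected by refitting from random initializations and measuring a
similarity index between consecutive solutions; the analysis model is rank 1,
fitted by alternating least squares with closed-form mode updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .encoding import AlignedRates


@dataclass
class SessionTensor:
    """Nonnegative neuron x time x trial rate tensor with axis metadata."""

    data: np.ndarray
    unit_ids: list[int]
    bin_centers: np.ndarray
    normalization: str = "none"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def build_tensor(aligned: list[AlignedRates], normalize: bool = True,
                 eps: float = 1e-12) -> SessionTensor:
    """Stack per-unit trials x bins rate matrices into a neuron x time x trial
    tensor; by default each neuron is divided by its maximum rate (+eps) so
    that high-rate units do not dominate the neuron factor."""
    if not aligned:
        raise ValueError("no aligned rates supplied")
    shape = aligned[0].rates.shape
    for a in aligned:
        if a.rates.shape != shape:
            raise ValueError("all units must share trial and time-bin axes")
    # AlignedRates stores trials x bins; tensor is neurons x bins x trials
    data = np.stack([a.rates.T for a in aligned], axis=0)
    norm = "none"
    if normalize:
        scale = data.max(axis=(1, 2), keepdims=True) + eps
        data = data / scale
        norm = "per-neuron max"
    return SessionTensor(data=data, unit_ids=[a.unit_id for a in aligned],
                         bin_centers=aligned[0].bin_centers, normalization=norm)


# ---------------------------------------------------------------------------
# CP-ALS
# ---------------------------------------------------------------------------

def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of two factor matrices."""
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _cp_reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    a, b, c = factors
    return np.einsum("ir,jr,kr->ijk", a, b, c)


def cp_als(tensor: np.ndarray, rank: int, max_iter: int = 200,
           tol: float = 1e-8, seed: int = 0
           ) -> tuple[list[np.ndarray], list[float]]:
    """Alternating least squares for rank-R CP; returns factor matrices and
    the per-iteration relative reconstruction-error trace (non-increasing).

    Each mode update solves the linear least-squares problem given the other
    two modes (normal equations with the Khatri-Rao product); for rank 1 this
    reduces to the closed-form vector update. Initial factors are drawn
    nonnegative (half-normal): rate tensors are nonnegative and this start
    avoids sign-straddling local optima without constraining the updates."""
    rng = np.random.default_rng(seed)
    factors = [np.abs(rng.standard_normal((s, rank))) for s in tensor.shape]
    norm_x = np.linalg.norm(tensor)
    unfoldings = [_unfold(tensor, m) for m in range(3)]
    errors: list[float] = []
    prev_err = np.inf
    for _ in range(max_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            rhs = (unfoldings[mode] @ kr).T
            try:
                factors[mode] = np.linalg.solve(gram.T, rhs).T
            except np.linalg.LinAlgError:
                # singular gram (e.g. over-parameterized rank): minimum-norm
                factors[mode] = np.linalg.lstsq(gram.T, rhs, rcond=None)[0].T
        err = float(np.linalg.norm(tensor - _cp_reconstruct(factors)) / norm_x)
        errors.append(err)
        if prev_err - err < tol:
            break
        prev_err = err
    return factors, errors


def canonicalize_rank1(w: np.ndarray, b: np.ndarray, a: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Resolve scale/sign ambiguity: ||w|| = ||b|| = 1 with the scale absorbed
    into the trial factor, and mean(w) >= 0, mean(b) >= 0 with any sign flips
    absorbed into the trial factor too."""
    nw, nb = np.linalg.norm(w), np.linalg.norm(b)
    if nw == 0 or nb == 0:
        raise ValueError("zero-norm factor cannot be canonicalized")
    w, b, a = w / nw, b / nb, a * (nw * nb)
    for vec in (w, b):
        if vec.mean() < 0:
            vec *= -1.0
            a = -a
    scale = float(np.linalg.norm(a))
    return w, b, a, scale


@dataclass
class CPResults:
    """Fitted CP factors with stability and fit diagnostics.

    For rank 1 the neuron and temporal factors are unit-norm vectors with the
    scale carried by the trial factor; ``similarity`` is the mean similarity
    index between solutions from consecutive initializations.
    """

    factors: list[np.ndarray]
    rank: int
    scale: float
    n_inits: int
    similarity: float
    reconstruction_error: float
    converged: bool
    n_iterations: int

    @property
    def neuron_factor(self) -> np.ndarray:
        return self.factors[0][:, 0] if self.rank == 1 else self.factors[0]

    @property
    def temporal_factor(self) -> np.ndarray:
        return self.factors[1][:, 0] if self.rank == 1 else self.factors[1]

    @property
    def trial_factor(self) -> np.ndarray:
        return self.factors[2][:, 0] if self.rank == 1 else self.factors[2]

    def summary(self) -> str:
        shp = " x ".join(str(f.shape[0]) for f in self.factors)
        return (f"CP rank-{self.rank} decomposition of a {shp} tensor\n"
                f"  relative reconstruction error: {self.reconstruction_error:.4f}\n"
                f"  similarity across {self.n_inits} initializations: "
                f"{self.similarity:.4f}\n"
                f"  scale: {self.scale:.4f}   converged: {self.converged} "
                f"({self.n_iterations} ALS iterations)")

    def plot(self, axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(10, 3))
        names = ["neuron factor", "temporal factor", "trial factor"]
        for ax, vec, name in zip(
                axes, [self.neuron_factor, self.temporal_factor,
                       self.trial_factor], names):
            ax.plot(np.atleast_2d(vec.T).T)
            ax.set_title(name)
        return axes


class CPDecomposition:
    """CP model of a session tensor, fitted by multi-start ALS.

    Parameters
    ----------
    tensor
        A :class:`SessionTensor` or a raw 3-d array.
    rank
        Number of components (the analysis default is 1).
    """

    def __init__(self, tensor: SessionTensor | np.ndarray, rank: int = 1):
        self.data = tensor.data if isinstance(tensor, SessionTensor) else np.asarray(tensor, float)
        if self.data.ndim != 3:
            raise ValueError("tensor must be 3-dimensional")
        if min(self.data.shape) < 2:
            raise ValueError("all tensor dimensions must be >= 2 for fitting")
        self.rank = rank

    def fit(self, n_inits: int = 10, max_iter: int = 200, tol: float = 1e-8,
            seed: int = 0) -> CPResults:
        """Best of ``n_inits`` random starts by reconstruction error, with the
        similarity index measured between consecutive initializations."""
        seeds = np.random.SeedSequence(seed).generate_state(n_inits)
        fits = []
        for s in seeds:
            factors, errors = cp_als(self.data, self.rank, max_iter=max_iter,
                                     tol=tol, seed=int(s % (2 ** 31)))
            fits.append((factors, errors))
        sims = [similarity_index(fits[i][0], fits[i + 1][0])
                for i in range(len(fits) - 1)]
        best_factors, best_errors = min(fits, key=lambda fe: fe[1][-1])
        if self.rank == 1:
            w, b, a, scale = canonicalize_rank1(
                best_factors[0][:, 0], best_factors[1][:, 0],
                best_factors[2][:, 0])
            best_factors = [w[:, None], b[:, None], a[:, None]]
        else:
            scale = float(np.linalg.norm(best_factors[2]))
        return CPResults(
            factors=best_factors, rank=self.rank, scale=scale,
            n_inits=n_inits,
            similarity=float(np.mean(sims)) if sims else 1.0,
            reconstruction_error=best_errors[-1],
            converged=len(best_errors) < max_iter,
            n_iterations=len(best_errors),
        )


def fit_cp_rank1(tensor: SessionTensor | np.ndarray, n_inits: int = 10,
                 tol: float = 1e-8, max_iter: int = 200, seed: int = 0
                 ) -> CPResults:
    """Convenience wrapper: rank-1 CP fit of a session tensor."""
    return CPDecomposition(tensor, rank=1).fit(n_inits=n_inits, tol=tol,
                                               max_iter=max_iter, seed=seed)


def similarity_index(factors_a: list[np.ndarray],
                     factors_b: list[np.ndarray]) -> float:
    """Stability score in [0, 1] between two CP solutions.

    Per matched component, the product over the three modes of the absolute
    cosine similarity (scale- and sign-invariant). For rank > 1, components
    are matched greedily by that product; the score is the mean over matches.
    """
    fa = [np.atleast_2d(f.T).T for f in factors_a]
    fb = [np.atleast_2d(f.T).T for f in factors_b]
    ra, rb = fa[0].shape[1], fb[0].shape[1]

    def comp_sim(i: int, j: int) -> float:
        prod = 1.0
        for m in range(3):
            x, y = fa[m][:, i], fb[m][:, j]
            nx, ny = np.linalg.norm(x), np.linalg.norm(y)
            if nx == 0 or ny == 0:
                raise ValueError("zero-norm factor in similarity index")
            prod *= abs(float(x @ y) / (nx * ny))
        return prod

    sim = np.array([[comp_sim(i, j) for j in range(rb)] for i in range(ra)])
    total, used = 0.0, set()
    for i in np.argsort(-sim.max(axis=1)):
        candidates = [j for j in range(rb) if j not in used]
        if not candidates:
            break
        j = max(candidates, key=lambda j: sim[i, j])
        used.add(j)
        total += sim[i, j]
    return total / max(ra, rb)


def select_rank(tensor: SessionTensor | np.ndarray, max_rank: int = 5,
                n_inits: int = 10, threshold: float = 0.9,
                max_iter: int = 200, tol: float = 1e-8, seed: int = 0) -> int:
    """Largest rank whose refits are stable: for each candidate rank the model
    is fitted ``n_inits`` times and the similarity index between consecutive
    initializations is averaged; the chosen rank is the maximum with mean
    similarity above ``threshold`` (0 if none qualifies)."""
    data = tensor.data if isinstance(tensor, SessionTensor) else np.asarray(tensor, float)
    chosen = 0
    for rank in range(1, max_rank + 1):
        seeds = np.random.SeedSequence((seed, rank)).generate_state(n_inits)
        fits = [cp_als(data, rank, max_iter=max_iter, tol=tol,
                       seed=int(s % (2 ** 31)))[0] for s in seeds]
        sims = [similarity_index(fits[i], fits[i + 1])
                for i in range(len(fits) - 1)]
        if np.mean(sims) > threshold:
            chosen = rank
    return chosen


# ---------------------------------------------------------------------------
# Trial-factor analyses
# ---------------------------------------------------------------------------

N_LAGS = 8  # lags 0..7 trials into the future


@dataclass
class TriggeredAverage:
    """Shuffle-corrected outcome-triggered averages of the trial factor."""

    lags: np.ndarray
    reward_avg: np.ndarray
    noreward_avg: np.ndarray
    n_shuffles: int

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags, self.reward_avg, "o-", color="tab:blue",
                label="reward-triggered")
        ax.plot(self.lags, self.noreward_avg, "o-", color="k",
                label="no-reward-triggered")
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_xlabel("trials after outcome")
        ax.set_ylabel("trial factor change (A.U.)")
        ax.legend()
        return ax


def _triggered(a: np.ndarray, trigger: np.ndarray) -> np.ndarray:
    """Mean of (a[k+j] - mean(a)) over trigger trials k, for j = 0..7."""
    centered = a - a.mean()
    n = len(a)
    out = np.full(N_LAGS, np.nan)
    idx = np.nonzero(trigger)[0]
    for j in range(N_LAGS):
        valid = idx[idx + j < n]
        if len(valid):
            out[j] = centered[valid + j].mean()
    return out


def triggered_average(trial_factor: np.ndarray, rewards: np.ndarray,
                      n_shuffles: int = 100, seed: int = 0) -> TriggeredAverage:
    """Reward- and no-reward-triggered averages of the trial factor at lags
    0..7, minus the mean of the same computation on reward-label shuffles."""
    a = np.asarray(trial_factor, float)
    rewards = np.asarray(rewards, bool)
    if len(a) < N_LAGS:
        raise ValueError(f"need at least {N_LAGS} trials")
    if len(a) != len(rewards):
        raise ValueError("trial factor and rewards must be the same length")
    rew = _triggered(a, rewards)
    norew = _triggered(a, ~rewards)
    rng = np.random.default_rng(seed)
    shuf_rew = np.zeros(N_LAGS)
    shuf_norew = np.zeros(N_LAGS)
    for _ in range(n_shuffles):
        perm = rng.permutation(rewards)
        shuf_rew += _triggered(a, perm)
        shuf_norew += _triggered(a, ~perm)
    return TriggeredAverage(lags=np.arange(N_LAGS),
                            reward_avg=rew - shuf_rew / n_shuffles,
                            noreward_avg=norew - shuf_norew / n_shuffles,
                            n_shuffles=n_shuffles)


def trialfactor_reward_correlation(trial_factor: np.ndarray,
                                   rewards: np.ndarray
                                   ) -> tuple[float, float]:
    """Pearson correlation between the trial factor a_k and the previous
    trial's reward indicator R_{k-1}, with a two-sided t-approximation p."""
    a = np.asarray(trial_factor, float)
    rewards = np.asarray(rewards, float)
    if len(a) < 10:
        raise ValueError("need at least 10 trials")
    if np.ptp(a) == 0:
        raise ValueError("trial factor is constant; correlation undefined")
    r, p = stats.pearsonr(a[1:], rewards[:-1])
    return float(r), float(p)
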