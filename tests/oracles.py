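"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain loops over trial records,
sharing no code with the package, so that agreement is evidence rather than
tautology.
"""

import numpy as np


def conditional_frequencies(trials) -> dict:
    """Loop over a trials table counting the conditional choice frequencies
    behind the risky win-stay and spatial win-stay/lose-switch estimators."""
    rows = trials.to_dict("records")
    c = {k: [0, 0] for k in ("post_safe_rew_safe", "post_risky_rew_safe",
                             "repeat_after_rew", "switch_after_unrew",
                             "repeat_any", "safe_any")}

    def tally(key, success):
        c[key][1] += 1
        c[key][0] += int(success)

    for k in range(1, len(rows)):
        prev, cur = rows[k - 1], rows[k]
        safe_now = cur["choice_side"] == cur["safe_side"]
        prev_safe = prev["choice_side"] == prev["safe_side"]
        repeat = cur["choice_side"] == prev["choice_side"]
        tally("safe_any", safe_now)
        tally("repeat_any", repeat)
        if prev["rewarded"] and prev_safe:
            tally("post_safe_rew_safe", safe_now)
        if prev["rewarded"] and not prev_safe:
            tally("post_risky_rew_safe", safe_now)
        if prev["rewarded"]:
            tally("repeat_after_rew", repeat)
        else:
            tally("switch_after_unrew", not repeat)

    freq = {k: (s / n if n else float("nan")) for k, (s, n) in c.items()}
    return {
        "risky_winstay": freq["post_safe_rew_safe"] - freq["post_risky_rew_safe"],
        "spatial_winstay": freq["repeat_after_rew"] - freq["repeat_any"],
        "spatial_loseswitch": freq["switch_after_unrew"] - (1 - freq["repeat_any"]),
        "counts": {k: tuple(v) for k, v in c.items()},
        "frequencies": freq,
    }


def numeric_optimal_scale(x, y) -> float:
    """1-D golden-section style minimization of ||a x - y||^2 by bracketing."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def loss(a):
        return float(np.sum((a * x - y) ** 2))

    lo, hi = -100.0, 100.0
    for _ in range(200):
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        if loss(m1) < loss(m2):
            hi = m2
        else:
            lo = m1
    return 0.5 * (lo + hi)


def triggered_average_lag(a, rewards, lag, n_shuffles, rng) -> float:
    """Shuffle-corrected outcome-triggered trial-factor average at one lag,
    recomputed with explicit loops."""
    a = np.asarray(a, float)
    rewards = np.asarray(rewards, bool)
    abar = a.mean()

    def avg(trig):
        vals = [a[k + lag] - abar for k in range(len(a))
                if trig[k] and k + lag < len(a)]
        return float(np.mean(vals))

    raw = avg(rewards)
    shuf = [avg(rng.permutation(rewards)) for _ in range(n_shuffles)]
    return raw - float(np.mean(shuf))


def rank1_reconstruction_error(tensor, w, b, a) -> float:
    """Relative Frobenius error of a rank-1 reconstruction, by loops."""
    t = np.asarray(tensor, float)
    total = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            for k in range(t.shape[2]):
                total += (t[i, j, k] - w[i] * b[j] * a[k]) ** 2
    return float(np.sqrt(total) / np.linalg.norm(t))
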