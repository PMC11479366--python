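"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by the most direct method available --
explicit rank-then-Pearson for Spearman, normal equations for OLS, an
exhaustive window scan for the adaptation metrics, a literal trace sum --
deliberately sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_bruteforce(x, y) -> float:
    """Pearson correlation of mid-ranks, computed from first principles."""
    rx, ry = midranks(np.asarray(x)), midranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def ols_normal_equations(y, a, l):
    """Least-squares coefficients of y on [1, a, l] by the normal equations."""
    X = np.column_stack([np.ones(len(a)), a, l])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


def trace_bruteforce(observations, gamma: float, lam: float) -> np.ndarray:
    """Eligibility trace after processing t observations: sum of decayed inputs.

    e_t = sum_{i<=t} (gamma*lam)**(t-i) o_i, evaluated literally.
    """
    t = len(observations)
    e = np.zeros_like(observations[0])
    for i, o in enumerate(observations):
        e = e + (gamma * lam) ** (t - 1 - (i)) * o
    return e


def adaptation_bruteforce(
    rewards, steps, switch_period: int = 20, streak: int = 5
):
    """Per-block adaptation rate/steps by exhaustive window scan.

    Returns a list of (rate, step_sum, censored) per goal block: the rate is
    the smallest local episode index whose trailing ``streak`` episodes are
    all rewarded, found by checking every window explicitly.
    """
    rewards = np.asarray(rewards)
    steps = np.asarray(steps)
    out = []
    for lo in range(0, len(rewards) - switch_period + 1, switch_period):
        block_r = rewards[lo : lo + switch_period]
        block_s = steps[lo : lo + switch_period]
        rate, censored = switch_period, True
        for i in range(streak, switch_period + 1):
            if np.all(block_r[i - streak : i] == 1):
                rate, censored = i, False
                break
        out.append((rate, int(block_s[:rate].sum()), censored))
    return out
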