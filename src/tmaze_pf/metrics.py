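"""Evaluation metrics: cumulative reward, step length, and block adaptation.

A run is segmented into goal blocks (the initial block plus one block per
goal relocation).  Within each block the *adaptation rate* is the number of
episodes, counted from the block start, until the agent first completes
``streak`` consecutive rewarded episodes (5 by default, so the optimum is
5); if the streak never completes, the block length is assigned and the
record is flagged censored.  The *adaptation step length* is the total
steps over the episodes the adaptation rate counts (the whole block when
censored).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .experiment import RunResult


@dataclass(frozen=True)
class AdaptationRecord:
    lam: float
    alpha_r: float
    run_id: int
    block_index: int
    adaptation_rate: int
    adaptation_steps: int
    censored: bool


def cumulative_reward(run: RunResult) -> float:
    """Total reward over the run's episodes."""
    return float(run.rewards.sum())


def mean_step_length(run: RunResult) -> float:
    """Arithmetic mean of per-episode step counts."""
    return float(run.steps.mean())


def _block_bounds(run: RunResult, block_index: int, switch_period: int) -> tuple[int, int]:
    n_blocks = run.n_episodes // switch_period
    if not 0 <= block_index < n_blocks:
        raise ValueError(
            f"block_index must lie in [0, {n_blocks}); got {block_index}"
        )
    lo = block_index * switch_period
    return lo, lo + switch_period


def adaptation_rate(
    run: RunResult,
    block_index: int,
    switch_period: int = 20,
    streak: int = 5,
) -> AdaptationRecord:
    """Episodes from block start to the first completed success streak.

    Local episode indices run 1..switch_period from the block start; the
    returned rate is the local index of the episode completing the first
    ``streak`` consecutive rewarded episodes, or ``switch_period`` with
    ``censored=True`` if no streak completes inside the block.
    """
    if streak > switch_period:
        raise ValueError("streak cannot exceed the block length")
    if streak < 1:
        raise ValueError("streak must be >= 1")
    lo, hi = _block_bounds(run, block_index, switch_period)
    rewards = run.rewards[lo:hi]
    steps = run.steps[lo:hi]
    rate, censored = switch_period, True
    consecutive = 0
    for i, r in enumerate(rewards, start=1):
        consecutive = consecutive + 1 if r == 1 else 0
        if consecutive >= streak:
            rate, censored = i, False
            break
    return AdaptationRecord(
        lam=run.lam,
        alpha_r=run.alpha_r,
        run_id=run.run_id,
        block_index=block_index,
        adaptation_rate=rate,
        adaptation_steps=int(steps[:rate].sum()),
        censored=censored,
    )


def adaptation_step_length(
    run: RunResult,
    block_index: int,
    switch_period: int = 20,
    streak: int = 5,
) -> AdaptationRecord:
    """Total steps over the episodes counted by the adaptation rate.

    Computed jointly with the rate; this is a naming convenience over
    :func:`adaptation_rate`, which already carries both fields.
    """
    return adaptation_rate(run, block_index, switch_period, streak)


def adaptation_records(
    run: RunResult, switch_period: int = 20, streak: int = 5
) -> list[AdaptationRecord]:
    """One record per goal block of the run (5 for the canonical schedule)."""
    n_blocks = run.n_episodes // switch_period
    return [
        adaptation_rate(run, b, switch_period, streak) for b in range(n_blocks)
    ]


def runs_frame(results: Iterable[RunResult]) -> pd.DataFrame:
    """Per-run summary table: cumulative reward and mean step length."""
    rows = [
        (
            run.lam,
            run.alpha_r,
            run.run_id,
            cumulative_reward(run),
            mean_step_length(run),
        )
        for run in results
    ]
    return pd.DataFrame(
        rows,
        columns=["lam", "alpha_r", "run_id", "cumulative_reward", "mean_step_length"],
    )


def adaptation_frame(
    results: Iterable[RunResult], switch_period: int = 20, streak: int = 5
) -> pd.DataFrame:
    """Per-run per-block adaptation table (one row per AdaptationRecord)."""
    rows = []
    for run in results:
        for rec in adaptation_records(run, switch_period, streak):
            rows.append(
                (
                    rec.lam,
                    rec.alpha_r,
                    rec.run_id,
                    rec.block_index,
                    rec.adaptation_rate,
                    rec.adaptation_steps,
                    rec.censored,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lam",
            "alpha_r",
            "run_id",
            "block_index",
            "adaptation_rate",
            "adaptation_steps",
            "censored",
        ],
    )
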