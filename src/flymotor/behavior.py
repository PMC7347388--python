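"""Behavioral endpoints and resampling statistics.

Endpoints for optogenetic walking experiments: the percent change in
walking speed around a stimulus, and whether a stationary fly initiates
sustained walking (>3 mm/s) within 500 ms of the stimulus.  Group
comparisons use a pooled two-sample bootstrap (10,000 draws by default,
two-tailed on the absolute difference of the group statistic), with
Benjamini–Hochberg step-up control of the false discovery rate across a
family of comparisons.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray


def percent_speed_change(
    speed: ArrayLike,
    onset_index: int,
    stim_ms: float,
    fps: float = 30.0,
    post_ms: float = 200.0,
    eps: float = 1e-6,
) -> float:
    """Percent change in walking speed caused by a stimulus.

    ``100 × (mean speed over the stimulus plus the following 200 ms −
    speed at onset) / speed at onset``; the onset sample itself is the
    baseline and is not part of the averaging window.  A fly that was
    effectively stationary at onset (speed ≤ ``eps``) has no defined
    percent change; ``nan`` is returned so the trial can be flagged.
    """
    v = np.asarray(speed, dtype=float)
    v0 = v[onset_index]
    if v0 <= eps:
        return float("nan")
    stop = min(onset_index + int(round((stim_ms + post_ms) / 1000.0 * fps)) + 1, v.size)
    return float(100.0 * (v[onset_index + 1 : stop].mean() - v0) / v0)


def walk_initiation(
    speed: ArrayLike,
    onset_index: int,
    fps: float = 30.0,
    threshold_mm_s: float = 3.0,
    window_ms: float = 500.0,
    sustained_fraction: float = 0.5,
) -> bool:
    """Did a stationary fly start walking after the stimulus?

    True iff speed exceeds ``threshold_mm_s`` (default 3 mm/s) for at
    least ``sustained_fraction`` (default half) of the ``window_ms``
    (default 500 ms) following the onset — a single-frame excursion does
    not count as sustained walking.
    """
    v = np.asarray(speed, dtype=float)
    n_win = int(round(window_ms / 1000.0 * fps))
    if onset_index + n_win > v.size:
        raise ValueError("speed trace does not cover onset + window")
    win = v[onset_index : onset_index + n_win]
    return bool(np.mean(win > threshold_mm_s) >= sustained_fraction)


def bootstrap_two_sample(
    outcomes_a: ArrayLike,
    outcomes_b: ArrayLike,
    statistic: str = "mean",
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Pooled two-sample bootstrap, two-tailed.

    Both groups are pooled; each draw resamples (with replacement)
    pseudo-groups of the original sizes and records the difference of the
    group statistic ("mean" or "fraction" — identical for 0/1 outcomes).
    The p-value is the fraction of draws at least as extreme (in absolute
    value) as the observed difference, with add-one smoothing
    ``(count + 1)/(n_draws + 1)`` so p is never exactly zero.

    Returns ``{"observed", "p", "null_sd"}``.
    """
    a = np.asarray(outcomes_a, dtype=float)
    b = np.asarray(outcomes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if statistic not in ("mean", "fraction"):
        raise ValueError("statistic must be 'mean' or 'fraction'")
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    n = pool.size
    draw_a = pool[rng.integers(0, n, size=(n_draws, a.size))].mean(axis=1)
    draw_b = pool[rng.integers(0, n, size=(n_draws, b.size))].mean(axis=1)
    null = draw_a - draw_b
    count = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    return {
        "observed": float(observed),
        "p": float((count + 1) / (n_draws + 1)),
        "null_sd": float(null.std()),
    }


def bh_fdr(p_values: ArrayLike, q: float = 0.05) -> tuple[NDArray, NDArray]:
    """Benjamini–Hochberg step-up procedure.

    Sort the m p-values; find the largest i with ``p(i) <= i q / m`` and
    reject hypotheses 1..i.  Also returns BH-adjusted p-values
    (monotone ``min_{j>=i} m p(j) / j``).

    Returns ``(rejected, adjusted)`` aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ranked <= thresh)[0]
    k = passing[-1] + 1 if passing.size else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True

    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj, 0.0, 1.0)
    return rejected, adjusted


def compare_groups(
    table,
    value_column: str,
    group_column: str = "group",
    groups: tuple[str, str] = ("treated", "control"),
    statistic: str = "mean",
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Bootstrap comparison of one endpoint between two groups of trials.

    ``table`` is a pandas DataFrame (one row per trial).  NaN endpoint
    values (e.g. undefined percent change) are dropped with their trials.
    """
    sub = table.dropna(subset=[value_column])
    a = sub.loc[sub[group_column] == groups[0], value_column].to_numpy(dtype=float)
    b = sub.loc[sub[group_column] == groups[1], value_column].to_numpy(dtype=float)
    res = bootstrap_two_sample(a, b, statistic=statistic, n_draws=n_draws, seed=seed)
    res.update({"group_a": groups[0], "group_b": groups[1], "n_a": int(a.size), "n_b": int(b.size)})
    return res
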