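"""Nonparametric reference limits with order-statistic confidence intervals.

The reference interval is the central 95% of the reference distribution,
estimated by the CLSI/IFCC rank method: in a sorted vector of ``n``
reference values the lower limit sits at fractional rank
``0.025 * (n + 1)`` and the upper limit at ``0.975 * (n + 1)`` (Weibull
plotting positions), with linear interpolation between adjacent order
statistics for fractional ranks (rounding to the nearest rank is
available as a config option).

Each limit carries a 90% confidence interval.  The default construction
is distribution-free: the CI for the ``p``-th percentile is the pair of
order statistics ``(x_(l), x_(u))`` with the narrowest width ``u - l``
such that ``P(l <= K < u) >= 0.90`` where ``K ~ Binomial(n, p)`` counts
observations below the true percentile.  When no such pair exists at the
given ``n`` (the sample is too small), a seeded percentile bootstrap of
the limit is used instead and the ``ci_method`` field records which
construction produced each CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RankPair",
    "ReferenceInterval",
    "nonparametric_ri",
    "rank_ci_for_percentile",
    "reference_limit_ranks",
    "value_at_rank",
]


@dataclass(frozen=True)
class RankPair:
    """Fractional ranks of the two reference limits in a sorted sample."""

    rank_low: float
    rank_high: float
    n: int
    p_low: float = 0.025
    p_high: float = 0.975


def reference_limit_ranks(
    n: int, p_low: float = 0.025, p_high: float = 0.975
) -> RankPair:
    """Plotting-position ranks ``p * (n + 1)``, clamped into [1, n]."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < p_low < p_high < 1.0:
        raise ValueError(
            f"need 0 < p_low < p_high < 1, got ({p_low}, {p_high})"
        )
    clamp = lambda r: min(max(r, 1.0), float(n))
    return RankPair(
        rank_low=clamp(p_low * (n + 1)),
        rank_high=clamp(p_high * (n + 1)),
        n=n, p_low=p_low, p_high=p_high,
    )


def value_at_rank(sorted_values: np.ndarray, rank: float) -> float:
    """Linearly interpolated order statistic at a fractional 1-based rank."""
    sorted_values = np.asarray(sorted_values, dtype=float)
    n = sorted_values.size
    if not 1.0 <= rank <= n:
        raise ValueError(f"rank {rank} outside [1, {n}]")
    lo = math.floor(rank)
    hi = math.ceil(rank)
    frac = rank - lo
    return float(
        (1.0 - frac) * sorted_values[lo - 1] + frac * sorted_values[hi - 1]
    )


def rank_ci_for_percentile(
    n: int, p: float, confidence: float = 0.90
) -> tuple[int, int] | None:
    """Narrowest order-statistic CI ranks for the ``p``-th percentile.

    Finds the pair ``1 <= l < u <= n`` minimising ``u - l`` subject to
    binomial coverage ``P(l <= K < u) >= confidence`` with
    ``K ~ Binomial(n, p)``; width ties are broken toward symmetric tail
    probabilities.  Returns ``None`` when no pair attains the coverage
    (small-``n`` regime), signalling the bootstrap fallback.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 < p < 1.0 and 0.0 < confidence < 1.0):
        raise ValueError("p and confidence must lie in (0, 1)")
    if n < 2:
        return None
    # C[j] = P(K <= j - 1), so coverage(l, u) = C[u] - C[l]
    C = np.concatenate([[0.0], stats.binom.cdf(np.arange(n), n, p)])
    target = confidence - 1e-12
    ls = np.arange(1, n)
    us = np.searchsorted(C, C[ls] + target, side="left")
    valid = (us <= n) & (us > ls)
    if not valid.any():
        return None
    widths = np.where(valid, us - ls, n + 1)
    w_min = int(widths.min())
    best: tuple[float, int, int] | None = None
    for l in range(1, n - w_min + 1):
        u = l + w_min
        if C[u] - C[l] >= target:
            asym = abs(C[l] - (1.0 - C[u]))  # lower vs upper tail mass
            if best is None or asym < best[0]:
                best = (asym, l, u)
    assert best is not None
    return best[1], best[2]


@dataclass(frozen=True)
class ReferenceInterval:
    """Estimated reference interval for one analyte in one partition."""

    analyte_name: str | None
    partition: str | None
    n: int
    mean: float
    median: float
    lower_limit: float
    upper_limit: float
    lower_ci: tuple[float, float] | None
    upper_ci: tuple[float, float] | None
    ci_method: str  # "rank-binomial" | "bootstrap" | "unavailable"
    confidence: float = 0.90
    p_low: float = 0.025
    p_high: float = 0.975


def _bootstrap_limit_ci(
    values: np.ndarray,
    p: float,
    confidence: float,
    n_boot: int,
    rng: np.random.Generator,
    rank_mode: str,
) -> tuple[float, float]:
    """Seeded percentile bootstrap of a rank-estimated limit."""
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = np.sort(values[idx], axis=1)
    rank = min(max(p * (n + 1), 1.0), float(n))
    if rank_mode == "round":
        rank = round(rank)
    lo = math.floor(rank)
    hi = math.ceil(rank)
    frac = rank - lo
    est = (1.0 - frac) * samples[:, lo - 1] + frac * samples[:, hi - 1]
    alpha = (1.0 - confidence) / 2.0
    return (
        float(np.quantile(est, alpha)),
        float(np.quantile(est, 1.0 - alpha)),
    )


def nonparametric_ri(
    values: np.ndarray,
    *,
    p_low: float = 0.025,
    p_high: float = 0.975,
    confidence: float = 0.90,
    ci_method: str = "auto",
    n_boot: int = 2000,
    seed: int = 0,
    rank_mode: str = "interpolate",
    analyte_name: str | None = None,
    partition: str | None = None,
) -> ReferenceInterval:
    """Estimate the reference interval of an (outlier-screened) vector.

    ``ci_method`` is ``"auto"`` (rank-binomial when attainable, else
    bootstrap), ``"rank-binomial"``, or ``"bootstrap"``.  ``rank_mode``
    selects interpolation (default) or rounding of fractional ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to estimate an interval")
    if rank_mode not in ("interpolate", "round"):
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    if ci_method not in ("auto", "rank-binomial", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    srt = np.sort(values)
    n = srt.size
    ranks = reference_limit_ranks(n, p_low, p_high)
    r_lo, r_hi = ranks.rank_low, ranks.rank_high
    if rank_mode == "round":
        r_lo, r_hi = float(round(r_lo)), float(round(r_hi))
    lower = value_at_rank(srt, r_lo)
    upper = value_at_rank(srt, r_hi)

    cis: list[tuple[float, float] | None] = []
    methods: list[str] = []
    rng = np.random.default_rng(seed)
    for p in (p_low, p_high):
        pair = (
            rank_ci_for_percentile(n, p, confidence)
            if ci_method in ("auto", "rank-binomial") else None
        )
        if pair is not None:
            l, u = pair
            cis.append((float(srt[l - 1]), float(srt[u - 1])))
            methods.append("rank-binomial")
        elif ci_method == "rank-binomial":
            cis.append(None)
            methods.append("unavailable")
        else:
            cis.append(_bootstrap_limit_ci(
                srt, p, confidence, n_boot, rng, rank_mode
            ))
            methods.append("bootstrap")

    method = methods[0] if methods[0] == methods[1] else "+".join(methods)
    return ReferenceInterval(
        analyte_name=analyte_name, partition=partition, n=n,
        mean=float(np.mean(srt)), median=float(np.median(srt)),
        lower_limit=lower, upper_limit=upper,
        lower_ci=cis[0], upper_ci=cis[1],
        ci_method=method, confidence=confidence,
        p_low=p_low, p_high=p_high,
    )
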