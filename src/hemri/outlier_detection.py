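"""Dixon/Reed extreme-value screening.

Before estimating reference limits, each analyte x partition vector is
screened with the one-third-range rule: sort the data, and for each tail
compute the gap ``D`` between the extreme value and its nearest distinct
neighbour and the full range ``R``; the extreme is rejected when
``D/R > 1/3``.  By default the rule is re-applied to the reduced vector
until no further removal (capped), both tails are tested on every pass,
and all tied copies of a flagged extreme are removed together.  The rule
is location- and scale-free, so screening is invariant under affine
transforms of the data.

The rule degenerates on tiny samples (it would flag an extreme of
``{1, 2, 3}``), so vectors shorter than ``min_n`` are passed through
unchanged with a warning marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OutlierScreenResult", "RemovedValue", "dixon_reed_screen"]

ONE_THIRD = 1.0 / 3.0


@dataclass(frozen=True)
class RemovedValue:
    """One rejected extreme: the D/R evidence at the pass that removed it."""

    value: float
    pass_index: int
    tail: str  # "low" | "high"
    d: float   # gap to nearest distinct neighbour at test time
    r: float   # full range at test time
    count: int = 1  # tied copies removed together

    @property
    def ratio(self) -> float:
        return self.d / self.r if self.r > 0 else 0.0


@dataclass(frozen=True)
class OutlierScreenResult:
    analyte_name: str | None
    partition: str | None
    retained: np.ndarray
    removed: list[RemovedValue] = field(default_factory=list)
    n_passes: int = 0
    skipped_small_n: bool = False

    @property
    def n_removed(self) -> int:
        return sum(rv.count for rv in self.removed)

    @property
    def n_input(self) -> int:
        return self.retained.size + self.n_removed


def _screen_pass(values: np.ndarray, pass_index: int):
    """One two-tailed application of the one-third-range rule.

    Returns (retained, removals) for this pass.  ``values`` must be
    sorted ascending.  With fewer than three distinct values, or zero
    range, nothing is removed (the D/R ratio is taken as 0 when R = 0).
    """
    distinct, counts = np.unique(values, return_counts=True)
    if distinct.size < 3:
        return values, []
    r = distinct[-1] - distinct[0]
    removals: list[RemovedValue] = []
    drop = np.zeros(distinct.size, dtype=bool)

    # strict inequality, with a relative guard so a ratio at exactly 1/3
    # is never flagged through floating-point noise
    threshold = ONE_THIRD * (1.0 + 1e-9)
    d_low = distinct[1] - distinct[0]
    if d_low / r > threshold:
        removals.append(RemovedValue(
            value=float(distinct[0]), pass_index=pass_index, tail="low",
            d=float(d_low), r=float(r), count=int(counts[0]),
        ))
        drop[0] = True
    d_high = distinct[-1] - distinct[-2]
    if d_high / r > threshold:
        removals.append(RemovedValue(
            value=float(distinct[-1]), pass_index=pass_index, tail="high",
            d=float(d_high), r=float(r), count=int(counts[-1]),
        ))
        drop[-1] = True
    if not removals:
        return values, []
    keep = ~np.isin(values, distinct[drop])
    return values[keep], removals


def dixon_reed_screen(
    values: np.ndarray,
    *,
    iterate: bool = True,
    min_n: int = 20,
    max_passes: int = 10,
    analyte_name: str | None = None,
    partition: str | None = None,
) -> OutlierScreenResult:
    """Screen a vector with the Dixon/Reed one-third-range rule.

    Parameters
    ----------
    values
        Finite numeric observations (any order).
    iterate
        Re-apply the rule to the reduced vector until a pass removes
        nothing (capped at ``max_passes``); ``False`` runs a single pass.
    min_n
        Vectors shorter than this are returned unchanged with
        ``skipped_small_n=True``.

    Returns
    -------
    OutlierScreenResult
        ``retained`` is sorted ascending; ``removed`` logs each rejected
        extreme with its D, R and pass index.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot screen an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    current = np.sort(values)
    if values.size < min_n:
        return OutlierScreenResult(
            analyte_name=analyte_name, partition=partition,
            retained=current, skipped_small_n=True,
        )

    removed: list[RemovedValue] = []
    n_passes = 0
    while n_passes < (max_passes if iterate else 1):
        n_passes += 1
        current, removals = _screen_pass(current, n_passes)
        if not removals:
            break
        removed.extend(removals)
    return OutlierScreenResult(
        analyte_name=analyte_name, partition=partition,
        retained=current, removed=removed, n_passes=n_passes,
    )
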