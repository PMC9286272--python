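"""Out-of-range (OOR) misclassification scoring.

When an interval derived elsewhere (typically the analyzer manual's
"manufacturer" interval) is applied to a local population, some healthy
subjects fall outside it.  This module counts, per analyte, the subjects
below and above a candidate interval and reports the OOR proportion,
quantifying the misclassification that motivates locally established
reference intervals.  Boundary values count as in range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["OORRow", "count_oor", "oor_frame", "oor_table"]


def count_oor(
    values: np.ndarray, interval: tuple[float, float]
) -> tuple[int, int]:
    """``(#{v < low}, #{v > high})``; values at a limit are in range."""
    low, high = interval
    if low > high:
        raise ValueError(f"inverted interval ({low}, {high})")
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    return int(np.sum(values < low)), int(np.sum(values > high))


@dataclass(frozen=True)
class OORRow:
    """Per-analyte misclassification against a candidate interval."""

    analyte_name: str
    manufacturer_interval: tuple[float, float]
    established_interval: tuple[float, float] | None
    below_count: int
    above_count: int
    denominator: int

    @property
    def total_oor(self) -> int:
        return self.below_count + self.above_count

    @property
    def percent(self) -> float:
        """OOR share of the denominator, one decimal."""
        return round(100.0 * self.total_oor / self.denominator, 1)


def oor_table(
    dataset: pd.DataFrame,
    manufacturer_intervals: Mapping[str, tuple[float, float]],
    established_intervals: Mapping[str, tuple[float, float]] | None = None,
    *,
    analytes: Sequence[str] | None = None,
    denominator_mode: str = "enrolled",
) -> list[OORRow]:
    """Score every analyte's values against the manufacturer interval.

    ``denominator_mode`` is ``"enrolled"`` (all rows of ``dataset``, the
    convention under which published OOR percentages are internally
    consistent) or ``"per-analyte"`` (non-missing values of each
    analyte).  ``established_intervals`` are carried through for
    reporting alongside.
    """
    if denominator_mode not in ("enrolled", "per-analyte"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    analytes = list(analytes) if analytes is not None else list(manufacturer_intervals)
    rows = []
    for analyte in analytes:
        if analyte not in manufacturer_intervals:
            raise KeyError(f"no manufacturer interval for analyte {analyte!r}")
        if analyte not in dataset.columns:
            raise KeyError(f"analyte column {analyte!r} missing from dataset")
        values = dataset[analyte].to_numpy(dtype=float)
        below, above = count_oor(values, manufacturer_intervals[analyte])
        denominator = (
            len(dataset) if denominator_mode == "enrolled"
            else int(np.sum(~np.isnan(values)))
        )
        rows.append(OORRow(
            analyte_name=analyte,
            manufacturer_interval=tuple(manufacturer_intervals[analyte]),
            established_interval=(
                tuple(established_intervals[analyte])
                if established_intervals and analyte in established_intervals
                else None
            ),
            below_count=below, above_count=above, denominator=denominator,
        ))
    return rows


def oor_frame(rows: Sequence[OORRow]) -> pd.DataFrame:
    """Render OOR rows as a table mirroring the published layout."""
    return pd.DataFrame([
        {
            "analyte": r.analyte_name,
            "manufacturer_low": r.manufacturer_interval[0],
            "manufacturer_high": r.manufacturer_interval[1],
            "established_low": r.established_interval[0] if r.established_interval else np.nan,
            "established_high": r.established_interval[1] if r.established_interval else np.nan,
            "below_n": r.below_count,
            "above_n": r.above_count,
            "total_n": r.total_oor,
            "denominator": r.denominator,
            "percent": r.percent,
        }
        for r in rows
    ])
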