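"""Synthetic CBC cohort generation calibrated to quantile triples.

The simulator reproduces the statistical structure a reference-interval
study assumes: a fixed number of subjects per partition (trimesters T1-T3
and non-pregnant NP), a fraction of subjects who fail eligibility
screening for realistic reasons (positive serology, chronic disease,
recent transfusion/donation, obesity, hypertension), analyte marginals
whose 2.5th / 50th / 97.5th percentiles match supplied calibration
targets, and sporadic gross outliers injected at a known ground truth.

Each analyte marginal is a three-parameter (shifted) lognormal solved in
closed form from its quantile triple; a symmetric triple short-circuits
to a normal, and a left-skewed triple is handled by reflection.  Analyte
values are truncated at zero (concentrations and fractions are
non-negative).  Marginals are independent across analytes: physiological
couplings such as Hgb-HCT are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalyteSpec",
    "CalibratedDistribution",
    "CalibrationError",
    "CohortConfig",
    "calibrate_distribution",
    "generate_study",
    "inject_outliers",
]

_Z_TAIL = float(stats.norm.ppf(0.975))  # 1.959963985...

#: Screening / demographic columns emitted by :func:`generate_study`,
#: in order, before the analyte columns.  This is the versioned cohort
#: schema consumed by ``cohort_screening`` and ``pipeline_io``.
SCHEMA_VERSION = "1"
DEMOGRAPHIC_COLUMNS = (
    "participant_id", "partition", "age", "residence", "altitude_class",
    "weight_kg", "height_m", "systolic_bp", "diastolic_bp",
)
FLAG_COLUMNS = (
    "hiv", "hbsag", "hcv", "syphilis", "crp",
    "hemoparasite", "intestinal_parasite",
    "chronic_disease", "transfusion_1y", "donation_3m", "admission_1y",
    "surgery_3y", "malaria_6m", "tb_2y", "medication", "iron_folate",
    "substance_use", "obstetric_complication", "chemical_exposure",
    "febrile", "exercise_prior",
    "menstruating", "breastfeeding", "oral_contraceptive",
    "specimen_quality_fail",
)


class CalibrationError(ValueError):
    """Raised when a quantile triple cannot define a valid distribution."""


@dataclass(frozen=True)
class AnalyteSpec:
    """Simulation calibration for one analyte.

    ``targets`` maps each partition label to the (2.5th percentile,
    median, 97.5th percentile) triple the simulated marginal must match.
    """

    name: str
    units: str
    targets: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for part, (lo, med, hi) in self.targets.items():
            if not (lo < med < hi):
                raise CalibrationError(
                    f"{self.name}/{part}: targets must satisfy "
                    f"q_low < q_med < q_high, got ({lo}, {med}, {hi})"
                )

    @property
    def family(self) -> str:
        """Distribution family tag of the first partition's triple."""
        lo, med, hi = next(iter(self.targets.values()))
        return "symmetric-normal" if np.isclose(hi - med, med - lo) \
            else "three-parameter-skewed"


@dataclass(frozen=True)
class CalibratedDistribution:
    """A continuous marginal whose anchor quantiles match a target triple.

    ``family`` is ``"normal"`` (symmetric triple) or ``"lognormal"``
    (shifted lognormal; ``sign=-1`` marks a reflected, left-skewed fit).
    """

    family: str
    sign: int
    shift: float
    scale: float
    sigma: float

    def _base(self):
        if self.family == "normal":
            return stats.norm(loc=self.shift, scale=self.scale)
        return stats.lognorm(s=self.sigma, loc=self.shift, scale=self.scale)

    def ppf(self, p):
        p = np.asarray(p, dtype=float)
        if self.sign < 0:
            return -self._base().ppf(1.0 - p)
        return self._base().ppf(p)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.sign < 0:
            return self._base().sf(-x)
        return self._base().cdf(x)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        draws = self._base().rvs(size=size, random_state=rng)
        return -draws if self.sign < 0 else draws


def calibrate_distribution(
    q_low: float,
    q_med: float,
    q_high: float,
    *,
    tol: float = 1e-6,
) -> CalibratedDistribution:
    """Solve a three-parameter family so its 2.5th/50th/97.5th quantiles
    hit ``(q_low, q_med, q_high)``.

    The family is a shifted lognormal ``shift + LogNormal(mu, sigma)``
    (reflected when the triple is left-skewed), which admits a closed-form
    solution for a symmetric-probability triple: with ``a = q_med - q_low``,
    ``b = q_high - q_med`` and ``z`` the 97.5th standard-normal quantile,

        sigma = ln(b/a) / z,   e^mu = a*b / (b - a),   shift = q_med - e^mu.

    An (effectively) symmetric triple degenerates to
    ``Normal(q_med, (q_high - q_low) / (2 z))``.

    Raises
    ------
    CalibrationError
        If the triple is non-monotone, or the solved parameters fail to
        reproduce the anchors to within ``tol``.
    """
    if not np.all(np.isfinite([q_low, q_med, q_high])):
        raise CalibrationError("targets must be finite")
    if not (q_low < q_med < q_high):
        raise CalibrationError(
            f"targets must satisfy q_low < q_med < q_high, "
            f"got ({q_low}, {q_med}, {q_high})"
        )
    a = q_med - q_low
    b = q_high - q_med
    span = q_high - q_low

    if abs(b - a) <= 1e-9 * span:
        dist = CalibratedDistribution(
            family="normal", sign=1, shift=q_med, scale=span / (2 * _Z_TAIL),
            sigma=0.0,
        )
    elif b > a:  # right skew
        sigma = np.log(b / a) / _Z_TAIL
        emu = a * b / (b - a)
        dist = CalibratedDistribution(
            family="lognormal", sign=1, shift=q_med - emu, scale=emu,
            sigma=sigma,
        )
    else:  # left skew: reflect the triple and fit right-skewed
        sigma = np.log(a / b) / _Z_TAIL
        emu = a * b / (a - b)
        dist = CalibratedDistribution(
            family="lognormal", sign=-1, shift=-q_med - emu, scale=emu,
            sigma=sigma,
        )

    anchors = np.array([0.025, 0.5, 0.975])
    resid = np.abs(dist.ppf(anchors) - np.array([q_low, q_med, q_high]))
    if np.max(resid) > tol:
        raise CalibrationError(
            f"calibration residuals {resid} exceed tol={tol} for targets "
            f"({q_low}, {q_med}, {q_high}); solved {dist}"
        )
    return dist


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated study cohort.

    Defaults reproduce the study structure the pipeline targets: four
    partitions of 150 subjects each with ~11.2% of subjects ineligible,
    and roughly one gross outlier per analyte within each partition.
    """

    partitions: tuple[str, ...] = ("T1", "T2", "T3", "NP")
    n_per_partition: int = 150
    ineligible_fraction: float = 0.112
    ineligibility_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "serology": 0.40,
            "chronic_disease": 0.20,
            "transfusion_donation": 0.12,
            "obesity": 0.16,
            "high_bp": 0.12,
        }
    )
    outlier_rate: float = 1.0 / 150.0
    outlier_magnitude: float = 4.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_partition < 1:
            raise ValueError("n_per_partition must be >= 1")
        for name, value in [
            ("ineligible_fraction", self.ineligible_fraction),
            ("outlier_rate", self.outlier_rate),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if any(w < 0 for w in self.ineligibility_weights.values()):
            raise ValueError("ineligibility weights must be non-negative")


def inject_outliers(
    values: np.ndarray,
    rate: float,
    magnitude: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, list[int]]:
    """Displace ``round(rate * n)`` entries to gross-outlier positions.

    Each selected entry is moved ``m * IQR`` beyond the clean extreme of
    a randomly chosen tail, where ``m`` is ``magnitude`` jittered upward
    by up to 25% so simultaneous outliers do not coincide.  A low-side
    displacement that would go negative is flipped to the high side
    (analyte values are non-negative).  Returns the modified copy and
    the displaced indices, the ground truth for screening tests.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot inject outliers into an empty vector")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    k = int(round(rate * values.size))
    out = values.copy()
    if k == 0:
        return out, []
    idx = rng.choice(values.size, size=k, replace=False)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = values.min(), values.max()
    for i in idx:
        m = magnitude * (1.0 + 0.25 * rng.random())
        if rng.random() < 0.5 and lo - m * iqr > 0:
            out[i] = lo - m * iqr
        else:
            out[i] = hi + m * iqr
    return out, sorted(int(i) for i in idx)


def _demographics(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    height = np.clip(rng.normal(1.60, 0.06, n), 1.45, 1.85)
    bmi = np.clip(rng.normal(22.5, 2.5, n), 16.5, 29.4)
    return {
        "age": rng.integers(15, 50, n),
        "residence": np.where(rng.random(n) < 0.52, "urban", "rural"),
        "altitude_class": np.where(rng.random(n) < 0.547, "lowland", "highland"),
        "height_m": np.round(height, 3),
        "weight_kg": np.round(bmi * height**2, 1),
        "systolic_bp": np.round(np.clip(rng.normal(112, 10, n), 90, 140)),
        "diastolic_bp": np.round(np.clip(rng.normal(72, 8, n), 55, 90)),
    }


def _apply_ineligibility(
    frame: pd.DataFrame,
    rows: Sequence[int],
    reasons: Sequence[str],
    rng: np.random.Generator,
) -> None:
    """Mutate the given rows in place so exactly the drawn rule fires."""
    serology_flags = ("hiv", "hbsag", "hcv", "syphilis", "crp")
    for row, reason in zip(rows, reasons):
        if reason == "serology":
            frame.loc[row, serology_flags[rng.integers(len(serology_flags))]] = True
        elif reason == "chronic_disease":
            frame.loc[row, "chronic_disease"] = True
        elif reason == "transfusion_donation":
            col = "transfusion_1y" if rng.random() < 0.5 else "donation_3m"
            frame.loc[row, col] = True
        elif reason == "obesity":
            bmi = rng.uniform(30.0, 36.0)
            frame.loc[row, "weight_kg"] = round(
                bmi * frame.loc[row, "height_m"] ** 2, 1
            )
        elif reason == "high_bp":
            frame.loc[row, "systolic_bp"] = float(rng.integers(142, 171))
        else:
            raise ValueError(f"unknown ineligibility reason {reason!r}")


def generate_study(
    config: CohortConfig,
    analytes: Sequence[AnalyteSpec],
) -> pd.DataFrame:
    """Generate one participant table (one row per enrolled subject).

    Ineligible subjects carry the screening fields that trigger their
    exclusion; every subject carries analyte values drawn from the
    calibrated per-partition marginals, with gross outliers injected at
    ``config.outlier_rate``.  Fully reproducible from ``config.random_seed``;
    ground-truth outlier indices (row positions per analyte/partition) are
    stored in ``df.attrs["outlier_truth"]``.
    """
    rng = np.random.default_rng(config.random_seed)
    for spec in analytes:
        missing = [p for p in config.partitions if p not in spec.targets]
        if missing:
            raise KeyError(
                f"analyte {spec.name!r} lacks calibration for partitions {missing}"
            )

    frames: list[pd.DataFrame] = []
    truth: dict[tuple[str, str], list[int]] = {}
    sid = 0
    for part in config.partitions:
        n = config.n_per_partition
        cols: dict[str, object] = {
            "participant_id": [f"S{sid + i:04d}" for i in range(n)],
            "partition": [part] * n,
        }
        sid += n
        cols.update(_demographics(n, rng))
        for flag in FLAG_COLUMNS:
            cols[flag] = np.zeros(n, dtype=bool)
        frame = pd.DataFrame(cols)

        ineligible = rng.random(n) < config.ineligible_fraction
        weights = config.ineligibility_weights
        names = list(weights)
        p = np.array([weights[k] for k in names], dtype=float)
        p = p / p.sum()
        reasons = rng.choice(names, size=int(ineligible.sum()), p=p)
        _apply_ineligibility(frame, list(frame.index[ineligible]), reasons, rng)

        for spec in analytes:
            dist = calibrate_distribution(*spec.targets[part])
            vals = dist.rvs(n, rng)
            for _ in range(100):  # truncate at zero by resampling
                neg = vals < 0
                if not neg.any():
                    break
                vals[neg] = dist.rvs(int(neg.sum()), rng)
            vals = np.maximum(vals, 0.0)
            vals, idx = inject_outliers(
                vals, config.outlier_rate, config.outlier_magnitude, rng
            )
            frame[spec.name] = vals
            truth[(spec.name, part)] = idx
        frames.append(frame)

    df = pd.concat(frames, ignore_index=True)
    df.attrs["outlier_truth"] = truth
    df.attrs["schema_version"] = SCHEMA_VERSION
    return df
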