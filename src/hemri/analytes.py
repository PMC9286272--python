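"""Default analyte panel, calibration targets, and manufacturer intervals.

The panel is the 19-parameter output of a 3-part differential hematology
analyzer (Mindray BC-3000 plus class): total WBC with a three-way
differential (lymphocyte / mid-cell / granulocyte, absolute and percent),
the red-cell series (RBC, Hgb, HCT, MCV, MCH, MCHC, RDW-CV, RDW-SD) and the
platelet series (PLT, MPV, PDW, PCT).

Calibration targets are (2.5th percentile, median, 97.5th percentile)
triples per partition for a cohort of reproductive-age women from a
highland East African study population, stratified into pregnancy
trimesters (T1, T2, T3) and non-pregnant women (NP).  ``PREGNANT_POOLED``
carries the corresponding triples for all pregnant women combined.

One published triple is internally inconsistent: the non-pregnant PDW
median is printed as 14.0, *below* the printed 2.5th percentile of 14.1.
A median target must lie strictly inside the interval, so the NP PDW
median here is the published mean (14.5) instead; this substitution is
synthetic and affects only the simulator's default calibration.
"""

from __future__ import annotations

from .synthetic_data import AnalyteSpec

PARTITIONS = ("T1", "T2", "T3", "NP")

#: Pregnancy partitions (trimesters), in gestational order.
PREGNANT_PARTITIONS = ("T1", "T2", "T3")

# name -> (units, {partition: (q2.5, median, q97.5)})
_PANEL = {
    "WBC": ("10^9/L", {
        "T1": (3.6, 7.7, 13.2),
        "T2": (4.56, 8.2, 13.59),
        "T3": (4.56, 8.6, 13.62),
        "NP": (3.6, 6.5, 10.3),
    }),
    "Lymph#": ("10^9/L", {
        "T1": (1.1, 2.0, 2.8),
        "T2": (1.03, 1.8, 2.6),
        "T3": (1.13, 1.9, 2.77),
        "NP": (1.24, 2.3, 3.7),
    }),
    "MID#": ("10^9/L", {
        "T1": (0.2, 0.5, 0.9),
        "T2": (0.2, 0.5, 1.08),
        "T3": (0.2, 0.5, 1.08),
        "NP": (0.2, 0.4, 0.8),
    }),
    "Gran#": ("10^9/L", {
        "T1": (2.23, 5.3, 8.62),
        "T2": (2.42, 5.9, 9.78),
        "T3": (2.61, 6.2, 10.23),
        "NP": (1.3, 3.5, 6.9),
    }),
    "Lymph%": ("%", {
        "T1": (12.78, 24.9, 45.60),
        "T2": (10.96, 20.8, 32.96),
        "T3": (13.53, 22.2, 45.68),
        "NP": (19.9, 35.7, 57.1),
    }),
    "MID%": ("%", {
        "T1": (3.94, 6.8, 12.00),
        "T2": (3.74, 6.65, 9.60),
        "T3": (3.83, 6.8, 12.33),
        "NP": (3.9, 6.8, 10.9),
    }),
    "Gran%": ("%", {
        "T1": (45.86, 65.8, 80.42),
        "T2": (58.62, 70.4, 81.50),
        "T3": (60.53, 71.9, 82.55),
        "NP": (33.4, 56.1, 71.8),
    }),
    "Hgb": ("g/dL", {
        "T1": (10.37, 12.3, 13.53),
        "T2": (9.99, 11.6, 12.90),
        "T3": (10.68, 12.7, 13.71),
        "NP": (12.4, 13.1, 14.3),
    }),
    "RBC": ("10^12/L", {
        "T1": (3.58, 3.86, 4.90),
        "T2": (3.35, 3.49, 4.01),
        "T3": (3.76, 3.78, 4.99),
        "NP": (4.44, 4.76, 5.01),
    }),
    "HCT": ("%", {
        "T1": (34.86, 41.05, 47.80),
        "T2": (33.93, 40.3, 46.19),
        "T3": (32.33, 39.9, 45.98),
        "NP": (38.4, 44.6, 50.1),
    }),
    "MCV": ("fL", {
        "T1": (86.67, 94.2, 103.03),
        "T2": (86.10, 94.4, 103.58),
        "T3": (87.62, 95.0, 105.77),
        "NP": (86.1, 92.6, 101.6),
    }),
    "MCH": ("pg", {
        "T1": (26.40, 30.0, 32.94),
        "T2": (26.89, 30.1, 33.20),
        "T3": (27.51, 30.4, 33.99),
        "NP": (27.1, 29.8, 32.4),
    }),
    "MCHC": ("g/dL", {
        "T1": (30.30, 32.5, 33.66),
        "T2": (30.13, 31.9, 33.2),
        "T3": (30.31, 32.6, 33.86),
        "NP": (30.4, 31.9, 34.1),
    }),
    "RDW-CV": ("%", {
        "T1": (12.44, 14.1, 15.99),
        "T2": (12.52, 14.2, 17.00),
        "T3": (12.62, 13.9, 16.20),
        "NP": (12.1, 12.4, 14.7),
    }),
    "RDW-SD": ("fL", {
        "T1": (40.60, 46.5, 55.50),
        "T2": (42.28, 49.6, 57.99),
        "T3": (41.30, 49.2, 59.84),
        "NP": (39.7, 45.4, 57.3),
    }),
    "PLT": ("10^9/L", {
        "T1": (167.05, 273.0, 390.00),
        "T2": (149.58, 253.0, 373.32),
        "T3": (124.60, 245.0, 356.90),
        "NP": (173.0, 304.0, 456.0),
    }),
    "MPV": ("fL", {
        "T1": (6.73, 8.6, 9.80),
        "T2": (7.05, 8.78, 10.25),
        "T3": (7.40, 8.85, 10.30),
        "NP": (7.1, 8.5, 10.1),
    }),
    "PDW": ("", {
        "T1": (15.10, 15.7, 16.36),
        "T2": (15.22, 15.8, 16.48),
        "T3": (15.16, 15.9, 16.57),
        # Published NP median (14.0) lies outside the published interval;
        # the published mean (14.5) is substituted (synthetic fix, see
        # module docstring).
        "NP": (14.1, 14.5, 15.5),
    }),
    "PCT": ("%", {
        "T1": (0.152, 0.22, 0.316),
        "T2": (0.110, 0.217, 0.321),
        "T3": (0.118, 0.21, 0.321),
        "NP": (0.168, 0.267, 0.382),
    }),
}

#: Quantile triples for the pooled pregnant cohort (all trimesters combined).
PREGNANT_POOLED: dict[str, tuple[float, float, float]] = {
    "WBC": (4.0, 8.1, 13.2),
    "Lymph#": (1.1, 1.9, 2.71),
    "MID#": (0.2, 0.5, 1.0),
    "Gran#": (2.2, 5.8, 9.8),
    "Lymph%": (12.9, 22.5, 38.1),
    "MID%": (4.2, 7.4, 11.6),
    "Gran%": (50.5, 70.4, 81.5),
    "Hgb": (10.1, 11.9, 13.7),
    "RBC": (3.45, 3.52, 4.67),
    "HCT": (33.5, 40.4, 46.5),
    "MCV": (84.8, 94.7, 103.5),
    "MCH": (27.5, 30.2, 33.0),
    "MCHC": (30.3, 31.9, 33.7),
    "RDW-CV": (12.5, 14.7, 16.1),
    "RDW-SD": (42.1, 48.3, 58.2),
    "PLT": (132.0, 253.0, 373.0),
    "MPV": (7.2, 8.7, 10.2),
    "PDW": (15.2, 15.8, 16.4),
    "PCT": (0.121, 0.217, 0.316),
}

#: Analyzer-manual ("manufacturer") reference intervals used for
#: out-of-range misclassification scoring.
MANUFACTURER_INTERVALS: dict[str, tuple[float, float]] = {
    "WBC": (4.0, 10.0),
    "Lymph#": (0.8, 4.0),
    "MID#": (0.1, 1.5),
    "Gran#": (2.0, 7.0),
    "Lymph%": (20.0, 40.0),
    "MID%": (3.0, 15.0),
    "Gran%": (50.0, 70.0),
    "Hgb": (11.0, 15.0),
    "RBC": (3.50, 5.00),
    "HCT": (37.0, 47.0),
    "MCV": (80.0, 100.0),
    "MCH": (27.0, 34.0),
    "MCHC": (32.0, 36.0),
    "RDW-CV": (11.0, 16.0),
    "RDW-SD": (35.0, 56.0),
    "PLT": (100.0, 300.0),
    "MPV": (6.5, 12.0),
    "PDW": (9.0, 17.0),
    "PCT": (0.108, 0.282),
}

ANALYTE_NAMES: tuple[str, ...] = tuple(_PANEL)


def default_analytes() -> list[AnalyteSpec]:
    """The full 19-analyte panel with per-partition calibration triples."""
    return [
        AnalyteSpec(name=name, units=units, targets=dict(targets))
        for name, (units, targets) in _PANEL.items()
    ]
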