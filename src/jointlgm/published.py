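"""Published estimates from the EMPHACIS mesothelioma trial analyses.

The trial's patient-level data are proprietary, but the published
per-item coefficient tables are public and self-consistent, which makes two
desk checks possible without any data access:

* the overall treatment hazard ratio of the shared random-effects model
  must equal ``exp(log(direct HR) + gamma_1 * beta_11)`` row by row, up to
  the 2-decimal rounding of the inputs;
* the naive time-varying Cox per-point hazard ratios imply percent hazard
  increases per 10-point score rise of roughly 9% (cough) to 23% (the
  five-item average symptom burden index, ASBI5).

``TABLE_NAIVE_TRAJ`` holds the naive-model and trajectory-link estimates
(per item: naive per-point and treatment HRs; trajectory-model growth means
``beta_00, beta_10, beta_11, beta_20``, per-point association HR ``e^gamma``
and direct treatment HR ``e^alpha``).  ``TABLE_REM`` holds the shared
random-effects estimates (growth means, link coefficients
``gamma_0, gamma_1, gamma_2``, direct HR ``e^alpha`` and overall HR
``e^(alpha + gamma_1 beta_11)``).  ``HR_TREATMENT_ONLY`` is the
treatment-only Cox hazard ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["TABLE_NAIVE_TRAJ", "TABLE_REM", "HR_TREATMENT_ONLY",
           "overall_hr_consistency", "naive_hr10_range"]

HR_TREATMENT_ONLY = 0.73

TABLE_NAIVE_TRAJ = pd.DataFrame(
    [
        ("anorexia",     1.011, 0.67, 28.8,  5.93, -0.138, -1.150, 1.014, 0.66),
        ("cough",        1.009, 0.72, 14.7, -1.29, -0.410,  0.193, 1.015, 0.72),
        ("dyspnea",      1.010, 0.73, 32.6,  2.74, -1.280, -0.327, 1.011, 0.73),
        ("fatigue",      1.012, 0.70, 36.4,  6.62, -1.033, -1.032, 1.014, 0.70),
        ("pain",         1.016, 0.70, 26.8,  0.63, -0.891,  0.061, 1.018, 0.71),
        ("interference", 1.013, 0.66, 41.5,  5.87, -0.881, -0.905, 1.015, 0.66),
        ("qol",          1.012, 0.69, 41.1,  4.86, -0.873, -0.710, 1.014, 0.69),
        ("symptoms",     1.012, 0.68, 34.1,  3.08, -0.805, -0.432, 1.014, 0.68),
        ("asbi5",        1.021, 0.69, 27.9,  3.09, -0.866, -0.435, 1.025, 0.68),
        ("asbi8",        1.019, 0.67, 32.0,  3.72, -0.883, -0.516, 1.022, 0.67),
    ],
    columns=["item", "naive_hr_score", "naive_hr_trt", "beta_00", "beta_10",
             "beta_11", "beta_20", "hr_score", "hr_trt"],
)

TABLE_REM = pd.DataFrame(
    [
        ("anorexia",     28.8,  6.09, -0.37, -1.12, 0.018, 0.060, 0.293, 0.66, 0.65),
        ("cough",        14.7, -1.24, -0.62,  0.26, 0.017, 0.083, 0.359, 0.74, 0.70),
        ("dyspnea",      32.6,  2.89, -1.60, -0.25, 0.010, 0.064, 0.260, 0.76, 0.68),
        ("fatigue",      36.3,  6.92, -1.29, -1.03, 0.014, 0.041, 0.104, 0.69, 0.65),
        ("pain",         26.8,  0.84, -1.30,  0.16, 0.017, 0.087, 0.333, 0.74, 0.66),
        ("interference", 41.5,  6.08, -1.12, -0.88, 0.017, 0.040, 0.127, 0.65, 0.62),
        ("qol",          41.1,  5.05, -1.06, -0.70, 0.015, 0.032, 0.070, 0.67, 0.65),
        ("symptoms",     34.1,  3.26, -1.08, -0.39, 0.015, 0.059, 0.219, 0.69, 0.65),
        ("asbi5",        27.9,  3.23, -1.17, -0.35, 0.024, 0.105, 0.414, 0.71, 0.63),
        ("asbi8",        32.0,  3.86, -1.14, -0.45, 0.022, 0.086, 0.317, 0.69, 0.62),
    ],
    columns=["item", "beta_00", "beta_10", "beta_11", "beta_20",
             "gamma_0", "gamma_1", "gamma_2", "hr_direct", "hr_overall"],
)


def overall_hr_consistency() -> pd.DataFrame:
    """Recompute the overall treatment HR from each published row.

    Returns the table with ``hr_overall_computed =
    exp(log(hr_direct) + gamma_1 * beta_11)`` and the discrepancy against
    the published overall HR (which should be within the 2-dp input
    rounding, +/-0.01).
    """
    t = TABLE_REM.copy()
    t["hr_overall_computed"] = np.exp(
        np.log(t["hr_direct"]) + t["gamma_1"] * t["beta_11"])
    t["discrepancy"] = t["hr_overall_computed"] - t["hr_overall"]
    return t


def naive_hr10_range() -> tuple:
    """(min, max) percent hazard increase per 10 points, naive model."""
    from .effects import hr_per_k_points

    pct = [hr_per_k_points(np.log(h), 10.0)
           for h in TABLE_NAIVE_TRAJ["naive_hr_score"]]
    return float(min(pct)), float(max(pct))
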