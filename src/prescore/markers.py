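"""Risk-marker panel definitions.

The PRE score tracks eight modifiable risk markers of kidney and
cardiovascular disease progression: glycated hemoglobin (HbA1c), systolic
blood pressure, urinary albumin-to-creatinine ratio (UACR), body weight,
hemoglobin, HDL cholesterol, LDL cholesterol and serum potassium.  UACR is
strongly right-skewed and is modelled on the natural-log scale everywhere
(Cox covariate, simulation, imputation); all other markers enter untouched.

:class:`MarkerSpec` carries a marker's identity, its measurement scale, and
the simulation parameters that define its baseline distribution and its
short-term response to treatment.  For ``natural_log`` markers every
distributional parameter (mean, SD, shifts, noise) lives on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InputError

IDENTITY = "identity"
NATURAL_LOG = "natural_log"
TRANSFORMS = (IDENTITY, NATURAL_LOG)

OUTCOMES = ("kidney", "cv")


@dataclass(frozen=True)
class MarkerSpec:
    """One risk marker and its simulation parameters.

    Parameters
    ----------
    name
        Column-safe identifier (``hba1c``, ``sbp``, ``uacr``, ...).
    unit
        Free-text measurement unit on the native scale.
    transform
        ``"identity"`` or ``"natural_log"``; the scale on which the marker
        enters the Cox model and on which shifts/noise are applied.
    baseline_mean, baseline_sd
        Baseline distribution on the transform scale (log scale for
        ``natural_log`` markers, which therefore always generate strictly
        positive native values).
    treatment_shift
        Placebo-corrected mean change at follow-up, transform scale.
    placebo_drift
        Mean change in the placebo arm, transform scale.
    fu_noise_sd
        Within-person SD of the follow-up measurement around its expected
        value, transform scale.  ``None`` falls back to
        ``0.5 * baseline_sd``.
    """

    name: str
    unit: str
    transform: str = IDENTITY
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    treatment_shift: float = 0.0
    placebo_drift: float = 0.0
    fu_noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(
                f"marker {self.name!r}: unknown transform {self.transform!r}"
            )
        if not self.baseline_sd > 0:
            raise ConfigurationError(
                f"marker {self.name!r}: baseline_sd must be > 0"
            )
        if self.fu_noise_sd is not None and self.fu_noise_sd < 0:
            raise ConfigurationError(
                f"marker {self.name!r}: fu_noise_sd must be >= 0"
            )

    @property
    def noise_sd(self) -> float:
        return self.fu_noise_sd if self.fu_noise_sd is not None else 0.5 * self.baseline_sd

    def to_model_scale(self, x):
        """Native values -> transform (model) scale."""
        x = np.asarray(x, dtype=float)
        if self.transform == NATURAL_LOG:
            if np.any(x[~np.isnan(x)] <= 0):
                raise InputError(f"marker {self.name!r}: nonpositive values cannot be log-transformed")
            return np.log(x)
        return x

    def to_native_scale(self, z):
        """Transform-scale values -> native scale."""
        z = np.asarray(z, dtype=float)
        return np.exp(z) if self.transform == NATURAL_LOG else z

    def with_shift(self, treatment_shift: float) -> "MarkerSpec":
        return replace(self, treatment_shift=treatment_shift)


def _log_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    # log-normal parameters from a printed median [IQR]
    mu = math.log(median)
    sd = (math.log(q3) - math.log(q1)) / (2 * 0.674489750196082)
    return mu, sd


# -- Default marker panels ---------------------------------------------------
#
# Trial panel: marginals of a liraglutide cardiovascular-outcome trial
# population (HbA1c 8.7 (1.5) %, SBP 135.9 (17.7) mmHg, UACR median 24.8
# [IQR ~7, ~157] mg/g, weight ~91.7 (21) kg, Hb 137.1 (15) g/L, HDL 1.2
# (0.3), LDL 2.3 (0.9) mmol/L, K 4.5 (0.5) mmol/L) with placebo-corrected
# 6-month shifts: HbA1c -1.4 %, SBP -3.0 mmHg, UACR -13.2 %, weight -2.3 kg,
# Hb -2.6 g/L, HDL +0.01 mmol/L; LDL and potassium essentially unchanged.
#
# Follow-up noise SDs are within-person short-term variabilities, not
# fractions of the cross-sectional SD: visit-to-visit SBP ~9 mmHg, HbA1c
# ~0.7 %, 6-month weight ~3 kg, log-UACR ~0.45 (UACR is noisy but not
# 3-fold-swing noisy), Hb ~7 g/L, lipids ~0.1-0.35 mmol/L, K ~0.3 mmol/L.

_UACR_TRIAL_MU, _UACR_TRIAL_SD = _log_params(24.8, 7.1, 145.0)
_UACR_BG_MU, _UACR_BG_SD = _log_params(276.9, 54.5, 1193.9)


def leader_like_markers() -> list[MarkerSpec]:
    """Default trial marker panel (two-arm GLP1-RA trial emulation)."""
    return [
        MarkerSpec("hba1c", "%", IDENTITY, 8.7, 1.55, -1.4, -0.2, 0.7),
        MarkerSpec("sbp", "mmHg", IDENTITY, 135.9, 17.75, -3.0, -0.5, 9.0),
        MarkerSpec("uacr", "mg/g", NATURAL_LOG, _UACR_TRIAL_MU, _UACR_TRIAL_SD,
                   math.log(1.0 - 0.132), 0.01, 0.45),
        MarkerSpec("weight", "kg", IDENTITY, 91.75, 21.0, -2.3, -0.5, 3.0),
        MarkerSpec("hb", "g/L", IDENTITY, 137.1, 15.0, -2.6, 0.0, 7.0),
        MarkerSpec("hdl", "mmol/L", IDENTITY, 1.2, 0.3, 0.01, 0.0, 0.12),
        MarkerSpec("ldl", "mmol/L", IDENTITY, 2.3, 0.9, 0.0, -0.05, 0.35),
        MarkerSpec("potassium", "mmol/L", IDENTITY, 4.5, 0.5, 0.0, 0.0, 0.3),
    ]


def background_markers() -> list[MarkerSpec]:
    """Default background-cohort panel: a pooled type-2-diabetes population at
    high kidney risk (much higher albuminuria, lower eGFR than the trial)."""
    return [
        MarkerSpec("hba1c", "%", IDENTITY, 8.1, 1.7),
        MarkerSpec("sbp", "mmHg", IDENTITY, 144.8, 20.0),
        MarkerSpec("uacr", "mg/g", NATURAL_LOG, _UACR_BG_MU, _UACR_BG_SD),
        MarkerSpec("weight", "kg", IDENTITY, 83.4, 19.8),
        MarkerSpec("hb", "g/L", IDENTITY, 128.0, 18.7),
        MarkerSpec("hdl", "mmol/L", IDENTITY, 1.2, 0.4),
        MarkerSpec("ldl", "mmol/L", IDENTITY, 3.1, 1.3),
        MarkerSpec("potassium", "mmol/L", IDENTITY, 4.6, 0.5),
    ]


def marker_names(markers: list[MarkerSpec]) -> list[str]:
    return [m.name for m in markers]


def transformed_matrix(df, markers: list[MarkerSpec], suffix: str) -> np.ndarray:
    """Stack ``<name>_<suffix>`` columns into an (n, p) transform-scale matrix."""
    cols = []
    for m in markers:
        col = f"{m.name}_{suffix}"
        if col not in df.columns:
            raise InputError(f"column {col!r} not present in patient table")
        cols.append(m.to_model_scale(df[col].to_numpy(dtype=float)))
    return np.column_stack(cols)
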