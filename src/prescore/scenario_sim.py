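"""Responder enrichment and trial extrapolation.

To extrapolate a trial's predicted effect to a population with a different
response distribution (e.g. a dedicated kidney-outcome trial of a related
drug), the treatment arm is re-weighted by *responder* status: a responder
is a treated patient whose marker reduction from baseline is greater than
or equal to the treatment-arm median reduction (ties count as responders).
Resampling the treatment arm with replacement to a chosen responder
proportion p — placebo arm untouched, arm size preserved — shifts the
realized mean marker change; rescoring the resampled trial traces the
predicted RRR as a function of the response magnitude, and inverting that
curve answers "how large a marker change is needed for a target RRR?".

Changes are computed on the transform scale, so for log-scale markers a
mean change Δ (log units) is reported as a percent reduction
100·(1 − e^Δ).  Inclusion-criteria filtering (conjunction of
disjunction-groups over baseline columns) supports subsetting a trial to a
narrower target population before any of this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background_model import CoxFit
from .errors import InputError, SimulationError
from .markers import NATURAL_LOG
from .pre_score import DEFAULT_HORIZON_YEARS, PREResult, bootstrap_ci, pre_rrr
from .synthetic_data import PLACEBO, TREATMENT, TrialDataset


# ---------------------------------------------------------------------------
# Inclusion criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Predicate:
    """column value in [lower, upper] (bounds optional, inclusivity per flag)."""

    column: str
    lower: float | None = None
    upper: float | None = None
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise InputError(f"predicate on {self.column!r} has no bounds")
        if (self.lower is not None and self.upper is not None
                and self.lower > self.upper):
            raise InputError(f"predicate on {self.column!r}: bounds out of order")

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        if self.column not in df.columns:
            raise InputError(f"criteria reference unknown column {self.column!r}")
        x = df[self.column].to_numpy(dtype=float)
        ok = np.ones(len(df), dtype=bool)
        if self.lower is not None:
            ok &= (x >= self.lower) if self.lower_inclusive else (x > self.lower)
        if self.upper is not None:
            ok &= (x <= self.upper) if self.upper_inclusive else (x < self.upper)
        return ok


@dataclass(frozen=True)
class InclusionCriteria:
    """Conjunction of disjunction-groups: a patient qualifies when, in every
    group, at least one predicate holds."""

    groups: tuple[tuple[Predicate, ...], ...]

    def __post_init__(self) -> None:
        if not self.groups or any(len(g) == 0 for g in self.groups):
            raise InputError("criteria need at least one predicate per group")

    @classmethod
    def all_of(cls, *predicates: Predicate) -> "InclusionCriteria":
        return cls(tuple((p,) for p in predicates))

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        keep = np.ones(len(df), dtype=bool)
        for group in self.groups:
            keep &= np.logical_or.reduce([p.evaluate(df) for p in group])
        return keep


def flow_like_criteria() -> InclusionCriteria:
    """Default chronic-kidney-disease enrichment band: reduced eGFR together
    with overt albuminuria.  The real dedicated-kidney-trial criteria are
    eGFR/UACR band combinations published only in trial registries; this
    single band (eGFR 25–60 ml/min/1.73 m², UACR 200–5000 mg/g) is a
    documented stand-in assumption, and criteria are configuration data."""
    return InclusionCriteria.all_of(
        Predicate("egfr_bl", 25.0, 60.0),
        Predicate("uacr_bl", 200.0, 5000.0),
    )


def apply_inclusion_criteria(trial: TrialDataset,
                             criteria: InclusionCriteria) -> TrialDataset:
    """Subset the trial to patients satisfying the criteria (arms may end up
    unbalanced; an empty subset is returned with a warning, and downstream
    scoring will reject it)."""
    keep = criteria.evaluate(trial.df)
    if not keep.any():
        import warnings

        warnings.warn("inclusion criteria select no patients", stacklevel=2)
    return TrialDataset(trial.df.loc[keep].reset_index(drop=True),
                        list(trial.markers))


# ---------------------------------------------------------------------------
# Responder machinery
# ---------------------------------------------------------------------------

def _marker_spec(trial: TrialDataset, marker: str):
    for m in trial.markers:
        if m.name == marker:
            return m
    raise InputError(f"unknown marker {marker!r}")


def _changes(trial: TrialDataset, marker: str, mask: np.ndarray) -> np.ndarray:
    spec = _marker_spec(trial, marker)
    bl = spec.to_model_scale(trial.df.loc[mask, f"{marker}_bl"].to_numpy(dtype=float))
    fu = spec.to_model_scale(trial.df.loc[mask, f"{marker}_fu"].to_numpy(dtype=float))
    if np.isnan(bl).any() or np.isnan(fu).any():
        raise InputError(f"marker {marker!r} has missing values; impute first")
    return fu - bl


def classify_responders(trial: TrialDataset, marker: str) -> pd.Series:
    """Responder labels for the treatment arm.

    The reduction (−change on the transform scale) is compared with the
    treatment-arm median reduction; ``reduction >= median`` defines a
    responder, so identical changes make everyone a responder.
    """
    trial.validate()
    treat = trial.arm_index(TREATMENT)
    reduction = -_changes(trial, marker, treat)
    threshold = np.median(reduction)
    labels = reduction >= threshold
    return pd.Series(labels, index=trial.df.index[treat], name="responder")


def shift_response_distribution(trial: TrialDataset, marker: str,
                                proportion: float, seed: int = 0) -> TrialDataset:
    """Resample the treatment arm (with replacement, within responder strata)
    so a fraction ``proportion`` are responders; placebo arm untouched, arm
    size preserved exactly."""
    if not 0.0 <= proportion <= 1.0:
        raise InputError("proportion must lie in [0, 1]")
    labels = classify_responders(trial, marker)
    responders = labels.index[labels].to_numpy()
    non_responders = labels.index[~labels].to_numpy()
    n_arm = len(labels)
    n_resp = int(round(proportion * n_arm))
    if n_resp > 0 and len(responders) == 0:
        raise SimulationError("no responders exist to enrich toward")
    if n_arm - n_resp > 0 and len(non_responders) == 0:
        # degenerate tie case: everyone is a responder; draw from the full arm
        non_responders = responders
    rng = np.random.default_rng(seed)
    picked = np.concatenate([
        rng.choice(responders, size=n_resp, replace=True) if n_resp else [],
        rng.choice(non_responders, size=n_arm - n_resp, replace=True)
        if n_arm - n_resp else [],
    ]).astype(int)
    placebo_df = trial.df.loc[trial.arm_index(PLACEBO)]
    treat_df = trial.df.loc[picked]
    out = pd.concat([placebo_df, treat_df], ignore_index=True)
    return TrialDataset(out, list(trial.markers))


# ---------------------------------------------------------------------------
# RRR-vs-response curve
# ---------------------------------------------------------------------------

@dataclass
class ScenarioCurve:
    """Predicted RRR against realized placebo-corrected marker change over a
    grid of responder proportions.  ``mean_change_per_point`` is on the
    reporting scale: percent reduction ``100·(1−e^Δ)`` for log markers,
    native difference otherwise."""

    marker: str
    outcome: str
    proportions: np.ndarray
    mean_change_per_point: np.ndarray
    rrr_per_point: np.ndarray
    ci_low_per_point: np.ndarray
    ci_high_per_point: np.ndarray
    results: list[PREResult] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(np.diff(self.proportions) <= 0):
            raise InputError("proportions must be strictly increasing")
        lengths = {len(self.proportions), len(self.mean_change_per_point),
                   len(self.rrr_per_point), len(self.ci_low_per_point),
                   len(self.ci_high_per_point)}
        if len(lengths) != 1:
            raise InputError("curve fields must have equal length")


def placebo_corrected_change(trial: TrialDataset, marker: str,
                             reporting_scale: bool = True) -> float:
    """Mean treatment-arm change minus mean placebo-arm change, transform
    scale; optionally converted to the reporting scale (percent reduction
    for log markers)."""
    spec = _marker_spec(trial, marker)
    delta = (_changes(trial, marker, trial.arm_index(TREATMENT)).mean()
             - _changes(trial, marker, trial.arm_index(PLACEBO)).mean())
    if reporting_scale and spec.transform == NATURAL_LOG:
        return float(100.0 * (1.0 - np.exp(delta)))
    return float(delta)


def simulate_rrr_curve(fit: CoxFit, trial: TrialDataset, marker: str,
                       proportions, horizon: float = DEFAULT_HORIZON_YEARS,
                       n_draws: int = 100, seed: int = 0,
                       marker_subset: list[str] | None = None) -> ScenarioCurve:
    """Trace the PRE-score RRR as the responder proportion for ``marker``
    varies, rescoring (with bootstrap CI) at each grid point."""
    proportions = np.asarray(list(proportions), dtype=float)
    if proportions.size == 0:
        raise InputError("the proportion grid must be nonempty")
    streams = np.random.SeedSequence(seed).spawn(len(proportions) + 1)
    changes, rrrs, los, his, results = [], [], [], [], []
    for i, p in enumerate(proportions):
        child = np.random.default_rng(streams[i])
        shifted = shift_response_distribution(
            trial, marker, float(p), seed=int(child.integers(2**31)))
        res = bootstrap_ci(fit, shifted, marker_subset, horizon=horizon,
                           n_draws=n_draws,
                           seed=int(child.integers(2**31)))
        changes.append(placebo_corrected_change(shifted, marker))
        rrrs.append(res.rrr_percent)
        los.append(res.ci_low_percent)
        his.append(res.ci_high_percent)
        results.append(res)
    return ScenarioCurve(marker=marker, outcome=fit.outcome,
                         proportions=proportions,
                         mean_change_per_point=np.asarray(changes),
                         rrr_per_point=np.asarray(rrrs),
                         ci_low_per_point=np.asarray(los),
                         ci_high_per_point=np.asarray(his),
                         results=results)


def required_change_for_target(curve: ScenarioCurve,
                               target_rrr_percent: float) -> float:
    """Smallest placebo-corrected mean change achieving the target RRR,
    by linear interpolation of change against RRR along the curve.

    Raises when the target lies outside the RRR range the curve spans,
    reporting the achievable range.
    """
    rrr = curve.rrr_per_point
    change = curve.mean_change_per_point
    candidates = [change[i] for i in np.flatnonzero(np.isclose(rrr, target_rrr_percent))]
    for i in range(len(rrr) - 1):
        lo, hi = sorted((rrr[i], rrr[i + 1]))
        if lo < target_rrr_percent < hi and rrr[i + 1] != rrr[i]:
            frac = (target_rrr_percent - rrr[i]) / (rrr[i + 1] - rrr[i])
            candidates.append(change[i] + frac * (change[i + 1] - change[i]))
    if not candidates:
        raise InputError(
            f"target RRR {target_rrr_percent:.3g}% outside the achievable "
            f"range [{rrr.min():.3g}%, {rrr.max():.3g}%]"
        )
    return float(min(candidates))
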