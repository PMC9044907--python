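"""The PRE score: coefficient-transfer prediction of relative risk reduction.

Background-cohort Cox coefficients are applied to each trial patient's
markers twice — at baseline and at the first follow-up — giving predicted
absolute risks at a fixed horizon.  Averaging within arm and forming each
arm's relative risk change

    Delta_arm = (mean risk at follow-up - mean risk at baseline)
                / mean risk at baseline,

the placebo-adjusted predicted relative risk reduction is

    RRR% = -100 * (Delta_treatment - Delta_placebo),

positive when treatment lowers predicted risk, and exactly zero when
follow-up equals baseline in both arms.  Only the markers in the chosen
subset are updated to their follow-up values; all other markers contribute
through their baseline values at both time points, which is how
single-marker scores are obtained.

A ratio form, RRR% = 100 * (1 - (1+Delta_T)/(1+Delta_P)), is available via
``method="ratio"`` for sensitivity analysis.

Confidence intervals are parametric-bootstrap percentiles: coefficient
vectors are drawn componentwise from independent Normal(beta_i, se_i)
(optionally from the full multivariate normal), the RRR is recomputed per
draw with the baseline hazard and covariate center held fixed, and the
2.5th/97.5th percentiles are reported.  The interval therefore quantifies
coefficient uncertainty only, not trial sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background_model import CoxFit
from .errors import InputError
from .markers import NATURAL_LOG
from .synthetic_data import PLACEBO, TREATMENT, TrialDataset

DEFAULT_HORIZON_YEARS = 3.5


@dataclass
class PREResult:
    """Predicted relative risk reduction for one outcome and marker subset."""

    outcome: str
    marker_subset: list[str]
    horizon: float
    mean_risk_placebo_bl: float
    mean_risk_placebo_fu: float
    mean_risk_treat_bl: float
    mean_risk_treat_fu: float
    rrr_percent: float
    ci_low_percent: float | None = None
    ci_high_percent: float | None = None
    n_bootstrap: int = 0
    method: str = "difference"
    m_imputations: int = 1
    bootstrap_draws: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("mean_risk_placebo_bl", "mean_risk_placebo_fu",
                     "mean_risk_treat_bl", "mean_risk_treat_fu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} = {v} is not a probability")
        if (self.ci_low_percent is not None and self.ci_high_percent is not None
                and self.ci_low_percent > self.ci_high_percent + 1e-12):
            raise InputError("ci_low must not exceed ci_high")


# ---------------------------------------------------------------------------
# Risk matrices
# ---------------------------------------------------------------------------

def _transform_column(fit: CoxFit, trial: TrialDataset, name: str,
                      suffix: str) -> np.ndarray:
    col = f"{name}_{suffix}"
    if col not in trial.df.columns:
        raise InputError(f"trial table lacks column {col!r}")
    x = trial.df[col].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise InputError(
            f"column {col!r} contains missing values; run imputation first")
    tr = fit.transforms[fit.markers.index(name)]
    if tr == NATURAL_LOG:
        if np.any(x <= 0):
            raise InputError(f"nonpositive values in log-scale column {col!r}")
        return np.log(x)
    return x


def _design_matrices(fit: CoxFit, trial: TrialDataset,
                     subset: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Transform-scale (n, p) matrices at baseline and at follow-up, with
    only ``subset`` markers updated to follow-up values."""
    unknown = [m for m in subset if m not in fit.markers]
    if unknown:
        raise InputError(f"unknown marker name(s): {unknown}")
    z_bl = np.column_stack(
        [_transform_column(fit, trial, m, "bl") for m in fit.markers])
    z_fu = z_bl.copy()
    for m in subset:
        z_fu[:, fit.markers.index(m)] = _transform_column(fit, trial, m, "fu")
    return z_bl, z_fu


def _arm_masks(trial: TrialDataset) -> tuple[np.ndarray, np.ndarray]:
    placebo = trial.arm_index(PLACEBO)
    treat = trial.arm_index(TREATMENT)
    if not placebo.any() or not treat.any():
        raise InputError("both trial arms must be non-empty")
    return placebo, treat


def _rrr_from_mean_risks(rp_bl, rp_fu, rt_bl, rt_fu, method: str):
    """RRR (percent) from the four arm-level mean risks; vectorized."""
    d_p = (rp_fu - rp_bl) / rp_bl
    d_t = (rt_fu - rt_bl) / rt_bl
    if method == "difference":
        return -100.0 * (d_t - d_p)
    if method == "ratio":
        return 100.0 * (1.0 - (1.0 + d_t) / (1.0 + d_p))
    raise InputError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Point estimate
# ---------------------------------------------------------------------------

def pre_rrr(fit: CoxFit, trial: TrialDataset, marker_subset: list[str] | None = None,
            horizon: float = DEFAULT_HORIZON_YEARS,
            method: str = "difference") -> PREResult:
    """Point estimate of the PRE-score RRR (no confidence interval)."""
    subset = list(marker_subset) if marker_subset is not None else list(fit.markers)
    z_bl, z_fu = _design_matrices(fit, trial, subset)
    placebo, treat = _arm_masks(trial)
    risk_bl = fit.risk_from_lp(fit.linear_predictor(z_bl), horizon)
    risk_fu = fit.risk_from_lp(fit.linear_predictor(z_fu), horizon)
    rp_bl, rp_fu = risk_bl[placebo].mean(), risk_fu[placebo].mean()
    rt_bl, rt_fu = risk_bl[treat].mean(), risk_fu[treat].mean()
    return PREResult(
        outcome=fit.outcome, marker_subset=subset, horizon=horizon,
        mean_risk_placebo_bl=rp_bl, mean_risk_placebo_fu=rp_fu,
        mean_risk_treat_bl=rt_bl, mean_risk_treat_fu=rt_fu,
        rrr_percent=float(_rrr_from_mean_risks(rp_bl, rp_fu, rt_bl, rt_fu, method)),
        method=method,
    )


def single_marker_rrr(fit: CoxFit, trial: TrialDataset, marker: str,
                      horizon: float = DEFAULT_HORIZON_YEARS,
                      method: str = "difference") -> PREResult:
    """PRE score updating a single marker to follow-up (all others at baseline)."""
    return pre_rrr(fit, trial, [marker], horizon=horizon, method=method)


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(fit: CoxFit, trial: TrialDataset,
                 marker_subset: list[str] | None = None,
                 horizon: float = DEFAULT_HORIZON_YEARS,
                 n_draws: int = 100, seed: int = 0,
                 method: str = "difference",
                 multivariate: bool = False) -> PREResult:
    """PRE-score RRR with a percentile confidence interval.

    ``n_draws`` coefficient vectors are sampled — componentwise independent
    normals around the fitted coefficients by default, or from the full
    estimated covariance with ``multivariate=True`` — and the RRR is
    recomputed for each with H0 and the covariate center fixed.  A zero
    standard error yields a point mass at the fitted coefficient.
    """
    if n_draws < 2:
        raise InputError("n_draws must be at least 2")
    point = pre_rrr(fit, trial, marker_subset, horizon=horizon, method=method)
    subset = point.marker_subset
    z_bl, z_fu = _design_matrices(fit, trial, subset)
    placebo, treat = _arm_masks(trial)

    rng = np.random.default_rng(seed)
    if multivariate:
        if fit.beta_covariance is None:
            raise InputError("fit carries no coefficient covariance matrix")
        betas = rng.multivariate_normal(fit.beta, fit.beta_covariance,
                                        size=n_draws)
    else:
        betas = fit.beta + rng.standard_normal((n_draws, len(fit.beta))) * fit.se

    h0 = fit.cumulative_hazard(horizon)
    centered_bl = z_bl - fit.covariate_center
    centered_fu = z_fu - fit.covariate_center
    risk_bl = -np.expm1(-h0 * np.exp(centered_bl @ betas.T))   # (n, n_draws)
    risk_fu = -np.expm1(-h0 * np.exp(centered_fu @ betas.T))
    draws = _rrr_from_mean_risks(
        risk_bl[placebo].mean(axis=0), risk_fu[placebo].mean(axis=0),
        risk_bl[treat].mean(axis=0), risk_fu[treat].mean(axis=0), method)

    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PREResult(
        outcome=point.outcome, marker_subset=subset, horizon=horizon,
        mean_risk_placebo_bl=point.mean_risk_placebo_bl,
        mean_risk_placebo_fu=point.mean_risk_placebo_fu,
        mean_risk_treat_bl=point.mean_risk_treat_bl,
        mean_risk_treat_fu=point.mean_risk_treat_fu,
        rrr_percent=point.rrr_percent,
        ci_low_percent=float(lo), ci_high_percent=float(hi),
        n_bootstrap=n_draws, method=method, bootstrap_draws=draws,
    )


# ---------------------------------------------------------------------------
# Pooling across imputations
# ---------------------------------------------------------------------------

def pool_over_imputations(results: list[PREResult]) -> PREResult:
    """Combine PRE results computed on m completed datasets.

    The point estimate (and each mean risk) is the average over imputations;
    the interval is the percentile CI of the *pooled* bootstrap draws, so
    between-imputation spread widens it naturally.
    """
    if not results:
        raise InputError("no results to pool")
    first = results[0]
    for r in results[1:]:
        if (r.outcome != first.outcome or sorted(r.marker_subset) !=
                sorted(first.marker_subset) or r.horizon != first.horizon
                or r.method != first.method):
            raise InputError("results to pool differ in outcome/subset/horizon")
    if len(results) == 1:
        return first

    def avg(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in results]))

    draws_list = [r.bootstrap_draws for r in results if r.bootstrap_draws is not None]
    pooled = np.concatenate(draws_list) if draws_list else None
    lo, hi = (np.percentile(pooled, [2.5, 97.5]) if pooled is not None
              else (first.ci_low_percent, first.ci_high_percent))
    return PREResult(
        outcome=first.outcome, marker_subset=list(first.marker_subset),
        horizon=first.horizon,
        mean_risk_placebo_bl=avg("mean_risk_placebo_bl"),
        mean_risk_placebo_fu=avg("mean_risk_placebo_fu"),
        mean_risk_treat_bl=avg("mean_risk_treat_bl"),
        mean_risk_treat_fu=avg("mean_risk_treat_fu"),
        rrr_percent=avg("rrr_percent"),
        ci_low_percent=None if lo is None else float(lo),
        ci_high_percent=None if hi is None else float(hi),
        n_bootstrap=sum(r.n_bootstrap for r in results),
        method=first.method, m_imputations=len(results),
        bootstrap_draws=pooled,
    )
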