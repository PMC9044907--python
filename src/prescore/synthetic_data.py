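"""Synthetic cohorts and two-arm trials with known ground truth.

The real patient-level data behind a coefficient-transfer risk score (a
pooled high-risk background cohort and a large cardiovascular-outcome trial)
are never public, so every stage of this package is exercised on synthetic
data whose generating mechanism is fully known:

* baseline markers follow a Gaussian copula — multivariate normal on the
  transform scale (log scale for UACR), exponentiated back to the native
  scale for log markers;
* event times follow a proportional-hazards model with Weibull (default
  exponential) baseline hazard and linear predictor ``β_true · (z − μ)``,
  covariates centred at their configured means;
* the trial's follow-up markers are ``baseline + placebo_drift +
  treatment_shift·1[treated] + noise`` on the transform scale, and the
  trial's outcomes are generated from the *follow-up* linear predictor, so
  by default the treatment effect on outcomes is purely marker-mediated —
  this is the ground truth a coefficient-transfer score should recover.
  An optional per-outcome ``direct_effect`` hazard multiplier adds a
  non-marker-mediated component (off by default) so the score's known
  blind spot can be reproduced deliberately.

Baseline hazards are calibrated numerically (:func:`calibrate_baseline_hazard`)
so the default background cohort reproduces realistic composite event
fractions (≈17.8 % kidney, ≈12.5 % cardiovascular over 4 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermitenorm

from .errors import ConfigurationError, SimulationError
from .markers import (
    OUTCOMES,
    MarkerSpec,
    background_markers,
    leader_like_markers,
    marker_names,
    transformed_matrix,
)

PLACEBO = "placebo"
TREATMENT = "treatment"

#: default ground-truth log-hazard-ratios per transformed marker unit,
#: aligned to (hba1c, sbp, uacr[log], weight, hb, hdl, ldl, potassium).
#: Log-UACR dominates the kidney outcome; HbA1c/lipids matter more for CV.
TRUE_BETA_KIDNEY = (0.03, 0.008, 0.90, 0.003, -0.010, -0.20, 0.04, 0.15)
TRUE_BETA_CV = (0.027, 0.006, 0.20, 0.004, -0.006, -0.30, 0.10, 0.10)


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------

@dataclass
class BackgroundDataset:
    """Single-cohort patient table used to estimate marker-outcome coefficients.

    ``df`` columns: ``id``, ``<marker>_bl`` (native scale), and per outcome
    ``time_<outcome>`` (years) and ``event_<outcome>`` (0/1).
    """

    df: pd.DataFrame
    markers: list[MarkerSpec]

    def validate(self) -> "BackgroundDataset":
        for m in self.markers:
            col = f"{m.name}_bl"
            if col not in self.df.columns:
                raise ConfigurationError(f"background table missing column {col!r}")
            if m.transform == "natural_log" and (self.df[col] <= 0).any():
                raise ConfigurationError(f"nonpositive values in log marker column {col!r}")
        for o in OUTCOMES:
            t, e = self.df[f"time_{o}"], self.df[f"event_{o}"]
            if (t <= 0).any():
                raise ConfigurationError(f"nonpositive times in time_{o}")
            if not e.isin((0, 1)).all():
                raise ConfigurationError(f"non-binary event indicator in event_{o}")
        return self

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class TrialDataset:
    """Two-arm patient table with baseline and follow-up marker values.

    ``df`` columns: ``id``, ``arm`` (``placebo``/``treatment``),
    ``<marker>_bl``, ``<marker>_fu`` (native scale; follow-up may be
    missing), ``egfr_bl`` (auxiliary covariate for inclusion filters), and
    ``time_<outcome>`` / ``event_<outcome>`` per outcome.
    """

    df: pd.DataFrame
    markers: list[MarkerSpec]

    def validate(self) -> "TrialDataset":
        if "arm" not in self.df.columns:
            raise ConfigurationError("trial table missing 'arm' column")
        for arm in (PLACEBO, TREATMENT):
            if not (self.df["arm"] == arm).any():
                raise ConfigurationError(f"trial has no patients in the {arm!r} arm")
        for m in self.markers:
            for suffix in ("bl", "fu"):
                if f"{m.name}_{suffix}" not in self.df.columns:
                    raise ConfigurationError(
                        f"trial table missing column {m.name}_{suffix}"
                    )
        return self

    def arm_index(self, arm: str) -> np.ndarray:
        return (self.df["arm"] == arm).to_numpy()

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), list(self.markers))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

def default_correlation(p: int, off_diagonal: float = 0.1) -> np.ndarray:
    """Weak exchangeable correlation across markers (configurable)."""
    c = np.full((p, p), off_diagonal)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a background cohort and a trial.

    Rates are events per person-year; ``true_beta_*`` are log hazard ratios
    per transformed marker unit aligned to ``markers``.  ``missingness`` maps
    marker name -> follow-up missing fraction, applied by
    :func:`inject_missingness` under ``missing_mechanism`` ("MCAR" or "MAR").
    """

    markers: list[MarkerSpec] = field(default_factory=leader_like_markers)
    marker_correlation: np.ndarray | None = None
    n_background: int = 6355
    n_per_arm: int = 4670
    true_beta_kidney: tuple[float, ...] = TRUE_BETA_KIDNEY
    true_beta_cv: tuple[float, ...] = TRUE_BETA_CV
    baseline_hazard_rate: dict[str, float] = field(
        default_factory=lambda: {"kidney": 0.01, "cv": 0.01}
    )
    follow_up_years: float = 4.0
    censoring_rate: float = 0.02
    weibull_shape: float = 1.0
    direct_effect: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    missing_mechanism: str = "MAR"
    egfr_mean: float = 79.1
    egfr_sd: float = 21.8
    egfr_uacr_corr: float = -0.35
    seed: int = 0

    # -- derived helpers ---------------------------------------------------

    def true_beta(self, outcome: str) -> np.ndarray:
        if outcome == "kidney":
            return np.asarray(self.true_beta_kidney, dtype=float)
        if outcome == "cv":
            return np.asarray(self.true_beta_cv, dtype=float)
        raise ConfigurationError(f"unknown outcome {outcome!r}")

    @property
    def correlation(self) -> np.ndarray:
        if self.marker_correlation is None:
            return default_correlation(len(self.markers))
        return np.asarray(self.marker_correlation, dtype=float)

    @property
    def means(self) -> np.ndarray:
        return np.array([m.baseline_mean for m in self.markers])

    @property
    def sds(self) -> np.ndarray:
        return np.array([m.baseline_sd for m in self.markers])

    def covariance(self) -> np.ndarray:
        d = np.diag(self.sds)
        return d @ self.correlation @ d

    def validate(self) -> "GeneratorConfig":
        p = len(self.markers)
        if p == 0:
            raise ConfigurationError("at least one marker is required")
        c = self.correlation
        if c.shape != (p, p):
            raise ConfigurationError("marker_correlation has the wrong shape")
        if not np.allclose(c, c.T):
            raise ConfigurationError("marker_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ConfigurationError("marker_correlation must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ConfigurationError("marker_correlation is not positive semi-definite")
        if self.n_background <= 0 or self.n_per_arm <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        for o in OUTCOMES:
            if self.baseline_hazard_rate.get(o, -1.0) < 0:
                raise ConfigurationError(f"baseline_hazard_rate[{o!r}] must be >= 0")
        if len(self.true_beta_kidney) != p or len(self.true_beta_cv) != p:
            raise ConfigurationError("true_beta vectors must align with markers")
        if self.follow_up_years <= 0 or self.censoring_rate < 0:
            raise ConfigurationError("follow_up_years must be > 0, censoring_rate >= 0")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be > 0")
        names = set(marker_names(self.markers))
        for name, rate in self.missingness.items():
            if name not in names:
                raise ConfigurationError(f"missingness refers to unknown marker {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missing rate for {name!r} outside [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ConfigurationError("missing_mechanism must be 'MCAR' or 'MAR'")
        return self


# ---------------------------------------------------------------------------
# Baseline-hazard calibration
# ---------------------------------------------------------------------------

def _event_probability(lam: float, lp: np.ndarray, weights: np.ndarray,
                       follow_up: float, censor_rate: float, shape: float) -> float:
    """Marginal event fraction under admin censoring at ``follow_up`` and
    exponential random censoring, averaged over the linear predictor."""
    rate = lam * np.exp(lp)
    if shape == 1.0:
        total = rate + censor_rate
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, rate / np.maximum(total, 1e-300)
                         * -np.expm1(-total * follow_up), 0.0)
    else:
        t = np.linspace(1e-9, follow_up, 513)
        # density of the Weibull-PH event time times censoring survival
        dens = (rate[:, None] * shape * t**(shape - 1)
                * np.exp(-rate[:, None] * t**shape - censor_rate * t))
        p = np.trapezoid(dens, t, axis=1)
    return float(np.sum(weights * p))


def calibrate_baseline_hazard(config: GeneratorConfig, target_event_fraction: float,
                              outcome: str) -> float:
    """Solve for the baseline hazard rate giving the target marginal event
    fraction under the configured covariate distribution (Gauss–Hermite
    quadrature over the Gaussian linear predictor)."""
    if not 0.0 < target_event_fraction < 1.0:
        raise ConfigurationError("target event fraction must be in (0, 1)")
    beta = config.true_beta(outcome)
    var = float(beta @ config.covariance() @ beta)
    nodes, w = roots_hermitenorm(101)
    w = w / w.sum()
    lp = np.sqrt(var) * nodes

    def gap(log_lam: float) -> float:
        return _event_probability(np.exp(log_lam), lp, w, config.follow_up_years,
                                  config.censoring_rate, config.weibull_shape) \
            - target_event_fraction

    return float(np.exp(brentq(gap, -25.0, 5.0, xtol=1e-12)))


def default_background_config(seed: int = 0, n_background: int = 6355,
                              **overrides) -> GeneratorConfig:
    """Background-pool emulation: high-albuminuria diabetic cohort with
    ≈17.8 % kidney and ≈12.5 % CV composite events over 4 years."""
    cfg = GeneratorConfig(markers=background_markers(), n_background=n_background,
                          seed=seed, **overrides).validate()
    cfg.baseline_hazard_rate = {
        "kidney": calibrate_baseline_hazard(cfg, 0.178, "kidney"),
        "cv": calibrate_baseline_hazard(cfg, 0.125, "cv"),
    }
    return cfg


def default_trial_config(seed: int = 0, n_per_arm: int = 4670,
                         **overrides) -> GeneratorConfig:
    """Trial emulation: lower-risk population, staggered follow-up visit
    availability expressed as per-marker follow-up missingness."""
    overrides.setdefault("missingness", {
        "uacr": 0.08, "hdl": 0.08, "ldl": 0.08, "hb": 0.12, "potassium": 0.12,
    })
    cfg = GeneratorConfig(markers=leader_like_markers(), n_per_arm=n_per_arm,
                          seed=seed, **overrides).validate()
    cfg.baseline_hazard_rate = {
        "kidney": calibrate_baseline_hazard(cfg, 0.025, "kidney"),
        "cv": calibrate_baseline_hazard(cfg, 0.139, "cv"),
    }
    return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _rng_for(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage from the one config seed
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stream])


def _draw_baseline(rng: np.random.Generator, config: GeneratorConfig,
                   n: int) -> tuple[np.ndarray, np.ndarray]:
    """Transform-scale baseline marker matrix (n, p) and eGFR vector."""
    chol = np.linalg.cholesky(config.correlation + 1e-12 * np.eye(len(config.markers)))
    eps = rng.standard_normal((n, len(config.markers)))
    z = config.means + (eps @ chol.T) * config.sds
    i_uacr = next((i for i, m in enumerate(config.markers) if m.name == "uacr"), None)
    rho = config.egfr_uacr_corr if i_uacr is not None else 0.0
    z_std = ((z[:, i_uacr] - config.means[i_uacr]) / config.sds[i_uacr]
             if i_uacr is not None else np.zeros(n))
    egfr = config.egfr_mean + config.egfr_sd * (
        rho * z_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(n))
    return z, np.clip(egfr, 5.0, None)


def _draw_outcome(rng: np.random.Generator, config: GeneratorConfig,
                  lp: np.ndarray, outcome: str,
                  treated: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Event time and indicator under PH with admin + random censoring."""
    n = lp.shape[0]
    log_rate = np.log(max(config.baseline_hazard_rate[outcome], 1e-300)) + lp
    if treated is not None and config.direct_effect.get(outcome, 0.0) != 0.0:
        log_rate = log_rate + config.direct_effect[outcome] * treated
    rate = np.exp(log_rate)
    t_event = (rng.exponential(1.0, n) / rate) ** (1.0 / config.weibull_shape)
    t_cens = (rng.exponential(1.0 / config.censoring_rate, n)
              if config.censoring_rate > 0 else np.full(n, np.inf))
    horizon = np.minimum(t_cens, config.follow_up_years)
    event = (t_event <= horizon).astype(int)
    time = np.maximum(np.minimum(t_event, horizon), 1e-9)
    return time, event


def _native_columns(z: np.ndarray, markers: list[MarkerSpec], suffix: str) -> dict:
    return {f"{m.name}_{suffix}": m.to_native_scale(z[:, j])
            for j, m in enumerate(markers)}


def generate_background_cohort(config: GeneratorConfig) -> BackgroundDataset:
    """Simulate the coefficient-estimation cohort (complete data)."""
    config.validate()
    rng = _rng_for(config, 0)
    n = config.n_background
    z, _ = _draw_baseline(rng, config, n)
    cols: dict = {"id": np.arange(n)}
    cols.update(_native_columns(z, config.markers, "bl"))
    for outcome in OUTCOMES:
        lp = (z - config.means) @ config.true_beta(outcome)
        t, e = _draw_outcome(rng, config, lp, outcome)
        cols[f"time_{outcome}"], cols[f"event_{outcome}"] = t, e
    return BackgroundDataset(pd.DataFrame(cols), list(config.markers)).validate()


def generate_trial(config: GeneratorConfig) -> TrialDataset:
    """Simulate a two-arm trial whose outcome effect is marker-mediated.

    Follow-up markers: ``z_fu = z_bl + placebo_drift + treatment_shift·1[T]
    + noise`` on the transform scale.  Outcomes are generated from the
    follow-up linear predictor (plus any configured direct effect), so the
    between-arm hazard ratio is exactly what the marker shifts imply.
    """
    config.validate()
    rng = _rng_for(config, 1)
    n = 2 * config.n_per_arm
    treated = np.zeros(n)
    treated[config.n_per_arm:] = 1.0
    z_bl, egfr = _draw_baseline(rng, config, n)
    drift = np.array([m.placebo_drift for m in config.markers])
    shift = np.array([m.treatment_shift for m in config.markers])
    noise_sd = np.array([m.noise_sd for m in config.markers])
    noise = rng.standard_normal((n, len(config.markers))) * noise_sd
    z_fu = z_bl + drift + np.outer(treated, shift) + noise

    cols: dict = {
        "id": np.arange(n),
        "arm": np.where(treated == 1.0, TREATMENT, PLACEBO),
    }
    cols.update(_native_columns(z_bl, config.markers, "bl"))
    cols.update(_native_columns(z_fu, config.markers, "fu"))
    cols["egfr_bl"] = egfr
    for outcome in OUTCOMES:
        lp = (z_fu - config.means) @ config.true_beta(outcome)
        t, e = _draw_outcome(rng, config, lp, outcome, treated=treated)
        cols[f"time_{outcome}"], cols[f"event_{outcome}"] = t, e
    return TrialDataset(pd.DataFrame(cols), list(config.markers)).validate()


def inject_missingness(trial: TrialDataset, config: GeneratorConfig) -> TrialDataset:
    """Blank follow-up marker values at the configured per-marker rates.

    MCAR deletes uniformly at random; MAR makes the missingness probability
    depend on the patient's *baseline* value of the same marker through a
    logistic link (unit slope on the standardized transformed baseline),
    with the intercept solved so the marginal rate matches the configured
    one.  Baseline and outcome columns are never touched.
    """
    config.validate()
    out = trial.copy()
    rng = _rng_for(config, 2)
    by_name = {m.name: m for m in trial.markers}
    for name, rate in config.missingness.items():
        if rate <= 0.0:
            continue
        spec = by_name[name]
        n = len(out.df)
        if rate >= 1.0:
            mask = np.ones(n, dtype=bool)
        elif config.missing_mechanism == "MCAR":
            mask = rng.random(n) < rate
        else:  # MAR on the observed baseline
            z = spec.to_model_scale(out.df[f"{name}_bl"].to_numpy())
            z_std = (z - z.mean()) / max(z.std(), 1e-12)
            # intercept chosen so mean probability hits the target rate
            alpha = brentq(lambda a: expit(a + z_std).mean() - rate, -30, 30)
            mask = rng.random(n) < expit(alpha + z_std)
        out.df.loc[mask, f"{name}_fu"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Ground-truth oracles
# ---------------------------------------------------------------------------

def true_rrr(config: GeneratorConfig, outcome: str, horizon: float,
             n: int = 400_000, seed: int = 12345,
             include_direct: bool = False,
             markers_shifted: list[str] | None = None) -> float:
    """Ground-truth relative risk reduction by brute-force counterfactual
    simulation: the same patients' events by ``horizon`` are simulated with
    and without the treatment marker shifts (shared exponential draws), and
    the percent reduction in the event fraction is returned.

    ``include_direct`` additionally applies the configured non-marker-mediated
    hazard multiplier in the shifted world, giving the "observed" treatment
    effect rather than the marker-mediated component.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    z_bl, _ = _draw_baseline(rng, config, n)
    drift = np.array([m.placebo_drift for m in config.markers])
    shift = np.array([m.treatment_shift for m in config.markers])
    if markers_shifted is not None:
        keep = np.isin(marker_names(config.markers), list(markers_shifted))
        shift = np.where(keep, shift, 0.0)
    noise = rng.standard_normal(z_bl.shape) * np.array(
        [m.noise_sd for m in config.markers])
    beta = config.true_beta(outcome)
    lam = config.baseline_hazard_rate[outcome]
    h = horizon ** config.weibull_shape
    e = rng.exponential(1.0, n)  # shared across counterfactuals
    lp_ctrl = (z_bl + drift + noise - config.means) @ beta
    lp_trt = lp_ctrl + shift @ beta
    rate_trt = lam * np.exp(lp_trt)
    if include_direct:
        rate_trt = rate_trt * np.exp(config.direct_effect.get(outcome, 0.0))
    ev_ctrl = (e <= lam * np.exp(lp_ctrl) * h).mean()
    ev_trt = (e <= rate_trt * h).mean()
    if ev_ctrl <= 0:
        raise SimulationError("no events in the counterfactual control world")
    return float(100.0 * (1.0 - ev_trt / ev_ctrl))


def true_cox_fit(config: GeneratorConfig, outcome: str,
                 t_max: float | None = None):
    """A :class:`~prescore.background_model.CoxFit` built from the generator's
    true coefficients and true baseline cumulative hazard (λ₀ t^k), centred at
    the configured marker means.  Used as the known-truth scorer in
    validation experiments; standard errors are zero by construction."""
    from .background_model import CoxFit  # local import avoids a cycle

    config.validate()
    t_max = t_max if t_max is not None else config.follow_up_years
    knots = np.linspace(1e-9, t_max, 513)
    lam = config.baseline_hazard_rate[outcome]
    beta = config.true_beta(outcome)
    return CoxFit(
        outcome=outcome,
        markers=marker_names(config.markers),
        transforms=[m.transform for m in config.markers],
        beta=beta,
        se=np.zeros_like(beta),
        covariate_center=config.means.copy(),
        baseline_times=knots,
        baseline_cumhaz=lam * knots ** config.weibull_shape,
        n_events=0,
        n_patients=0,
    )
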