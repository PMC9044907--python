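"""Marker-outcome association model on the background cohort.

The risk equation is a multivariable Cox proportional hazards model,

    h(t | x) = h0(t) * exp( sum_i beta_i * (z_i - c_i) ),

where z_i is the i-th risk marker on its model scale (natural log for
UACR), c_i is the covariate center (the background-cohort mean, so that
exp(lp) is the hazard relative to the average background patient), and
h0(t) is the baseline hazard.  Partial-likelihood estimation (Efron tie
handling) is delegated to lifelines; the centred Breslow baseline
cumulative hazard H0(t) is computed here as an explicit step function so a
fit can be serialized and reused for scoring without refitting.

Absolute risk at a horizon follows from the survival function:

    risk(x, t) = 1 - exp( -H0(t) * exp(lp(x)) ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .errors import FittingError, InputError
from .markers import NATURAL_LOG, MarkerSpec, marker_names
from .synthetic_data import BackgroundDataset

#: design-matrix condition number above which a collinearity warning is recorded
_COLLINEARITY_THRESHOLD = 1e8


@dataclass
class CoxFit:
    """A fitted (or ground-truth) proportional-hazards risk model.

    ``beta``/``se`` are per transformed marker unit; ``covariate_center`` is
    on the transform scale; ``baseline_times``/``baseline_cumhaz`` define the
    nondecreasing step function H0(t) evaluated at the center.
    """

    outcome: str
    markers: list[str]
    transforms: list[str]
    beta: np.ndarray
    se: np.ndarray
    covariate_center: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_events: int
    n_patients: int
    beta_covariance: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.covariate_center = np.asarray(self.covariate_center, dtype=float)
        self.baseline_times = np.asarray(self.baseline_times, dtype=float)
        self.baseline_cumhaz = np.asarray(self.baseline_cumhaz, dtype=float)
        p = len(self.markers)
        if not (len(self.beta) == len(self.se) == len(self.covariate_center)
                == len(self.transforms) == p):
            raise InputError("beta/se/center/transforms must align with markers")
        if np.any(self.se < 0):
            raise InputError("standard errors must be nonnegative")
        if np.any(np.diff(self.baseline_cumhaz) < -1e-12):
            raise InputError("baseline cumulative hazard must be nondecreasing")

    # -- baseline hazard ---------------------------------------------------

    @property
    def support_end(self) -> float:
        """Last time at which H0 is defined (no extrapolation beyond it)."""
        return float(self.baseline_times[-1])

    def cumulative_hazard(self, horizon) -> np.ndarray:
        """H0 evaluated at ``horizon`` (scalar or array), H0(0) = 0."""
        h = np.asarray(horizon, dtype=float)
        if np.any(h < 0):
            raise InputError("horizon must be nonnegative")
        if np.any(h > self.support_end + 1e-12):
            raise InputError(
                f"horizon beyond the last observed event time "
                f"({self.support_end:.4g} years); no extrapolation"
            )
        idx = np.searchsorted(self.baseline_times, h, side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]

    # -- prediction --------------------------------------------------------

    def _transform(self, native: np.ndarray) -> np.ndarray:
        z = np.array(native, dtype=float, copy=True)
        for j, tr in enumerate(self.transforms):
            if tr == NATURAL_LOG:
                if np.any(z[..., j] <= 0):
                    raise InputError(
                        f"marker {self.markers[j]!r}: nonpositive value for a "
                        "log-scale marker"
                    )
                z[..., j] = np.log(z[..., j])
        return z

    def linear_predictor(self, z: np.ndarray) -> np.ndarray:
        """Centred linear predictor from transform-scale values (n, p)."""
        return (np.asarray(z, dtype=float) - self.covariate_center) @ self.beta

    def risk_from_lp(self, lp: np.ndarray, horizon: float) -> np.ndarray:
        h0 = self.cumulative_hazard(horizon)
        return -np.expm1(-h0 * np.exp(lp))

    def predict_risk(self, marker_values, horizon: float) -> np.ndarray:
        """Absolute event probability by ``horizon`` for native-scale values.

        ``marker_values`` is a mapping/DataFrame of marker name -> value(s)
        or an array with columns in ``self.markers`` order.
        """
        if isinstance(marker_values, (dict, pd.DataFrame)):
            native = np.column_stack(
                [np.asarray(marker_values[m], dtype=float).ravel()
                 for m in self.markers])
        else:
            native = np.atleast_2d(np.asarray(marker_values, dtype=float))
        z = self._transform(native)
        risk = self.risk_from_lp(self.linear_predictor(z), horizon)
        return risk if risk.size > 1 else float(risk[0])

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome,
            "markers": list(self.markers),
            "transforms": list(self.transforms),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "covariate_center": self.covariate_center.tolist(),
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "n_events": int(self.n_events),
            "n_patients": int(self.n_patients),
            "beta_covariance": (None if self.beta_covariance is None
                                else np.asarray(self.beta_covariance).tolist()),
            "warnings": list(self.warnings),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoxFit":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        cov = payload.pop("beta_covariance", None)
        return cls(**payload, beta_covariance=None if cov is None else np.asarray(cov))


# ---------------------------------------------------------------------------
# Breslow baseline cumulative hazard
# ---------------------------------------------------------------------------

def breslow_cumhaz(times: np.ndarray, events: np.ndarray,
                   lp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimator of H0(t) at the centering of ``lp``.

    Steps d_j / sum_{i in risk set} exp(lp_i) at each distinct event time,
    vectorized via a reverse cumulative sum of exp(lp) over sorted times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    order = np.argsort(times, kind="stable")
    t, e, w = times[order], events[order], np.exp(np.asarray(lp, dtype=float)[order])
    risk_sum = np.cumsum(w[::-1])[::-1]  # sum of exp(lp) over {i : t_i >= t_j}
    event_times = np.unique(t[e == 1])
    first = np.searchsorted(t, event_times, side="left")
    d = np.array([np.sum(e[t == s]) for s in event_times], dtype=float)
    increments = d / risk_sum[first]
    return event_times, np.cumsum(increments)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_cox(background: BackgroundDataset, markers: list[MarkerSpec],
            outcome: str, adjustment_covariates: list[str] | None = None) -> CoxFit:
    """Fit the multivariable Cox model for one outcome on the background cohort.

    Markers enter on their model scale (log for UACR); the covariate center
    is the cohort mean of each transformed marker, and H0 is the Breslow
    step function at that center.  ``adjustment_covariates`` optionally adds
    extra baseline columns to the regression (their coefficients are fitted
    but excluded from the scoring model surface).
    """
    background.validate()
    names = marker_names(markers)
    df = background.df
    if df[f"event_{outcome}"].sum() < 2:
        raise FittingError(f"need at least 2 {outcome} events to fit")

    design = pd.DataFrame({
        m.name: m.to_model_scale(df[f"{m.name}_bl"].to_numpy()) for m in markers
    })
    if df[[f"{m.name}_bl" for m in markers]].isna().any().any():
        raise InputError("background cohort contains missing marker values")
    extra = list(adjustment_covariates or [])
    for col in extra:
        design[col] = df[col].to_numpy(dtype=float)

    warnings_list: list[str] = []
    std = design.to_numpy() - design.to_numpy().mean(axis=0)
    sv = np.linalg.svd(std / np.maximum(std.std(axis=0), 1e-300), compute_uv=False)
    cond = sv[0] / max(sv[-1], 1e-300)
    if cond > _COLLINEARITY_THRESHOLD:
        warnings_list.append(
            f"collinear design: condition number {cond:.3g} exceeds "
            f"{_COLLINEARITY_THRESHOLD:.0e}"
        )

    design["_time"] = df[f"time_{outcome}"].to_numpy(dtype=float)
    design["_event"] = df[f"event_{outcome}"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="_time", event_col="_event",
                show_progress=False)
    except ConvergenceError as err:
        raise FittingError(f"Cox model did not converge: {err}") from err

    beta = cph.params_.reindex(names + extra).to_numpy()
    se = cph.standard_errors_.reindex(names + extra).to_numpy()
    cov = cph.variance_matrix_.reindex(index=names + extra,
                                       columns=names + extra).to_numpy()
    center_all = design[names + extra].mean().to_numpy()

    lp = (design[names + extra].to_numpy() - center_all) @ beta
    event_times, cumhaz = breslow_cumhaz(design["_time"].to_numpy(),
                                         design["_event"].to_numpy(), lp)

    return CoxFit(
        outcome=outcome,
        markers=names,
        transforms=[m.transform for m in markers],
        beta=beta[:len(names)],
        se=se[:len(names)],
        covariate_center=center_all[:len(names)],
        baseline_times=event_times,
        baseline_cumhaz=cumhaz,
        n_events=int(design["_event"].sum()),
        n_patients=len(design),
        beta_covariance=cov[:len(names), :len(names)],
        warnings=warnings_list,
    )


def predict_risk(fit: CoxFit, marker_values, horizon: float):
    """Functional alias for :meth:`CoxFit.predict_risk`."""
    return fit.predict_risk(marker_values, horizon)
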