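"""Multiple imputation by chained equations with predictive mean matching.

Missing follow-up marker values are filled under a missing-at-random
assumption.  Each incomplete variable is regressed (ordinary least squares,
on the transform scale — log for UACR) on all other marker columns plus a
treatment-arm indicator; a coefficient vector is drawn from the approximate
Bayesian posterior (normal around the OLS solution with a scaled
inverse-chi-square residual variance), and every missing entry receives the
*observed* value of one of the ``k_donors`` patients whose predicted mean is
closest — predictive mean matching, so imputed values are always real
observed values and skewed marginals are respected without a parametric
residual model.

Variables are visited in increasing order of missingness count, the chained
sweeps are repeated ``n_iterations`` times, and the whole procedure is run
``m`` times with independent seeded streams to yield m completed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ImputationError, InputError
from .synthetic_data import TREATMENT, TrialDataset


@dataclass(frozen=True)
class ImputationConfig:
    """m completed datasets, chained-equation sweeps, donor-pool size, seed."""

    m: int = 5
    n_iterations: int = 5
    k_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_iterations < 1 or self.k_donors < 1:
            raise InputError("m, n_iterations and k_donors must all be >= 1")


def _posterior_beta_draw(x_obs: np.ndarray, y_obs: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """OLS solution and one draw from its approximate Bayesian posterior."""
    n, p = x_obs.shape
    gram = x_obs.T @ x_obs + 1e-10 * np.eye(p)
    gram_inv = np.linalg.inv(gram)
    beta_hat = gram_inv @ (x_obs.T @ y_obs)
    dof = max(n - p, 1)
    rss = float(np.sum((y_obs - x_obs @ beta_hat) ** 2))
    sigma2 = rss / rng.chisquare(dof) if rss > 0 else 0.0
    cov = sigma2 * gram_inv
    # symmetrize against round-off before factorizing
    chol = np.linalg.cholesky((cov + cov.T) / 2 + 1e-14 * np.eye(p))
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_star


def _pmm_fill(pred_obs: np.ndarray, pred_mis: np.ndarray, y_obs: np.ndarray,
              k: int, rng: np.random.Generator) -> np.ndarray:
    """For each missing case, donate the observed value of one of the k
    nearest observed cases by predicted mean (uniform draw among the k)."""
    nn = NearestNeighbors(n_neighbors=min(k, len(pred_obs)))
    nn.fit(pred_obs.reshape(-1, 1))
    _, idx = nn.kneighbors(pred_mis.reshape(-1, 1))
    chosen = idx[np.arange(len(pred_mis)), rng.integers(0, idx.shape[1], len(pred_mis))]
    return y_obs[chosen]


def _impute_once(z: np.ndarray, arm: np.ndarray, observed: np.ndarray,
                 order: np.ndarray, n_iterations: int, k: int,
                 rng: np.random.Generator) -> np.ndarray:
    """One chained-equation chain on the transform-scale matrix ``z``."""
    filled = z.copy()
    # initial fill: random draws from each variable's observed values
    for j in order:
        obs_j = observed[:, j]
        filled[~obs_j, j] = rng.choice(filled[obs_j, j], size=(~obs_j).sum())
    for _ in range(n_iterations):
        for j in order:
            obs_j = observed[:, j]
            mis_j = ~obs_j
            others = np.delete(np.arange(z.shape[1]), j)
            x = np.column_stack([np.ones(len(z)), arm, filled[:, others]])
            beta_hat, beta_star = _posterior_beta_draw(x[obs_j], filled[obs_j, j], rng)
            pred_obs = x[obs_j] @ beta_hat
            pred_mis = x[mis_j] @ beta_star
            filled[mis_j, j] = _pmm_fill(pred_obs, pred_mis, filled[obs_j, j], k, rng)
    return filled


def impute_chained_pmm(trial: TrialDataset,
                       config: ImputationConfig = ImputationConfig()
                       ) -> list[TrialDataset]:
    """Return ``config.m`` completed copies of the trial.

    Observed cells are never modified; every imputed cell holds an observed
    donor value of the same variable.  With no missing cells the input is
    returned unchanged (m copies).
    """
    trial.validate()
    cols = [f"{m.name}_{s}" for m in trial.markers for s in ("bl", "fu")]
    specs = {f"{m.name}_{s}": m for m in trial.markers for s in ("bl", "fu")}
    raw = trial.df[cols]
    if not raw.map(lambda v: isinstance(v, (int, float, np.floating, np.integer))
                   or pd.isna(v)).all().all():
        raise InputError("non-numeric cells in marker columns")

    z = np.column_stack([specs[c].to_model_scale(raw[c].to_numpy(dtype=float))
                         for c in cols])
    observed = ~np.isnan(z)
    if observed.all():
        return [trial.copy() for _ in range(config.m)]

    n_missing = (~observed).sum(axis=0)
    for j, col in enumerate(cols):
        if n_missing[j] == len(trial):
            raise ImputationError(f"variable {col!r} has no observed values")
        if 0 < observed[:, j].sum() < config.k_donors and n_missing[j] > 0:
            raise ImputationError(
                f"variable {col!r} has fewer observed values than k_donors")
    # visit sequence: increasing missingness count, ties by column order
    incomplete = np.flatnonzero(n_missing > 0)
    order = incomplete[np.argsort(n_missing[incomplete], kind="stable")]

    arm = (trial.df["arm"] == TREATMENT).to_numpy(dtype=float)
    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    completed = []
    for chain in range(config.m):
        rng = np.random.default_rng(streams[chain])
        filled = _impute_once(z, arm, observed, order, config.n_iterations,
                              config.k_donors, rng)
        out = trial.copy()
        for j in order:  # only incomplete columns are rewritten
            col = cols[j]
            vals = raw[col].to_numpy(dtype=float).copy()
            mis = ~observed[:, j]
            vals[mis] = specs[col].to_native_scale(filled[mis, j])
            out.df[col] = vals
        completed.append(out)
    return completed
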