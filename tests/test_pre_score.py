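"""PRE-score estimator: exact nulls, arithmetic oracle, bootstrap, pooling."""

import copy

import numpy as np
import pandas as pd
import pytest

import prescore as ps
from conftest import make_trial


def _single_marker_trial(placebo_bl, placebo_fu, treat_bl, treat_fu, marker=None):
    marker = marker or ps.MarkerSpec("x", "u")
    rows = {
        "arm": ["placebo"] * len(placebo_bl) + ["treatment"] * len(treat_bl),
        "x_bl": list(placebo_bl) + list(treat_bl),
        "x_fu": list(placebo_fu) + list(treat_fu),
        "egfr_bl": 60.0,
    }
    return make_trial([marker], rows)


def test_null_change_gives_exactly_zero_rrr(kidney_fit, trial):
    frozen = trial.copy()
    for m in kidney_fit.markers:
        frozen.df[f"{m}_fu"] = frozen.df[f"{m}_bl"]
    for subset in (None, ["uacr"], ["hba1c", "sbp"]):
        res = ps.pre_rrr(kidney_fit, frozen, subset)
        assert res.rrr_percent == 0.0


def test_two_patient_arithmetic_oracle(tiny_fit):
    """One patient per arm, H0 = 0.1: placebo lp 0 -> 0, treatment lp
    0 -> -ln 2; RRR = 100 (1 - (1-e^-0.05)/(1-e^-0.1)) ~ 48.75 %."""
    trial = _single_marker_trial([0.0], [0.0], [0.0], [-np.log(2.0)])
    res = ps.pre_rrr(tiny_fit, trial, horizon=3.5)

    # independent per-patient recomputation, plain arithmetic
    def risk(lp):
        return 1.0 - np.exp(-0.1 * np.exp(lp))

    delta_placebo = (risk(0.0) - risk(0.0)) / risk(0.0)
    delta_treat = (risk(-np.log(2.0)) - risk(0.0)) / risk(0.0)
    expected = -100.0 * (delta_treat - delta_placebo)
    assert res.rrr_percent == pytest.approx(expected, rel=1e-12)
    assert res.rrr_percent == pytest.approx(48.7503, abs=5e-4)


def test_zero_coefficient_marker_scores_zero(trial, kidney_fit):
    fit = copy.deepcopy(kidney_fit)
    fit.beta = fit.beta.copy()
    fit.beta[fit.markers.index("potassium")] = 0.0
    res = ps.single_marker_rrr(fit, trial, "potassium")
    assert res.rrr_percent == 0.0


def test_single_active_marker_equals_integrated(kidney_fit, trial):
    """If only UACR changes between baseline and follow-up, the UACR-only
    score equals the integrated score."""
    t = trial.copy()
    for m in kidney_fit.markers:
        if m != "uacr":
            t.df[f"{m}_fu"] = t.df[f"{m}_bl"]
    only = ps.single_marker_rrr(kidney_fit, t, "uacr")
    integrated = ps.pre_rrr(kidney_fit, t)
    assert only.rrr_percent == pytest.approx(integrated.rrr_percent, rel=1e-12)


def test_integrated_not_sum_of_single_markers(kidney_fit, trial):
    singles = sum(ps.single_marker_rrr(kidney_fit, trial, m).rrr_percent
                  for m in kidney_fit.markers)
    integrated = ps.pre_rrr(kidney_fit, trial).rrr_percent
    assert integrated != pytest.approx(singles, abs=1e-6)


def test_placebo_adjustment_absorbs_common_change(tiny_fit):
    """A change common to both (mirrored) arms is absorbed by the placebo
    adjustment: exactly when there is no treatment effect, and to first
    order (risk nonlinearity is second order in the common change) when a
    treatment effect is present."""
    bl = [0.0, 0.5, -0.3, 1.0]
    # no treatment effect: common change -> RRR exactly 0
    same = _single_marker_trial(bl, [b - 0.4 for b in bl], bl,
                                [b - 0.4 for b in bl])
    assert ps.pre_rrr(tiny_fit, same).rrr_percent == pytest.approx(0.0, abs=1e-12)
    # with a treatment effect, a small common change moves the RRR only
    # proportionally to its size (first-order invariance)
    trial0 = _single_marker_trial(bl, bl, bl, [b - 0.7 for b in bl])
    r0 = ps.pre_rrr(tiny_fit, trial0).rrr_percent
    devs = []
    for c in (0.05, 0.2):
        shifted = _single_marker_trial(bl, [b - c for b in bl], bl,
                                       [b - 0.7 - c for b in bl])
        devs.append(abs(ps.pre_rrr(tiny_fit, shifted).rrr_percent - r0))
    assert devs[0] < 2.5
    assert devs[0] < 0.5 * devs[1]  # deviation shrinks with the common change


def test_vectorized_matches_per_patient_loop(kidney_fit, trial):
    rows = pd.concat([trial.df[trial.df.arm == "placebo"].head(50),
                      trial.df[trial.df.arm == "treatment"].head(50)],
                     ignore_index=True)
    sub = ps.TrialDataset(rows, trial.markers)
    res = ps.pre_rrr(kidney_fit, sub)
    # per-patient loop oracle
    risks_bl, risks_fu, arms = [], [], []
    for _, row in sub.df.iterrows():
        bl = {m: [row[f"{m}_bl"]] for m in kidney_fit.markers}
        fu = {m: [row[f"{m}_fu"]] for m in kidney_fit.markers}
        risks_bl.append(kidney_fit.predict_risk(bl, res.horizon))
        risks_fu.append(kidney_fit.predict_risk(fu, res.horizon))
        arms.append(row["arm"])
    risks_bl, risks_fu = np.array(risks_bl), np.array(risks_fu)
    arms = np.array(arms)
    d = {}
    for arm in ("placebo", "treatment"):
        sel = arms == arm
        d[arm] = (risks_fu[sel].mean() - risks_bl[sel].mean()) / risks_bl[sel].mean()
    expected = -100.0 * (d["treatment"] - d["placebo"])
    assert res.rrr_percent == pytest.approx(expected, rel=1e-12)


def test_horizon_insensitivity(kidney_fit, trial):
    """Under a proportional-hazards generator the RRR is nearly flat in the
    risk horizon (ratio of ratios)."""
    rrrs = [ps.pre_rrr(kidney_fit, trial, horizon=h).rrr_percent
            for h in (1.0, 2.0, 3.0, 3.5)]
    assert max(rrrs) - min(rrrs) < 1.0


def test_kidney_rrr_monotone_in_uacr_reduction(kidney_fit):
    rrrs = []
    for extra in (0.0, 0.2, 0.4):
        markers = [m.with_shift(m.treatment_shift - extra) if m.name == "uacr"
                   else m for m in ps.leader_like_markers()]
        cfg = ps.GeneratorConfig(markers=markers, n_per_arm=4000, seed=17)
        cfg.baseline_hazard_rate = {"kidney": 0.01, "cv": 0.03}
        rrrs.append(ps.pre_rrr(kidney_fit, ps.generate_trial(cfg)).rrr_percent)
    assert rrrs[0] < rrrs[1] < rrrs[2]


def test_input_errors(kidney_fit, trial):
    with pytest.raises(ps.InputError):
        ps.pre_rrr(kidney_fit, trial, ["nonexistent"])
    lonely = ps.TrialDataset(
        trial.df[trial.df.arm == "placebo"].copy(), trial.markers)
    with pytest.raises(ps.InputError):
        ps.pre_rrr(kidney_fit, lonely)
    holey = trial.copy()
    holey.df.loc[3, "uacr_fu"] = np.nan
    with pytest.raises(ps.InputError):
        ps.pre_rrr(kidney_fit, holey)


class TestBootstrap:
    def test_zero_se_collapses_interval(self, trial, kidney_fit):
        fit = copy.deepcopy(kidney_fit)
        fit.se = np.zeros_like(fit.se)
        res = ps.bootstrap_ci(fit, trial, n_draws=50, seed=1)
        assert res.ci_low_percent == pytest.approx(res.rrr_percent, rel=1e-12)
        assert res.ci_high_percent == pytest.approx(res.rrr_percent, rel=1e-12)

    def test_seeded_determinism(self, trial, kidney_fit):
        a = ps.bootstrap_ci(kidney_fit, trial, n_draws=100, seed=5)
        b = ps.bootstrap_ci(kidney_fit, trial, n_draws=100, seed=5)
        assert (a.ci_low_percent, a.ci_high_percent) == \
            (b.ci_low_percent, b.ci_high_percent)
        c = ps.bootstrap_ci(kidney_fit, trial, n_draws=100, seed=6)
        assert (a.ci_low_percent, a.ci_high_percent) != \
            (c.ci_low_percent, c.ci_high_percent)

    def test_two_draws_interval_near_min_max(self, trial, kidney_fit):
        res = ps.bootstrap_ci(kidney_fit, trial, n_draws=2, seed=2)
        lo, hi = sorted(res.bootstrap_draws)
        # 2.5/97.5 percentiles of two points interpolate very close to them
        assert res.ci_low_percent == pytest.approx(lo, abs=0.06 * (hi - lo) + 1e-9)
        assert res.ci_high_percent == pytest.approx(hi, abs=0.06 * (hi - lo) + 1e-9)

    def test_interval_ordered_and_brackets_point(self, trial, kidney_fit):
        res = ps.bootstrap_ci(kidney_fit, trial, n_draws=100, seed=3)
        assert res.ci_low_percent <= res.ci_high_percent
        assert res.n_bootstrap == 100

    def test_multivariate_mode(self, trial, kidney_fit):
        res = ps.bootstrap_ci(kidney_fit, trial, n_draws=100, seed=3,
                              multivariate=True)
        assert res.ci_low_percent < res.ci_high_percent

    def test_rejects_single_draw(self, trial, kidney_fit):
        with pytest.raises(ps.InputError):
            ps.bootstrap_ci(kidney_fit, trial, n_draws=1)


class TestPooling:
    def test_single_result_identity(self, trial, kidney_fit):
        res = ps.bootstrap_ci(kidney_fit, trial, n_draws=20, seed=1)
        assert ps.pool_over_imputations([res]) is res

    def test_identical_results_pool_to_same(self, trial, kidney_fit):
        res = ps.bootstrap_ci(kidney_fit, trial, n_draws=50, seed=1)
        pooled = ps.pool_over_imputations([res, copy.deepcopy(res)])
        assert pooled.rrr_percent == pytest.approx(res.rrr_percent, rel=1e-12)
        # duplicating the draw set can move a percentile only within the
        # interpolation gap between adjacent order statistics
        gap = np.diff(np.sort(res.bootstrap_draws)).max()
        assert pooled.ci_low_percent == pytest.approx(res.ci_low_percent, abs=gap)
        assert pooled.ci_high_percent == pytest.approx(res.ci_high_percent, abs=gap)
        assert pooled.m_imputations == 2

    def test_heterogeneous_subsets_rejected(self, trial, kidney_fit):
        a = ps.pre_rrr(kidney_fit, trial, ["uacr"])
        b = ps.pre_rrr(kidney_fit, trial, ["sbp"])
        with pytest.raises(ps.InputError):
            ps.pool_over_imputations([a, b])
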