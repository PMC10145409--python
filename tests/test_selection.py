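"""Supervised forward selection: per-step oracles, sign constraints,
pruning, trace replay, and end-state invariants."""

import numpy as np
import pandas as pd
import pytest

from pahlur.predictors import PredictorSpec
from pahlur.regression import fit_ols
from pahlur.selection import (
    SelectionConfig,
    _loo_stable,
    develop_model,
    forward_select,
    prune_significance,
    replay_trace,
    screen_univariate,
)
from tests.conftest import random_design, uncertain_registry


def signed_registry(signs: dict[str, str]):
    return {c: PredictorSpec(c, "geo", None, "", s) for c, s in signs.items()}


class TestLooStable:
    def test_single_active_row_excluded(self):
        assert not _loo_stable(np.r_[5.0, np.zeros(9)])

    def test_two_active_rows_kept(self):
        assert _loo_stable(np.r_[5.0, 3.0, np.zeros(8)])

    def test_constant_excluded(self):
        assert not _loo_stable(np.ones(10))


class TestScreenUnivariate:
    def test_matches_per_candidate_ols(self):
        rng = np.random.default_rng(0)
        X = random_design(rng, 25, 8)
        y = (X["v00"] * 2 - X["v03"]).to_numpy() + rng.normal(0, 1, 25)
        reg = uncertain_registry(X.columns)
        cands = screen_univariate(y, X, reg)
        assert len(cands) == 8
        for c in cands:
            ref = fit_ols(y, X[[c.code]])
            assert c.r2 == pytest.approx(ref.r2, abs=1e-10)
            assert c.slope == pytest.approx(ref.coefficients[c.code],
                                            abs=1e-10)
        r2s = [c.r2 for c in cands]
        assert r2s == sorted(r2s, reverse=True)
        assert cands[0].code == "v00"

    def test_wrong_sign_marked_ineligible_and_sorted_last(self):
        rng = np.random.default_rng(1)
        X = random_design(rng, 20, 2)
        y = (X["v00"] * 3).to_numpy()  # positive association
        reg = signed_registry({"v00": "-", "v01": "uncertain"})
        cands = screen_univariate(y, X, reg)
        assert not cands[-1].eligible and cands[-1].code == "v00"
        assert cands[0].eligible

    def test_unregistered_columns_ignored(self):
        rng = np.random.default_rng(2)
        X = random_design(rng, 15, 3)
        reg = uncertain_registry(["v00"])
        cands = screen_univariate(rng.normal(size=15), X, reg)
        assert [c.code for c in cands] == ["v00"]


class TestForwardSelect:
    def test_each_step_is_the_oracle_best(self):
        """Every 'added' step must be the highest-adjusted-R^2 admissible
        addition, verified by refitting all alternatives."""
        rng = np.random.default_rng(4)
        X = random_design(rng, 25, 10)
        beta = np.zeros(10)
        beta[[1, 4, 7]] = [2.0, -1.5, 1.0]
        y = (X @ beta).to_numpy() + rng.normal(0, 0.5, 25)
        reg = uncertain_registry(X.columns)
        model = forward_select(y, X, reg)
        added = [t.candidate for t in model.trace if t.action == "added"]
        current = []
        for code in added:
            best_adj, best_codes = -np.inf, None
            for alt in X.columns:
                if alt in current:
                    continue
                trial = current + [alt]
                try:
                    f = fit_ols(y, X[trial])
                except ValueError:
                    continue
                if f.adj_r2 > best_adj:
                    best_adj, best_codes = f.adj_r2, alt
            assert code == best_codes, f"step chose {code}, oracle {best_codes}"
            current.append(code)

    def test_small_gain_rejected_and_traced(self):
        rng = np.random.default_rng(8)
        n = 30
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 5 * x1 + rng.normal(0, 1e-4, n)  # x2 adds nothing
        X = pd.DataFrame({"x1": x1, "x2": x2})
        reg = uncertain_registry(["x1", "x2"])
        model = forward_select(y, X, reg)
        assert model.fit.codes == ["x1"]
        actions = {t.action for t in model.trace}
        assert "rejected_gain" in actions

    def test_sign_flip_of_entered_variable_blocks_addition(self):
        """A candidate whose entry would flip an already-entered slope's
        sign out of its permitted direction is rejected."""
        rng = np.random.default_rng(12)
        n = 40
        x1 = rng.normal(size=n)
        # x2 nearly collinear with x1: entering it flips x1's slope
        x2 = x1 + rng.normal(0, 0.05, n)
        y = x1 + 0.9 * x2 + rng.normal(0, 0.1, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        reg = signed_registry({"x1": "+", "x2": "+"})
        model = forward_select(y, X, reg)
        for code, b in model.fit.coefficients.items():
            assert b > 0, f"{code} slope {b} violates '+' constraint"

    def test_no_eligible_candidate_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        X = random_design(rng, 15, 2)
        y = (3 * X["v00"] + 2 * X["v01"]).to_numpy()
        reg = signed_registry({"v00": "-", "v01": "-"})
        model = forward_select(y, X, reg)
        assert model.fit.p == 0
        assert model.fit.intercept == pytest.approx(y.mean())

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        X = random_design(rng, 25, 12)
        y = rng.normal(size=25)
        reg = uncertain_registry(X.columns)
        m1 = forward_select(y, X, reg)
        m2 = forward_select(y, X, reg)
        assert m1.fit.codes == m2.fit.codes
        assert [(t.step, t.candidate, t.action) for t in m1.trace] == [
            (t.step, t.candidate, t.action) for t in m2.trace
        ]


class TestPruneSignificance:
    def test_all_survivors_significant(self):
        rng = np.random.default_rng(10)
        X = random_design(rng, 30, 6)
        y = (4 * X["v00"]).to_numpy() + rng.normal(0, 1, 30)
        reg = uncertain_registry(X.columns)
        model = forward_select(y, X, reg, SelectionConfig(gain_threshold=0.0))
        pruned = prune_significance(model, y, X, alpha=0.05)
        for code, p in pruned.fit.p_values.items():
            assert p < 0.05, f"{code} survived with p={p}"

    def test_largest_p_removed_first(self):
        rng = np.random.default_rng(14)
        X = random_design(rng, 30, 4)
        y = rng.normal(size=30)
        reg = uncertain_registry(X.columns)
        model = forward_select(y, X, reg, SelectionConfig(gain_threshold=0.0))
        fit_before = model.fit
        pruned = prune_significance(model, y, X, alpha=0.05)
        removals = [t for t in pruned.trace if t.action == "removed_pvalue"]
        if removals and fit_before.p:
            first = removals[0].candidate
            worst = max(fit_before.p_values, key=fit_before.p_values.get)
            assert first == worst


class TestReplayTrace:
    def test_replay_reproduces_final_model(self):
        rng = np.random.default_rng(20)
        X = random_design(rng, 28, 9)
        beta = np.zeros(9)
        beta[[0, 5]] = [1.5, -2.0]
        y = (X @ beta).to_numpy() + rng.normal(0, 0.6, 28)
        reg = uncertain_registry(X.columns)
        model, _ = develop_model(y, X, reg, config=SelectionConfig(
            moran_permutations=99))
        refit = replay_trace(model.trace, y, X)
        assert refit.codes == model.fit.codes
        assert list(refit.coefficients.values()) == pytest.approx(
            list(model.fit.coefficients.values()), abs=1e-12
        )


class TestDevelopModel:
    def test_end_state_invariants_random_data(self):
        cfg = SelectionConfig(moran_permutations=99)
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = random_design(rng, 25, 10)
            beta = np.zeros(10)
            beta[rng.choice(10, 3, replace=False)] = rng.normal(0, 2, 3)
            y = (X @ beta).to_numpy() + rng.normal(0, 1, 25)
            reg = uncertain_registry(X.columns)
            model, diags = develop_model(y, X, reg, config=cfg)
            for code, p in model.fit.p_values.items():
                assert p < cfg.alpha
            for code, v in diags.vif.items():
                assert v < cfg.vif_threshold

    def test_near_duplicate_predictors_not_both_kept(self):
        rng = np.random.default_rng(30)
        n = 30
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(0, 0.02, n)  # corr ~ 0.999
        x3 = rng.normal(size=n)
        y = 2 * x1 + x3 + rng.normal(0, 0.3, n)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        reg = uncertain_registry(X.columns)
        model, diags = develop_model(
            y, X, reg, config=SelectionConfig(moran_permutations=99))
        assert not ({"x1", "x2"} <= set(model.fit.codes))
        for v in diags.vif.values():
            assert v < 5.0

    def test_moran_reported_when_coords_given(self):
        rng = np.random.default_rng(33)
        X = random_design(rng, 20, 4)
        y = (X["v00"]).to_numpy() + rng.normal(0, 0.5, 20)
        coords = rng.uniform(0, 1000, (20, 2))
        reg = uncertain_registry(X.columns)
        _, diags = develop_model(
            y, X, reg, coords=coords,
            config=SelectionConfig(moran_permutations=199),
            rng=np.random.default_rng(0),
        )
        assert diags.morans_i is not None
        assert diags.morans_i.expected == pytest.approx(-1 / 19)
        assert diags.morans_i.n_permutations == 199

    def test_min_rows_enforced(self):
        X = random_design(np.random.default_rng(0), 5, 2)
        with pytest.raises(ValueError, match="at least"):
            develop_model(np.zeros(5), X, uncertain_registry(X.columns))


class TestSelectionConfig:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"alpha": 1.5}, "alpha"),
            ({"gain_threshold": -0.1}, "gain_threshold"),
            ({"vif_threshold": 0.5}, "vif_threshold"),
            ({"gain_mode": "magic"}, "gain_mode"),
        ],
    )
    def test_bad_values_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SelectionConfig(**kwargs)
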