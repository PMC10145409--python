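"""LOOCV against a brute-force oracle, detection gating, non-detect
substitution, and the batch runner's stratum accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pahlur.concentrations import ConcentrationRecord, generate_concentrations
from pahlur.selection import SelectionConfig
from pahlur.validation import (
    detection_gate,
    kruskal_wallis,
    loocv,
    rmse,
    run_batch,
    substitute_nondetects,
)
from tests.conftest import random_design


class TestRMSE:
    def test_hand_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_zero_for_perfect(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([1.0], [1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse([], [])


class TestLOOCV:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        X = random_design(rng, 18, 3)
        y = (X["v00"] * 2 - X["v02"]).to_numpy() + rng.normal(0, 0.7, 18)
        structure = ["v00", "v02"]
        res = loocv(y, X, structure)
        # independent fold loop built on raw lstsq
        n = len(y)
        preds = np.empty(n)
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            design = np.column_stack(
                [np.ones(n - 1), X.iloc[keep][structure].to_numpy()]
            )
            beta, *_ = np.linalg.lstsq(design, y[keep], rcond=None)
            row = np.r_[1.0, X.iloc[i][structure].to_numpy()]
            preds[i] = row @ beta
        assert res.predictions == pytest.approx(preds, abs=1e-10)
        assert res.rmse == pytest.approx(
            np.sqrt(np.mean((preds - y) ** 2)), abs=1e-12
        )
        assert res.pearson_r == pytest.approx(
            np.corrcoef(preds, y)[0, 1], abs=1e-12
        )

    def test_noiseless_signal_predicted_exactly(self):
        rng = np.random.default_rng(4)
        X = random_design(rng, 15, 2)
        y = (1.0 + 3 * X["v00"]).to_numpy()
        res = loocv(y, X, ["v00"])
        assert res.rmse <= 1e-8 * np.linalg.norm(y)
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_outcome_gives_constant_predictions(self):
        rng = np.random.default_rng(5)
        X = random_design(rng, 12, 1)
        y = np.full(12, 7.0)
        with pytest.warns(UserWarning, match="constant"):
            res = loocv(y, X, ["v00"])
        assert np.isnan(res.pearson_r)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    def test_failing_fold_named(self):
        # predictor non-constant only thanks to row 0: fold 0 fails
        X = pd.DataFrame({"x": np.r_[5.0, np.zeros(9)]})
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="row 0"):
            loocv(y, X, ["x"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            loocv(np.zeros(4), random_design(np.random.default_rng(0), 4, 1),
                  [])


class TestKruskalWallis:
    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        g1 = rng.normal(0, 1, 20)
        g2 = rng.normal(0.5, 1, 25)
        g3 = rng.normal(1.0, 1, 15)
        h, p = kruskal_wallis(g1, g2, g3)
        h_ref, p_ref = stats.kruskal(g1, g2, g3)
        assert h == pytest.approx(h_ref) and p == pytest.approx(p_ref)

    def test_all_identical_is_degenerate_null(self):
        assert kruskal_wallis([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([1.0, 2.0])


class TestDetectionGate:
    def rec(self, detected):
        return ConcentrationRecord("s", "A", "windy", "gaseous", 1.0, detected)

    def test_boundary_at_half(self):
        recs_fail = [self.rec(True)] * 12 + [self.rec(False)] * 13
        recs_pass = [self.rec(True)] * 13 + [self.rec(False)] * 12
        ok, rate = detection_gate(recs_fail, 0.5)
        assert not ok and rate == pytest.approx(12 / 25)
        ok, rate = detection_gate(recs_pass, 0.5)
        assert ok and rate == pytest.approx(13 / 25)

    def test_exact_threshold_passes(self):
        recs = [self.rec(True)] * 10 + [self.rec(False)] * 10
        ok, rate = detection_gate(recs, 0.5)
        assert ok and rate == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detection_gate([])


class TestSubstituteNondetects:
    def test_rules(self):
        vals = np.array([1.0, 2.0, 3.0])
        det = np.array([True, False, True])
        out = substitute_nondetects(vals, det, 0.05, "dl_sqrt2")
        assert out == pytest.approx([1.0, 0.05 / np.sqrt(2), 3.0])
        out = substitute_nondetects(vals, det, 0.05, "dl_half")
        assert out[1] == pytest.approx(0.025)
        out = substitute_nondetects(vals, det, 0.05, "zero")
        assert out[1] == 0.0
        assert vals[1] == 2.0  # input untouched

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown non-detect rule"):
            substitute_nondetects(np.ones(2), [True, True], 0.05, "drop")


@pytest.fixture(scope="module")
def small_batch(scenario, world_net, covariate_table, registry30):
    world, net = world_net
    recs = [
        r for r in generate_concentrations(world, net, scenario)
        if r.species in ("Ace", "Flo", "BghiP")
    ]
    coords = np.array([(s[1], s[2]) for s in net.sites])
    cfg = SelectionConfig(moran_permutations=99)
    report = run_batch(recs, covariate_table, registry30, coords=coords,
                       config=cfg, seed=5)
    return recs, report


class TestRunBatch:
    def test_every_stratum_modeled_or_skipped(self, small_batch):
        recs, report = small_batch
        present = {(r.species, r.season, r.phase) for r in recs}
        assert report.strata() == present
        assert len(present) == 18  # 3 species x 3 seasons x 2 phases

    def test_gaseous_bghip_gated_out(self, small_batch):
        _, report = small_batch
        skipped = {(s.species, s.season, s.phase) for s in report.skipped}
        for season in ("windy", "non-heating", "heating"):
            assert ("BghiP", season, "gaseous") in skipped
        for s in report.skipped:
            if s.species == "BghiP" and s.phase == "gaseous":
                assert "detection rate" in s.reason

    def test_rows_respect_thresholds(self, small_batch):
        _, report = small_batch
        assert report.rows
        for row in report.rows:
            assert row.detection_rate >= 0.5
            assert row.n == 25
            for p in row.model.fit.p_values.values():
                assert p < 0.05

    def test_report_frame_schema(self, small_batch):
        _, report = small_batch
        df = report.to_frame()
        assert list(df.columns) == [
            "PAH", "Season", "Phase", "LUR Model", "R2", "adj_R2", "RMSE",
            "LOOCV_r", "detection_rate", "n",
        ]
        assert len(df) == len(report.rows)

    def test_deterministic_given_seed(self, scenario, world_net,
                                      covariate_table, registry30):
        world, net = world_net
        recs = [r for r in generate_concentrations(world, net, scenario)
                if r.species == "Ace"]
        cfg = SelectionConfig(moran_permutations=99)
        coords = np.array([(s[1], s[2]) for s in net.sites])
        rep1 = run_batch(recs, covariate_table, registry30, coords, cfg,
                         seed=3)
        rep2 = run_batch(recs, covariate_table, registry30, coords, cfg,
                         seed=3)
        eq1 = [r.model.equation() for r in rep1.rows]
        eq2 = [r.model.equation() for r in rep2.rows]
        assert eq1 == eq2
        assert [r.moran_p for r in rep1.rows] == [r.moran_p for r in rep2.rows]

    def test_missing_site_records_become_skip_not_crash(
            self, scenario, world_net, covariate_table, registry30):
        world, net = world_net
        recs = [r for r in generate_concentrations(world, net, scenario)
                if r.species == "Flo" and r.site_id != net.ids()[0]]
        report = run_batch(recs, covariate_table, registry30,
                           config=SelectionConfig(moran_permutations=99))
        assert not report.rows
        assert all("missing" in s.reason for s in report.skipped)
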