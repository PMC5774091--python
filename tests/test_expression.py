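"""FPKM transforms, standard curves and relative-expression recovery."""

import numpy as np
import pandas as pd
import pytest

from familyscan import expression as ex
from familyscan import synthetic_data as sd


class TestHeatmapTransform:
    def test_constant_matrix_all_zero(self):
        m = pd.DataFrame(np.full((3, 4), 5.0))
        out = ex.heatmap_transform(m, pseudocount=0.0)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_hand_computed_2x2(self):
        m = pd.DataFrame([[4.0, 1.0], [1.0, 2.0]])
        out = ex.heatmap_transform(m, pseudocount=0.0)
        assert np.allclose(out.to_numpy(), [[1.0, -1.0], [-1.0, 0.0]])

    def test_zero_cell_finite_with_pseudocount(self):
        m = pd.DataFrame([[0.0, 8.0]])
        out = ex.heatmap_transform(m, pseudocount=0.01)
        assert np.isfinite(out.to_numpy()).all()

    def test_normalization_conservation(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(2, 1, size=(10, 6)))
        out = ex.heatmap_transform(m, pseudocount=0.0)
        assert float((2.0 ** out).to_numpy().mean()) == pytest.approx(1.0)

    def test_all_zero_no_pseudocount_is_error(self):
        with pytest.raises(ValueError):
            ex.heatmap_transform(pd.DataFrame(np.zeros((2, 2))), pseudocount=0.0)


class TestTissueCallsAndRatios:
    def test_silent_and_expressed(self):
        m = pd.DataFrame({"t1": [0.0, 5.0], "t2": [0.3, 0.0]}, index=["a", "b"])
        expressed, never = ex.tissue_calls(m, threshold=1.0)
        assert never == ["a"] and bool(expressed.loc["b", "t1"])

    def test_planted_silent_genes(self, default_sim):
        mats = sd.simulate_fpkm(default_sim.config)
        _, never = ex.tissue_calls(mats["tissues"])
        assert never == default_sim.truth["silent_genes"]

    def test_stress_ratio_basics(self):
        control = pd.DataFrame({"s": [1.0, 2.0]})
        assert np.allclose(ex.stress_ratio(control, control, 0.0).to_numpy(), 1.0)
        out = ex.stress_ratio(pd.DataFrame({"s": [10.0]}),
                              pd.DataFrame({"s": [1.0]}), 0.0)
        assert float(out.iloc[0, 0]) == 10.0
        finite = ex.stress_ratio(pd.DataFrame({"s": [1.0]}),
                                 pd.DataFrame({"s": [0.0]}), 0.01)
        assert np.isfinite(float(finite.iloc[0, 0]))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ex.stress_ratio(pd.DataFrame(np.ones((2, 2))),
                            pd.DataFrame(np.ones((3, 2))))


class TestStandardCurve:
    def test_perfect_doubling_chemistry(self):
        # Cq rises by log2(3) per 3-fold dilution at 100% efficiency
        dilutions = [3, 9, 27, 81]
        cq = [25 + (-1 / np.log10(2)) * np.log10(1 / d) for d in dilutions]
        curve = ex.fit_standard_curve(dilutions, cq)
        assert curve.slope == pytest.approx(-3.3219, abs=1e-3)
        assert curve.efficiency_pct == pytest.approx(100.0, abs=0.1)
        assert curve.r_squared == pytest.approx(1.0)

    def test_flat_series_flagged(self):
        curve = ex.fit_standard_curve([3, 9, 27], [20.0, 20.0, 20.0])
        assert curve.slope == 0.0
        with pytest.raises(ZeroDivisionError):
            _ = curve.efficiency_pct

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ex.fit_standard_curve([3, 9], [20, 21])

    def test_slope_recovery_under_noise(self):
        # Monte Carlo over seeded replicates: sigma 0.1 Cq noise leaves
        # the slope estimator unbiased (mean within +-0.15) with the
        # spread least-squares theory predicts (sd sigma/sqrt(Sxx))
        rng = np.random.default_rng(17)
        true_slope = -1 / np.log10(2)
        estimates = []
        for _ in range(1000):
            d = np.array([3, 9, 27, 81])
            cq = 24 + true_slope * np.log10(1 / d) + rng.normal(0, 0.1, size=4)
            estimates.append(ex.fit_standard_curve(d, cq).slope)
        x = np.log10(1 / np.array([3, 9, 27, 81]))
        theory_sd = 0.1 / np.sqrt(((x - x.mean()) ** 2).sum())
        assert np.mean(estimates) == pytest.approx(true_slope, abs=0.15)
        assert np.std(estimates) == pytest.approx(theory_sd, rel=0.15)


def _cq_tables(fold, sigma=0.0, seed=0, slope=None, intercept_t=24.0,
               intercept_r=21.0):
    rng = np.random.default_rng(seed)
    slope = -1 / np.log10(2) if slope is None else slope
    rows_t, rows_r = [], []
    for tp, f in (("0h", 1.0), ("24h", fold)):
        for bio in (1, 2, 3):
            for tech in (1, 2):
                qt = 0.05 * f
                rows_t.append({"condition": "heat", "timepoint": tp,
                               "bio_rep": bio, "tech_rep": tech,
                               "cq": intercept_t + slope * np.log10(qt)
                               + rng.normal(0, sigma)})
                rows_r.append({"condition": "heat", "timepoint": tp,
                               "bio_rep": bio, "tech_rep": tech,
                               "cq": intercept_r + slope * np.log10(0.05)
                               + rng.normal(0, sigma)})
    return pd.DataFrame(rows_t), pd.DataFrame(rows_r)


class TestRelativeExpression:
    def _curves(self, intercept_t=24.0, intercept_r=21.0):
        slope = -1 / np.log10(2)
        return (ex.StandardCurve(slope, intercept_t, 1.0),
                ex.StandardCurve(slope, intercept_r, 1.0))

    def test_control_sample_is_unity(self):
        t, r = _cq_tables(fold=7.0, sigma=0.05, seed=4)
        ct, cr = self._curves()
        rels = ex.relative_expression(t, r, ct, cr, "0h", gene="g")
        ctrl = next(x for x in rels if x.timepoint == "0h")
        assert ctrl.fold_change_mean == pytest.approx(1.0, abs=1e-9)
        assert ctrl.n_bio == 3 and ctrl.n_tech == 2

    def test_hundredfold_delta_cq(self):
        # a -log2(100) Cq shift at 100% efficiency is a 100-fold change
        t, r = _cq_tables(fold=100.0)
        ct, cr = self._curves()
        rels = ex.relative_expression(t, r, ct, cr, "0h")
        stressed = next(x for x in rels if x.timepoint == "24h")
        assert stressed.fold_change_mean == pytest.approx(100.0, rel=1e-6)

    @pytest.mark.parametrize("fold", [0.5, 1.0, 10.0, 150.0])
    def test_planted_folds_recovered(self, fold):
        t, r = _cq_tables(fold=fold, sigma=0.1, seed=int(fold * 10))
        ct, cr = self._curves()
        rels = ex.relative_expression(t, r, ct, cr, "0h")
        stressed = next(x for x in rels if x.timepoint == "24h")
        assert stressed.fold_change_mean == pytest.approx(fold, rel=0.15)


class TestClassifyResponse:
    @pytest.mark.parametrize("folds,cls", [
        ((120, 300), "up_extreme"),
        ((1.1, 0.95), "no_change"),
        ((5, 80), "up"),
        ((0.2, 0.4), "down"),
    ])
    def test_rules(self, folds, cls):
        assert ex.classify_response(folds) == cls

    def test_monotonicity(self):
        folds = (0.3, 0.4)
        assert ex.classify_response(folds) == "down"
        order = ["down", "no_change", "up", "up_extreme"]
        prev = order.index(ex.classify_response(folds))
        for scale in (3, 10, 500):
            now = order.index(ex.classify_response([f * scale for f in folds]))
            assert now >= prev
            prev = now

    def test_planted_up_extreme_set(self, default_sim):
        cq = sd.simulate_qpcr(default_sim.config)
        folds = ex.quantify_qpcr_table(cq, "ef1a", "0h")
        extreme = sorted(set(
            folds[(folds.response_class == "up_extreme")
                  & (folds.condition == "heat")].gene))
        assert extreme == sorted(default_sim.truth["up_extreme"])
        assert len(extreme) == 14
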