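"""Two-way decomposition, cell summaries and the cell-means collapse."""

import numpy as np
import pytest
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

import anovatab as at
from anovatab.exceptions import DesignError, NumericError, ReplicationError


class TestCellSummaries:
    def test_toy_hand_computation(self, toy_dataset):
        cells = at.cell_summaries(toy_dataset, "y")
        assert [c.treatment for c in cells] == \
            [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")]
        assert [c.mean for c in cells] == [2.0, 3.0, 6.0, 7.0]
        for c in cells:
            assert c.sem == pytest.approx(1.0)  # s = sqrt(2), n = 2
            assert c.n == 2

    def test_constant_cell(self):
        ds = at.Dataset("A", "B", [
            ("a1", "b1", {"y": 5.0})] * 3 + [
            ("a1", "b2", {"y": 1.0}), ("a2", "b1", {"y": 2.0}),
            ("a2", "b2", {"y": 3.0})])
        c = at.cell_summaries(ds, "y")[0]
        assert (c.mean, c.sem, c.n) == (5.0, 0.0, 3)

    def test_missing_values_reduce_n(self):
        ds = at.Dataset("A", "B", [
            ("a1", "b1", {"y": 1.0}), ("a1", "b1", {"y": 2.0}),
            ("a1", "b1", {"y": None}),
            ("a1", "b2", {"y": 1.0}), ("a2", "b1", {"y": 1.0}),
            ("a2", "b2", {"y": 1.0})])
        assert at.cell_summaries(ds, "y")[0].n == 2

    def test_empty_cell_rejected(self):
        ds = at.Dataset("A", "B", [
            ("a1", "b1", {"y": 1.0}), ("a1", "b2", {"y": 2.0}),
            ("a2", "b1", {"y": 3.0}), ("a2", "b2", {"y": None})])
        with pytest.raises(DesignError, match="incomplete"):
            at.cell_summaries(ds, "y")


class TestFitTwoWay:
    def test_toy_hand_computation(self, toy_dataset):
        res = at.fit_two_way(toy_dataset, "y")
        ss = {t.name: t.ss for t in res.terms}
        assert ss["A"] == pytest.approx(32.0)
        assert ss["B"] == pytest.approx(2.0)
        assert ss["A×B"] == pytest.approx(0.0, abs=1e-10)
        assert ss["residual"] == pytest.approx(8.0)
        assert res.mse == pytest.approx(2.0)
        a, b = res.term("A"), res.term("B")
        assert a.f == pytest.approx(16.0)
        assert a.p == pytest.approx(0.016130, abs=1e-5)
        assert b.f == pytest.approx(1.0)
        assert b.p == pytest.approx(0.373901, abs=1e-5)
        assert res.term("A×B").p == pytest.approx(1.0)

    def test_balanced_order_invariance(self, toy_dataset):
        r1 = at.fit_two_way(toy_dataset, "y", ("A", "B"))
        r2 = at.fit_two_way(toy_dataset, "y", ("B", "A"))
        assert r1.term("A").ss == pytest.approx(r2.term("B").ss)
        assert r1.term("B").ss == pytest.approx(r2.term("A").ss)
        assert r1.mse == pytest.approx(r2.mse)

    @pytest.mark.parametrize("order", [("A", "B"), ("B", "A")])
    def test_unbalanced_matches_sequential_oracle(self, toy_dataset, order):
        ds = at.Dataset("A", "B", toy_dataset.records[:-1])  # drop a record
        res = at.fit_two_way(ds, "y", order)
        frame = ds.to_frame()
        f1, f2 = order
        model = ols(f"y ~ C({f1}) * C({f2})", frame).fit()
        table = anova_lm(model, typ=1)
        assert res.term("A").ss == pytest.approx(table.loc[f"C({f1})",
                                                           "sum_sq"])
        assert res.term("B").ss == pytest.approx(table.loc[f"C({f2})",
                                                           "sum_sq"])
        assert res.term("A×B").ss == pytest.approx(
            table.loc[f"C({f1}):C({f2})", "sum_sq"])
        assert res.term("A").p == pytest.approx(table.loc[f"C({f1})",
                                                          "PR(>F)"])

    def test_unbalanced_order_matters(self, toy_dataset):
        rows = toy_dataset.records[:-1] + [("a1", "b1", {"y": 10.0})]
        ds = at.Dataset("A", "B", rows)
        r1 = at.fit_two_way(ds, "y", ("A", "B"))
        r2 = at.fit_two_way(ds, "y", ("B", "A"))
        assert r1.term("A").ss != pytest.approx(r2.term("B").ss)

    def test_one_observation_per_cell_rejected(self):
        ds = at.Dataset("A", "B", [
            ("a1", "b1", {"y": 1.0}), ("a1", "b2", {"y": 2.0}),
            ("a2", "b1", {"y": 3.0}), ("a2", "b2", {"y": 4.0})])
        with pytest.raises(ReplicationError,
                           match="will not be conducted"):
            at.fit_two_way(ds, "y")

    def test_ss_decomposition_property(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            spec = at.GeneratorSpec(
                seed=seed,
                cell_means=tuple(tuple(rng.normal(0, 3, 2)) for _ in range(2)),
                sigma=1.5, n=int(rng.integers(3, 8)))
            ds = at.generate_dataset(spec)
            res = at.fit_two_way(ds, "y")
            y = np.array([r[2]["y"] for r in ds.records])
            total = float(np.sum((y - y.mean()) ** 2))
            assert sum(t.ss for t in res.terms) == pytest.approx(
                total, rel=1e-9)
            for t in res.terms[:3]:
                assert 0.0 <= t.p <= 1.0
                assert t.f >= 0.0


class TestCellMeansFit:
    def test_toy_mse(self, toy_dataset):
        fit = at.fit_cell_means(toy_dataset, "y")
        assert fit.mse == pytest.approx(2.0)
        assert fit.df_error == 4
        assert fit.balanced

    def test_mse_matches_two_way(self, plasma):
        for resp in ("Ser", "Cit", "Lys"):
            two = at.fit_two_way(plasma, resp)
            one = at.fit_cell_means(plasma, resp)
            assert one.mse == pytest.approx(two.mse, rel=1e-12)

    def test_between_treatment_decomposition(self, toy_dataset):
        res = at.fit_two_way(toy_dataset, "y")
        fit = at.fit_cell_means(toy_dataset, "y")
        between = sum(
            c.n * (c.mean - 4.5) ** 2 for c in fit.cells)  # grand mean 4.5
        model_ss = sum(res.term(n).ss for n in ("A", "B", "A×B"))
        assert model_ss == pytest.approx(between)

    def test_replication_error(self):
        ds = at.Dataset("A", "B", [
            ("a1", "b1", {"y": 1.0}), ("a1", "b2", {"y": 2.0}),
            ("a2", "b1", {"y": 3.0}), ("a2", "b2", {"y": 4.0})])
        with pytest.raises(ReplicationError):
            at.fit_cell_means(ds, "y")

    def test_summary_reconstruction_matches_raw_fit(self, plasma):
        raw = at.fit_cell_means(plasma, "Ser")
        rebuilt = at.cell_means_from_summary(raw.cells)
        assert rebuilt.mse == pytest.approx(raw.mse, rel=1e-9)
        assert rebuilt.df_error == raw.df_error


class TestCheckDesign:
    def test_balanced_grid(self, plasma):
        report = at.check_design(plasma)
        assert report.balanced
        assert set(report.n_grid.values()) == {9}

    def test_unbalanced_flag(self, toy_dataset):
        ds = at.Dataset("A", "B", toy_dataset.records[:-1])
        report = at.check_design(ds)
        assert not report.balanced
        assert (report.min_n, report.max_n) == (1, 2)

    def test_missing_value_warning(self):
        ds = at.Dataset("A", "B", [
            ("a1", "b1", {"y": 1.0}), ("a1", "b1", {"y": None}),
            ("a1", "b2", {"y": 2.0}), ("a2", "b1", {"y": 3.0}),
            ("a2", "b2", {"y": 4.0})])
        report = at.check_design(ds)
        assert any("'y'" in w and "missing" in w for w in report.warnings)
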