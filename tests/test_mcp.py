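"""All-pairwise comparison procedures under the cell-means model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

import anovatab as at
from anovatab.anova_core import CellMeansFit, CellSummary
from anovatab.exceptions import InputError, NumericError
from anovatab.mcp import _duncan_gamma, _q_critical
from conftest import fit_from_table, random_balanced_fit, significant_pairs


class TestLSD:
    def test_toy_hand_computation(self, toy_fit_2):
        (res,) = at.lsd_pairwise(toy_fit_2, at.MCPConfig(test="lsd"))
        assert res.statistic == pytest.approx(-2.828427, abs=1e-5)
        assert res.p_raw == pytest.approx(0.047421, abs=1e-5)
        assert res.significant

    def test_equal_means(self):
        cells = (CellSummary("a1", "b1", 5.0, 1.0, 3),
                 CellSummary("a2", "b1", 5.0, 1.0, 3))
        fit = CellMeansFit(cells, mse=3.0, df_error=4, balanced=True)
        (res,) = at.lsd_pairwise(fit, at.MCPConfig(test="lsd"))
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_pair_count(self, plasma):
        fit = at.fit_cell_means(plasma, "Ser")
        assert len(at.lsd_pairwise(fit, at.MCPConfig(test="lsd"))) == 6

    def test_zero_mse_rejected(self):
        cells = (CellSummary("a1", "b1", 1.0, 0.0, 3),
                 CellSummary("a2", "b1", 2.0, 0.0, 3))
        fit = CellMeansFit(cells, mse=0.0, df_error=4, balanced=True)
        with pytest.raises(NumericError):
            at.lsd_pairwise(fit, at.MCPConfig(test="lsd"))


class TestAdjustPvalues:
    def test_examples(self):
        assert at.adjust_pvalues([0.01, 0.5], "none") == [0.01, 0.5]
        assert at.adjust_pvalues([0.01] * 6, "bonferroni")[0] == \
            pytest.approx(0.06)
        assert at.adjust_pvalues([0.01, 0.02, 0.03], "holm") == \
            pytest.approx([0.03, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            at.adjust_pvalues([0.5, 1.2], "holm")

    @pytest.mark.parametrize("method", ["bonferroni", "holm"])
    def test_matches_statsmodels(self, method):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 10)
        _, adj, *_ = multipletests(p, method=method)
        assert at.adjust_pvalues(p, method) == pytest.approx(adj)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8),
           st.integers(0, 20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone(self, p, idx):
        """Raising one raw p never lowers any adjusted p."""
        for method in ("bonferroni", "holm"):
            base = at.adjust_pvalues(p, method)
            bumped = list(p)
            i = idx % len(p)
            bumped[i] = min(1.0, bumped[i] + 0.1)
            higher = at.adjust_pvalues(bumped, method)
            assert all(h >= b - 1e-12 for h, b in zip(higher, base))


class TestTukeyKramer:
    def test_critical_value_balanced_k4_df32(self):
        assert _q_critical(0.05, 4, 32) == pytest.approx(3.8316, abs=2e-4)

    def test_ser_reconstruction(self):
        fit = fit_from_table("Ser")
        res = at.tukey_kramer(fit, at.MCPConfig())
        sig = {p for p in significant_pairs(res)}
        lean_vs_over = {
            frozenset(p) for p in itertools.combinations(fit.treatments, 2)
            if {t[1] for t in p} == {"Lean", "Overweight"}
        }
        assert sig == lean_vs_over

    def test_matches_statsmodels_tukeyhsd(self, plasma):
        fit = at.fit_cell_means(plasma, "Cit")
        res = at.tukey_kramer(fit, at.MCPConfig())
        groups, values = [], []
        for la, lb, r in plasma.records:
            groups.append(f"{la}-{lb}")
            values.append(r["Cit"])
        hsd = pairwise_tukeyhsd(np.array(values), np.array(groups))
        ours = {frozenset(r.pair): r.p_raw for r in res}
        for (g1, g2), p in zip(
            itertools.combinations(hsd.groupsunique, 2), hsd.pvalues
        ):
            key = frozenset(
                (tuple(g.split("-")) for g in (g1, g2))
            )
            assert ours[key] == pytest.approx(p, abs=1e-6)

    def test_tukey_subset_of_raw_lsd(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            fit = random_balanced_fit(rng)
            cfg_t = at.MCPConfig(test="tukey")
            cfg_l = at.MCPConfig(test="lsd")
            assert significant_pairs(at.tukey_kramer(fit, cfg_t)) <= \
                significant_pairs(at.lsd_pairwise(fit, cfg_l))


class TestRangeTests:
    def test_duncan_gamma(self):
        assert _duncan_gamma(2, 0.05) == pytest.approx(0.05)
        assert _duncan_gamma(3, 0.05) == pytest.approx(0.0975)

    def test_snk_adjacent_pair_equals_lsd(self):
        """For adjacent ordered means, q(alpha,2,df) = sqrt(2)*t(alpha/2,df),
        so the SNK decision on an adjacent pair that is actually tested
        coincides with the unadjusted LSD decision."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            fit = random_balanced_fit(rng, spread=2.0)
            snk = {frozenset(r.pair): r for r in
                   at.range_test(fit, at.MCPConfig(test="snk"))}
            lsd = {frozenset(r.pair): r for r in
                   at.lsd_pairwise(fit, at.MCPConfig(test="lsd"))}
            order = sorted(fit.cells, key=lambda c: -c.mean)
            for c1, c2 in zip(order, order[1:]):
                key = frozenset((c1.treatment, c2.treatment))
                if snk[key].significant:  # tested and rejected
                    assert lsd[key].significant

    def test_step_down_protection(self):
        # tiny spread, huge variance: the full range is not significant
        cells = tuple(
            CellSummary(la, lb, m, 10.0, 9) for (la, lb), m in zip(
                [("A", "x"), ("A", "y"), ("B", "x"), ("B", "y")],
                [0.0, 0.1, 0.2, 0.3])
        )
        fit = CellMeansFit(cells, mse=900.0, df_error=32, balanced=True)
        for test in ("snk", "duncan"):
            res = at.range_test(fit, at.MCPConfig(test=test))
            assert not any(r.significant for r in res)
            assert all(r.p_raw is None and r.p_adj is None for r in res)

    def test_range_tests_reject_other_configs(self, toy_fit_2):
        with pytest.raises(InputError):
            at.range_test(toy_fit_2, at.MCPConfig(test="tukey"))


class TestWestfall:
    def test_single_pair_matches_raw(self, toy_fit_2):
        cfg = at.MCPConfig(test="westfall", nsim=100_000, seed=5)
        (res,) = at.westfall_adjust(toy_fit_2, cfg)
        assert res.p_adj == pytest.approx(res.p_raw, abs=0.01)

    def test_adjusted_at_least_raw_and_below_holm(self):
        fit = fit_from_table("Lys")
        cfg = at.MCPConfig(test="westfall", nsim=100_000, seed=17)
        res = at.westfall_adjust(fit, cfg)
        raws = [r.p_raw for r in res]
        holm = at.adjust_pvalues(raws, "holm")
        for r, h in zip(res, holm):
            assert r.p_adj >= r.p_raw
            assert r.p_adj <= h + 0.01

    def test_deterministic_given_seed(self, toy_fit_2):
        cfg = at.MCPConfig(test="westfall", nsim=2_000, seed=42)
        r1 = at.westfall_adjust(toy_fit_2, cfg)
        r2 = at.westfall_adjust(toy_fit_2, cfg)
        assert [r.p_adj for r in r1] == [r.p_adj for r in r2]


class TestConfigAndInvariants:
    def test_adjust_only_with_lsd(self):
        with pytest.raises(InputError):
            at.MCPConfig(test="tukey", adjust="holm")

    def test_nesting_on_shared_fits(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            fit = random_balanced_fit(rng, spread=1.5)
            tukey = significant_pairs(at.pairwise(fit, at.MCPConfig()))
            snk = significant_pairs(
                at.pairwise(fit, at.MCPConfig(test="snk")))
            duncan = significant_pairs(
                at.pairwise(fit, at.MCPConfig(test="duncan")))
            lsd = significant_pairs(
                at.pairwise(fit, at.MCPConfig(test="lsd")))
            holm = significant_pairs(
                at.pairwise(fit, at.MCPConfig(test="lsd", adjust="holm")))
            bonf = significant_pairs(at.pairwise(
                fit, at.MCPConfig(test="lsd", adjust="bonferroni")))
            assert tukey <= snk <= duncan
            assert bonf <= holm <= lsd

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(33)
        fit = random_balanced_fit(rng, spread=2.0)
        relabel = {c.treatment: ("T", f"g{i}")
                   for i, c in enumerate(fit.cells)}
        shuffled = CellMeansFit(
            tuple(CellSummary(*relabel[c.treatment], c.mean, c.sem, c.n)
                  for c in reversed(fit.cells)),
            fit.mse, fit.df_error, fit.balanced)
        for cfg in (at.MCPConfig(), at.MCPConfig(test="snk"),
                    at.MCPConfig(test="lsd")):
            base = {frozenset(r.pair): r.significant
                    for r in at.pairwise(fit, cfg)}
            perm = {frozenset(r.pair): r.significant
                    for r in at.pairwise(shuffled, cfg)}
            mapped = {
                frozenset(relabel[t] for t in key): v
                for key, v in base.items()
            }
            assert mapped == perm
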