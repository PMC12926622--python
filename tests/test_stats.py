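import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sps

from selftouch.stats import (
    _signed_rank_cdf_table,
    correlation,
    fdr_adjust,
    fit_time_regression,
    one_sample_against_zero,
    paired_compare,
    partial_correlation,
    rm_anova,
    rm_anova_oneway,
    rm_anova_twoway,
)


class TestTimeRegression:
    def make_inputs(self, points):
        norm = pd.DataFrame(
            [
                {"participant_id": "P01", "session": "vision", "group": g, "delta_pse": y}
                for g, (x, y) in points.items()
            ]
        )
        fracs = pd.DataFrame(
            [
                {"participant_id": "P01", "session": "vision", "group": g, "mean_fraction": x}
                for g, (x, y) in points.items()
            ]
        )
        return norm, fracs

    def test_collinear_points_recovered_exactly(self):
        pts = {g: (x, -0.002 * x + 0.05) for g, x in [("early25", 20.0), ("mid50", 50.0), ("late75", 75.0), ("target", 100.0)]}
        reg = fit_time_regression(*self.make_inputs(pts))
        assert reg["slope"].iloc[0] == pytest.approx(-0.002, abs=1e-12)
        assert reg["intercept"].iloc[0] == pytest.approx(0.05, abs=1e-10)

    def test_constant_values_give_zero_slope(self):
        pts = {g: (x, -0.12) for g, x in [("early25", 20.0), ("mid50", 50.0), ("late75", 75.0)]}
        reg = fit_time_regression(*self.make_inputs(pts))
        assert reg["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert reg["intercept"].iloc[0] == pytest.approx(-0.12)

    def test_fewer_than_three_points_flagged(self):
        pts = {g: (x, 0.0) for g, x in [("early25", 20.0), ("mid50", 50.0)]}
        reg = fit_time_regression(*self.make_inputs(pts))
        assert not reg["valid"].iloc[0]
        assert np.isnan(reg["slope"].iloc[0])


class TestPairedCompare:
    def test_antisymmetric_normal_differences_give_null_t(self):
        diffs = np.array([-2.0, -1.5, -1.0, -0.5, -0.1, 0.1, 0.5, 1.0, 1.5, 2.0])
        res = paired_compare(diffs, np.zeros_like(diffs))
        assert res.test_used == "paired_t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)
        assert res.effect == pytest.approx(0.0, abs=1e-12)
        assert res.ci95[0] < 0 < res.ci95[1]

    def test_all_negative_non_normal_differences_give_rrb_minus_one(self):
        # heavy outlier forces the Shapiro gate to the Wilcoxon branch
        diffs = -np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 2.0, 2.5, 3.0, 60.0, 61.0, 80.0])
        res = paired_compare(diffs, np.zeros_like(diffs))
        assert res.test_used == "wilcoxon"
        assert res.statistic == 0.0  # T+ = 0
        assert res.effect == pytest.approx(-1.0)
        assert res.ci95[1] < 0

    def test_wilcoxon_p_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        diffs = np.sign(base) * np.abs(base) ** 3  # heavy-tailed: non-normal
        if sps.shapiro(diffs).pvalue >= 0.05:
            diffs[0] *= 50
        res = paired_compare(diffs, np.zeros_like(diffs))
        assert res.test_used == "wilcoxon"
        ref = sps.wilcoxon(diffs, method="exact")
        assert res.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_signed_rank_table_matches_enumeration(self):
        # brute force over all 2^8 sign assignments of ranks 1..8
        n = 8
        pmf = _signed_rank_cdf_table(n)
        counts = np.zeros(n * (n + 1) // 2 + 1)
        for mask in range(2**n):
            t_plus = sum(r for r in range(1, n + 1) if mask & (1 << (r - 1)))
            counts[t_plus] += 1
        assert pmf == pytest.approx(counts / counts.sum())

    def test_rank_biserial_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        a = rng.normal(size=20) ** 3
        b = a + np.abs(rng.normal(size=20)) ** 3  # mostly negative diffs
        res = paired_compare(a, b)
        if res.test_used == "wilcoxon":
            ref = float(pg.wilcoxon(a, b)["RBC"].iloc[0])
            assert res.effect == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_compare(np.ones(10), np.zeros(10))

    def test_one_sample_wrapper(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0.5, 1.0, 25)
        res = one_sample_against_zero(v)
        ref = sps.ttest_1samp(v, 0.0)
        if res.test_used == "paired_t":
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_raw == pytest.approx(ref.pvalue)


class TestFdr:
    def test_hand_computed_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @staticmethod
    def brute_force_bh(p):
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            idx = order[rank_from_top - 1]
            val = min(prev, p[idx] * m / rank_from_top)
            adj[idx] = val
            prev = val
        return np.minimum(adj, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_step_up_definition(self, p):
        assert fdr_adjust(p) == pytest.approx(self.brute_force_bh(p), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=10))
    def test_monotone_and_order_invariant(self, p):
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert fdr_adjust(np.array(p)[perm]) == pytest.approx(adj[perm])


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            Y = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            res = rm_anova_oneway(Y)
            t = sps.ttest_rel(Y[:, 0], Y[:, 1])
            assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
            assert res.p == pytest.approx(t.pvalue, rel=1e-10)
            assert res.epsilon_gg == 1.0

    def test_matches_pingouin_oneway(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        L = np.array([[1, 0, 0, 0], [0.8, 1.5, 0, 0], [0.2, 0.1, 0.5, 0], [0.3, 0.3, 0.2, 2.0]])
        Y = rng.normal(size=(24, 4)) @ L.T + rng.normal(size=(24, 1))
        res = rm_anova_oneway(Y)
        df = (
            pd.DataFrame(Y, columns=list("abcd"))
            .assign(subj=range(24))
            .melt(id_vars="subj", var_name="cond", value_name="y")
        )
        ref = pg.rm_anova(dv="y", within="cond", subject="subj", data=df, correction=True)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        if res.sphericity_violated:
            assert res.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_matches_pingouin_twoway(self):
        import pingouin as pg

        rng = np.random.default_rng(13)
        Y = rng.normal(size=(20, 4, 2)) + rng.normal(size=(20, 1, 1))
        mine = rm_anova_twoway(Y, ("A", "B"))
        rows = [
            {"subj": i, "A": f"a{a}", "B": f"b{b}", "y": Y[i, a, b]}
            for i in range(20)
            for a in range(4)
            for b in range(2)
        ]
        ref = pg.rm_anova(dv="y", within=["A", "B"], subject="subj", data=pd.DataFrame(rows))
        for r, (_, row) in zip(mine, ref.iterrows()):
            assert r.F == pytest.approx(float(row["F"]), rel=1e-8)
            assert r.epsilon_gg == pytest.approx(float(row["eps"]), rel=1e-6)

    def test_effect_grows_p_shrinks(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(12, 4))
        effect = np.array([0.0, 0.1, 0.2, 0.3])
        p_small = rm_anova_oneway(base + 1.0 * effect).p
        p_large = rm_anova_oneway(base + 5.0 * effect).p
        assert p_large < p_small

    def test_long_format_two_way_matches_wide(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(8, 3, 2))
        rows = [
            {"s": i, "f1": f"l{a}", "f2": f"m{b}", "y": Y[i, a, b]}
            for i in range(8)
            for a in range(3)
            for b in range(2)
        ]
        long = rm_anova(pd.DataFrame(rows), dv="y", within=["f1", "f2"], subject="s")
        wide = rm_anova_twoway(Y, ("f1", "f2"))
        for a, b in zip(long, wide):
            assert a.F == pytest.approx(b.F, rel=1e-10)

    def test_missing_cells_rejected(self):
        rows = [
            {"s": i, "c": f"l{j}", "y": float(i + j)} for i in range(5) for j in range(3)
        ][:-1]
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(pd.DataFrame(rows), dv="y", within=["c"], subject="s")


class TestCorrelations:
    def test_orthogonal_covariate_equals_simple_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 40))
        z = rng.normal(size=40)
        # orthogonalize z against centered x and y so it carries no shared variance
        X = np.column_stack([np.ones(40), x - x.mean(), y - y.mean()])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        res = partial_correlation(x, y, z)
        simple = correlation(x, y, "pearson")
        assert res.coefficient == pytest.approx(simple.coefficient, abs=1e-10)

    def test_covariate_driven_y_gives_zero_partial(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=60)
        x = rng.normal(size=60)
        y = 2.0 * z + 1.0
        res = partial_correlation(x, y, z)
        assert res.coefficient == pytest.approx(0.0, abs=1e-7)

    def test_matches_matrix_formula_oracle(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=50)
        x = 0.5 * z + rng.normal(size=50)
        y = -0.3 * z + 0.4 * x + rng.normal(size=50)
        res = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert res.coefficient == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        z = rng.normal(size=30)
        x = 0.5 * z + rng.normal(size=30)
        y = 0.5 * z + rng.normal(size=30)
        res = partial_correlation(x, y, z)
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z")
        assert res.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_constant_covariate_falls_back_with_warning(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 20))
        with pytest.warns(UserWarning):
            res = partial_correlation(x, y, np.ones(20))
        assert res.partialled is None

    def test_kendall_tau_exposed(self):
        x = np.arange(10.0)
        res = correlation(x, x**3, "kendall")
        assert res.coefficient == pytest.approx(1.0)
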