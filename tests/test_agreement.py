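import numpy as np
import pytest

from foveapit.agreement import (
    bootstrap_ci,
    compare_distributions,
    dalign,
    fitting_rmse,
    icc_2_1,
    relative_bias,
)
from foveapit.preprocessing import RegularGrid


def grid(values, spacing=0.02):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    return RegularGrid(ax, ax, values, spacing)


def icc_2_1_oracle(x):
    """Brute-force two-way ANOVA variance-components ICC(2,1)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ssb = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msb, msc, mse = ssb / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)


class TestDalign:
    def test_identical_grids_zero(self):
        g = grid(np.random.default_rng(0).uniform(200, 300, (6, 6)))
        assert dalign(g, g) == 0.0

    def test_constant_offset_equals_offset(self):
        a = grid(np.full((9, 9), 250.0))
        b = grid(np.full((9, 9), 257.3))
        assert dalign(a, b) == pytest.approx(7.3, abs=1e-12)

    def test_equals_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            va, vb = rng.uniform(150, 350, (2, 5, 5))
            ref = sum(
                abs(va[i, j] - vb[i, j]) for i in range(5) for j in range(5)
            ) / 25
            assert abs(dalign(grid(va), grid(vb)) - ref) < 1e-12

    def test_undefined_cells_skipped_pairwise(self):
        va = np.full((4, 4), 250.0)
        vb = np.full((4, 4), 252.0)
        va[0, 0] = np.nan
        vb[3, 3] = np.nan
        assert dalign(grid(va), grid(vb)) == pytest.approx(2.0)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="axes"):
            dalign(grid(np.zeros((4, 4))), grid(np.zeros((5, 5))))


class TestFittingRmse:
    def test_identical_zero_and_constant_difference(self):
        a = np.full((24, 101), 260.0)
        assert fitting_rmse(a, a) == 0.0
        assert fitting_rmse(a, a - 4.2) == pytest.approx(4.2, abs=1e-12)

    def test_equals_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            va, vb = rng.uniform(150, 350, (2, 5, 5))
            ref = np.sqrt(
                sum((va[i, j] - vb[i, j]) ** 2 for i in range(5) for j in range(5)) / 25
            )
            assert abs(fitting_rmse(va, vb) - ref) < 1e-12

    def test_rmse_dominates_dalign(self):
        """RMSE >= Dalign >= 0 for any pair (Jensen's inequality)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            va, vb = rng.uniform(150, 350, (2, 7, 7))
            d = dalign(grid(va), grid(vb))
            r = fitting_rmse(va, vb)
            assert r >= d >= 0


class TestRelativeBias:
    def test_closed_forms_and_sign_convention(self):
        assert relative_bias(250.0, 250.0) == 0.0
        assert relative_bias(275.0, 250.0) == pytest.approx(10.0)
        # underestimation is negative
        assert relative_bias(0.802 * 300.0, 300.0) == pytest.approx(-19.8)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_bias(1.0, 0.0)


class TestICC:
    def test_duplicated_column_gives_one(self):
        col = np.array([1.0, 2.0, 5.0, 3.5])
        assert icc_2_1(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(10, 3, size=(8, 2))
            assert abs(icc_2_1(x) - icc_2_1_oracle(x)) < 1e-10

    def test_column_exchange_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 2))
        assert icc_2_1(x) == pytest.approx(icc_2_1(x[:, ::-1]), abs=1e-12)

    def test_matches_pingouin_reference(self):
        """Independent cross-check against the published ICC2 implementation."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        x = rng.normal(100, 15, size=(12, 2)) + rng.normal(0, 5, size=(12, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "value": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="value")
        # absolute agreement, single rater: labelled ICC2 or ICC(A,1)
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc_2_1(x) == pytest.approx(icc2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.zeros((5, 2)))  # zero variance
        with pytest.raises(ValueError):
            icc_2_1(np.ones((2, 2)))  # too few subjects

    def test_converges_to_variance_component_ratio(self):
        """ICC -> sigma_s^2/(sigma_s^2+sigma_r^2+sigma_e^2) for large n."""
        rng = np.random.default_rng(7)
        n = 2000
        subj = rng.normal(0, 2.0, size=(n, 1))
        # two fixed rater effects +/-0.5: variance component with the
        # k-1 divisor is sum(theta^2)/(k-1) = 0.5
        rater = np.array([[0.5, -0.5]])
        err = rng.normal(0, 1.0, size=(n, 2))
        x = 100 + subj + rater + err
        expected = 4.0 / (4.0 + 0.5 + 1.0)
        assert icc_2_1(x) == pytest.approx(expected, abs=0.02)


class TestBootstrap:
    def test_constant_data_zero_width_ci(self):
        pairs = np.tile([[3.0, 5.0]], (6, 1))
        lo, hi = bootstrap_ci(pairs, statistic=lambda p: p.mean(), n_resamples=200, seed=0)
        assert lo == hi == 4.0

    def test_seed_contract(self):
        rng = np.random.default_rng(8)
        pairs = rng.normal(size=(15, 2))
        a = bootstrap_ci(pairs, n_resamples=500, seed=42)
        b = bootstrap_ci(pairs, n_resamples=500, seed=42)
        c = bootstrap_ci(pairs, n_resamples=500, seed=43)
        assert a == b
        assert a != c

    def test_coverage_on_simulated_icc(self):
        """The 95% CI covers the population ICC in roughly 95% of replicates."""
        rho = 0.8  # population ICC of the simulated two-way model
        sigma_s = np.sqrt(4.0)
        sigma_e = np.sqrt(4.0 * (1 - rho) / rho)
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            subj = rng.normal(0, sigma_s, size=(40, 1))
            x = subj + rng.normal(0, sigma_e, size=(40, 2))
            lo, hi = bootstrap_ci(x, n_resamples=300, seed=int(rng.integers(2**31)))
            hits += lo <= rho <= hi
        assert 0.91 <= hits / n_rep <= 0.99

    def test_mostly_undefined_statistic_rejected(self):
        def bad(p):
            raise ValueError("undefined")

        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(np.ones((5, 2)) * [[1, 2]], statistic=bad, n_resamples=50, seed=0)


class TestCompareDistributions:
    def test_shuffled_copies_not_significant(self):
        rng = np.random.default_rng(10)
        base = rng.normal(10, 2, 60)
        groups = [rng.permutation(base) for _ in range(4)]
        rep = compare_distributions(groups)
        assert rep.kruskal_p > 0.01
        assert not rep.significant

    def test_large_shift_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)  # 10 sd shift
        rep = compare_distributions([a, b], names=["a", "b"])
        assert rep.pairwise[0]["p"] < 1e-6
        assert rep.pairwise[0]["significant"]

    def test_reports_shapiro_and_all_pairs(self):
        rng = np.random.default_rng(12)
        rep = compare_distributions([rng.normal(size=20) for _ in range(3)])
        assert len(rep.pairwise) == 3
        assert len(rep.shapiro_p) == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_distributions([np.arange(5.0)])

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([np.arange(5.0), np.array([1.0])])
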