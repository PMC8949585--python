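import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkir import (
    DegenerateDataError,
    PairedSeries,
    UndefinedStatisticError,
    evaluate_agreement,
    icc_agreement,
    paired_t,
    passing_bablok,
)


def pb_oracle(x, y):
    """Brute-force shifted-median Passing-Bablok slope (independent enumeration)."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = np.inf * np.sign(dy) if dx == 0 else dy / dx
            if s != -1.0:
                slopes.append(s)
    slopes = sorted(slopes)
    N = len(slopes)
    K = sum(s < -1 for s in slopes)
    if N % 2 == 1:
        return slopes[(N + 1) // 2 + K - 1]
    return 0.5 * (slopes[N // 2 + K - 1] + slopes[N // 2 + K])


class TestPassingBablok:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = passing_bablok(x, x)
        assert res.slope == 1.0 and res.intercept == 0.0
        assert res.slope_ci[0] <= 1.0 <= res.slope_ci[1]

    def test_exact_affine_relation(self):
        x = np.array([1.0, 3.0, 4.0, 7.0, 9.0, 12.0])
        res = passing_bablok(x, 2 * x + 3)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n", [5, 8, 10, 13, 15])
    def test_matches_bruteforce_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 400, size=n)
        y = 0.9 * x + 10 + rng.normal(0, 20, size=n)
        res = passing_bablok(x, y)
        assert res.slope == pytest.approx(pb_oracle(x, y), abs=0)
        assert res.intercept == pytest.approx(float(np.median(y - res.slope * x)))
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]

    def test_ten_point_slope_is_median_of_enumerated_slopes(self):
        # positively correlated data: offset K = 0, so the estimator is the
        # plain median of the C(10,2) pairwise slopes
        rng = np.random.default_rng(42)
        x = 100.0 + 20.0 * np.arange(10) + rng.uniform(0, 5, size=10)
        y = x + rng.normal(0, 3, size=10)
        i, j = np.triu_indices(10, k=1)
        enumerated = (y[j] - y[i]) / (x[j] - x[i])
        assert (enumerated > -1).all()
        assert passing_bablok(x, y).slope == pytest.approx(
            float(np.median(enumerated))
        )

    @settings(max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 10),
        shift=st.floats(-50, 50),
        seed=st.integers(0, 100),
    )
    def test_scale_and_shift_equivariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 400, size=12)
        y = 1.1 * x + rng.normal(0, 10, size=12)
        base = passing_bablok(x, y)
        scaled = passing_bablok(scale * x, scale * y)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)
        shifted = passing_bablok(x + shift, y + shift)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert shifted.intercept == pytest.approx(
            base.intercept + shift * (1 - base.slope), rel=1e-9, abs=1e-9
        )

    def test_linearity_pvalue_high_for_linear_data(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(50, 400, size=40)
        y = 1.05 * x - 4 + rng.normal(0, 8, size=40)
        assert passing_bablok(x, y).linearity_pvalue > 0.05

    def test_all_x_identical_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            passing_bablok(np.full(5, 3.0), np.arange(5.0))


class TestICC:
    def test_identical_series_gives_one(self):
        x = np.array([100.0, 150.0, 200.0, 250.0, 300.0, 120.0])
        icc, (lo, hi) = icc_agreement(x, x)
        assert icc == pytest.approx(1.0)
        assert lo <= icc <= hi

    def test_six_by_two_hand_anova_decomposition(self):
        # independent in-test ANOVA arithmetic on a printed 6x2 table
        x = np.array([110.0, 160.0, 140.0, 200.0, 250.0, 190.0])
        y = np.array([120.0, 150.0, 150.0, 190.0, 260.0, 200.0])
        data = np.column_stack([x, y])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            (data - data.mean(axis=1)[:, None] - data.mean(axis=0)[None, :] + grand)
            ** 2
        ).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc, _ = icc_agreement(x, y)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_two_way_random_absolute_single(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = rng.uniform(100, 300, size=20)
        y = x + rng.normal(0, 20, size=20)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(20), 2),
                "raters": np.tile(["m", "e"], 20),
                "scores": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        icc, (lo, hi) = icc_agreement(x, y)
        assert icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds to 2 dp
        assert lo == pytest.approx(ref_lo, abs=0.011)
        assert hi == pytest.approx(ref_hi, abs=0.011)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(100, 300, size=15)
        y = x + rng.normal(0, 10, size=15)
        icc_a, _ = icc_agreement(x, y)
        icc_b, _ = icc_agreement(x + 50, y + 50)
        assert icc_b == pytest.approx(icc_a, rel=1e-12)

    def test_permuted_pairs_have_low_icc(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(100, 300, size=200)
        y = rng.permutation(x)
        icc, _ = icc_agreement(x, y)
        assert abs(icc) < 0.2

    def test_zero_between_pair_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_agreement(np.full(5, 7.0), np.full(5, 7.0))


class TestPairedT:
    def test_identical_vectors(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_five_point_hand_computation(self):
        pre = np.array([100.0, 120.0, 90.0, 150.0, 110.0])
        post = np.array([130.0, 125.0, 100.0, 180.0, 115.0])
        d = post - pre
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, p = paired_t(pre, post)
        assert t == pytest.approx(t_hand)
        assert 0 < p < 1


def test_evaluate_agreement_bundles_all_statistics():
    rng = np.random.default_rng(21)
    x = rng.uniform(100, 300, size=30)
    y = x + rng.normal(0, 10, size=30)
    pairs = PairedSeries(x=x, y=y)
    res = evaluate_agreement(pairs, pre=x[:15], post=x[:15] + rng.normal(5, 10, 15))
    d = res.to_dict()
    assert d["n"] == 30
    assert res.icc_ci[0] <= res.icc <= res.icc_ci[1]
    assert res.pb.slope_ci[0] <= res.pb.slope <= res.pb.slope_ci[1]
    assert res.t_pvalue is not None
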