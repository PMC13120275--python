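"""Statistical indices against worked examples and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import cwqsar as cq


def brute_iic(obs, calc):
    """Independent residual-partition computation of the IIC."""
    obs, calc = np.asarray(obs, float), np.asarray(calc, float)
    r = np.corrcoef(obs, calc)[0, 1]
    d = obs - calc
    neg = [x for x in d if x < 0]
    pos = [x for x in d if x >= 0]
    mae_n = sum(-x for x in neg) / len(neg) if neg else 0.0
    mae_p = sum(pos) / len(pos) if pos else 0.0
    hi = max(mae_n, mae_p)
    return r if hi == 0 else r * min(mae_n, mae_p) / hi


def brute_cii(obs, calc):
    """Leave-one-out loop recomputing every correlation from scratch."""
    obs, calc = np.asarray(obs, float), np.asarray(calc, float)
    full = np.corrcoef(obs, calc)[0, 1] ** 2
    total = 0.0
    for k in range(len(obs)):
        o = np.delete(obs, k)
        c = np.delete(calc, k)
        if np.var(o) == 0 or np.var(c) == 0:
            continue
        rk2 = np.corrcoef(o, c)[0, 1] ** 2
        if rk2 - full > 0:
            total += rk2 - full
    return 1.0 - total


def brute_q2(x, y):
    """Leave-one-out loop of separate least-squares refits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    press = 0.0
    for k in range(len(x)):
        xt, yt = np.delete(x, k), np.delete(y, k)
        c1, c0 = np.polyfit(xt, yt, 1)
        press += (y[k] - (c0 + c1 * x[k])) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


def brute_ccc(obs, calc):
    obs, calc = np.asarray(obs, float), np.asarray(calc, float)
    r = np.corrcoef(obs, calc)[0, 1]
    so, sc = obs.std(), calc.std()
    return 2 * r * so * sc / (so**2 + sc**2 + (obs.mean() - calc.mean()) ** 2)


@st.composite
def paired_series(draw):
    n = draw(st.integers(4, 20))
    elems = st.floats(-10, 10, allow_nan=False, width=32)
    obs = draw(hnp.arrays(np.float64, n, elements=elems))
    calc = draw(hnp.arrays(np.float64, n, elements=elems))
    return obs, calc


class TestIic:
    def test_perfect_fit_equals_r(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert cq.iic(y, y) == pytest.approx(1.0)

    def test_symmetric_residuals_give_r(self):
        obs = [0.0, 1.0, 2.0, 3.0]
        calc = [0.1, 0.9, 2.1, 2.9]  # residuals -0.1, +0.1, -0.1, +0.1
        assert cq.iic(obs, calc) == pytest.approx(cq.pearson_r(obs, calc))

    def test_worked_residual_partition(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        calc = [1.1, 1.9, 3.2, 3.6]
        # residuals [-0.1, +0.1, -0.2, +0.4]: MAE- = 0.15, MAE+ = 0.25
        r = cq.pearson_r(obs, calc)
        assert cq.iic(obs, calc) == pytest.approx(0.6 * r, abs=1e-12)

    def test_one_sided_residuals_score_zero(self):
        obs = [1.0, 2.0, 3.0]
        calc = [0.5, 1.4, 2.3]  # all residuals positive
        assert cq.iic(obs, calc) == 0.0

    def test_zero_variance_undefined(self):
        with pytest.raises(cq.DegenerateError):
            cq.iic([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(paired_series())
    def test_magnitude_never_exceeds_r(self, pair):
        obs, calc = pair
        if np.var(obs) == 0 or np.var(calc) == 0:
            return
        assert abs(cq.iic(obs, calc)) <= abs(cq.pearson_r(obs, calc)) + 1e-12


class TestCii:
    def test_exact_line_gives_one(self):
        obs = [1.0, 2.0, 3.0, 4.0, 5.0]
        calc = [2.0, 4.0, 6.0, 8.0, 10.0]
        assert cq.cii(obs, calc) == pytest.approx(1.0)

    def test_outlier_protest_arithmetic(self):
        obs = [1.0, 2.0, 3.0, 10.0]
        calc = [1.0, 2.0, 3.0, 4.0]
        # deleting the 4th point leaves an exact line: its protest is 1 - R2
        full = cq.r2(obs, calc)
        assert cq.cii(obs, calc) == pytest.approx(
            brute_cii(obs, calc), abs=1e-12
        )
        protests = 1.0 - cq.cii(obs, calc)
        assert protests >= (1.0 - full) - 1e-12

    def test_needs_four_points(self):
        with pytest.raises(cq.InputError):
            cq.cii([1.0, 2.0, 3.0], [1.0, 2.0, 3.1])

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 50))
            obs = rng.normal(size=n)
            calc = obs + rng.normal(scale=0.5, size=n)
            assert cq.cii(obs, calc) == pytest.approx(
                brute_cii(obs, calc), abs=1e-10
            )


class TestCcc:
    def test_identity_is_one(self):
        y = [1.0, 2.0, 5.0]
        assert cq.ccc(y, y) == pytest.approx(1.0)

    def test_location_shift_penalized_monotonically(self):
        obs = np.array([1.0, 2.0, 3.0])
        vals = [cq.ccc(obs, obs + c) for c in (0.0, 0.5, 1.0, 2.0)]
        assert vals[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_perfect_anticorrelation(self):
        assert cq.ccc([-1.0, 1.0], [1.0, -1.0]) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(cq.DegenerateError):
            cq.ccc([1.0, 1.0], [1.0, 2.0])


class TestQ2:
    def test_exact_linear_relation_gives_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 * x - 1.0
        assert cq.q2_loo(x, y) == pytest.approx(1.0)

    def test_q2_never_exceeds_r2(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(scale=0.3, size=15)
        c1, c0 = np.polyfit(x, y, 1)
        r2_fit = 1.0 - np.sum((y - (c0 + c1 * x)) ** 2) / np.sum(
            (y - y.mean()) ** 2
        )
        assert cq.q2_loo(x, y) <= r2_fit + 1e-12

    def test_matches_brute_force_refits(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 1.5 * x + rng.normal(scale=0.2, size=10)
        assert cq.q2_loo(x, y) == pytest.approx(brute_q2(x, y), abs=1e-10)

    def test_zero_endpoint_variance_undefined(self):
        with pytest.raises(cq.DegenerateError):
            cq.q2_loo([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestFRatio:
    @pytest.mark.parametrize(
        "r2_val, n, expected",
        [(0.719, 210, 532), (0.5556, 210, 260), (0.734, 210, 574)],
    )
    def test_reproduces_published_values(self, r2_val, n, expected):
        assert round(cq.f_ratio(r2_val, n)) == expected

    def test_null_model_is_zero(self):
        assert cq.f_ratio(0.0, 100) == 0.0

    def test_perfect_fit_diverges(self):
        with pytest.raises(cq.DegenerateError):
            cq.f_ratio(1.0, 100)

    def test_strictly_increasing_in_r2_and_n(self):
        assert cq.f_ratio(0.6, 50) > cq.f_ratio(0.5, 50)
        assert cq.f_ratio(0.5, 60) > cq.f_ratio(0.5, 50)


class TestRmseR2:
    def test_identical_series(self):
        y = [1.0, 2.0, 3.0]
        assert cq.rmse(y, y) == 0.0
        assert cq.r2(y, y) == pytest.approx(1.0)

    def test_rmse_arithmetic(self):
        assert cq.rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))

    @given(
        a=st.floats(0.1, 5.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_r2_invariant_under_affine_calculated(self, a, b):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        calc = np.array([1.2, 1.9, 4.5, 7.0])
        assert cq.r2(obs, a * calc + b) == pytest.approx(
            cq.r2(obs, calc), abs=1e-9
        )


def test_evaluate_set_has_all_columns(benchmark_tf1):
    report = benchmark_tf1.metrics["calibration"]
    assert report.COLUMNS == ("n", "r2", "ccc", "iic", "cii", "q2", "rmse", "f")
    for col in report.COLUMNS:
        assert getattr(report, col) is not None
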