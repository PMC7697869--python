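import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sdistep import (
    DataError,
    InsufficientDataError,
    PairedMeasurements,
    StepSeries,
    agreement_report,
    bland_altman,
    icc_2_1,
    passing_bablok,
    report_frame,
)


def pb_bruteforce(x, y, alpha=0.05):
    """Exhaustive Passing-Bablok oracle: explicit loops, no vectorisation."""
    n = len(x)
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0:
                continue
            s = dy / dx
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    big_n = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)

    def at(rank):  # 1-based, clipped
        return slopes[min(max(rank - 1, 0), big_n - 1)]

    if big_n % 2:
        slope = at((big_n + 1) // 2 + k)
    else:
        slope = 0.5 * (at(big_n // 2 + k) + at(big_n // 2 + 1 + k))
    w = stats.norm.ppf(1 - alpha / 2) * math.sqrt(n * (n - 1) * (2 * n + 5) / 18)
    m1 = round((big_n - w) / 2)
    m2 = big_n - m1 + 1
    lo, hi = at(m1 + k), at(m2 + k)
    intercept = float(np.median([yi - slope * xi for xi, yi in zip(x, y)]))
    int_lo = float(np.median([yi - hi * xi for xi, yi in zip(x, y)]))
    int_hi = float(np.median([yi - lo * xi for xi, yi in zip(x, y)]))
    return slope, (lo, hi), intercept, (int_lo, int_hi)


def icc_anova_oracle(x, y):
    """ICC(2,1) from explicitly assembled two-way ANOVA mean squares."""
    mat = np.column_stack([x, y])
    n, k = mat.shape
    grand = mat.mean()
    msr = k * ((mat.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((mat.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((mat - grand) ** 2).sum() - (n - 1) / k * 0  # assembled below
    ssr = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    sst = ((mat - grand) ** 2).sum()
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestPassingBablok:
    def test_identity_data(self):
        x = np.linspace(0.4, 0.9, 20)
        res = passing_bablok(PairedMeasurements(x=x, y=x.copy()))
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope_ci[0] <= 1.0 <= res.slope_ci[1]
        assert res.intercept_ci[0] <= 0.0 <= res.intercept_ci[1]

    def test_exact_affine_relation(self):
        x = np.linspace(1.0, 3.0, 15)
        res = passing_bablok(PairedMeasurements(x=x, y=2 * x + 1))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 61))
        x = rng.uniform(0.3, 1.2, n)
        y = 0.97 * x + 0.02 + rng.normal(0, 0.05, n)
        res = passing_bablok(PairedMeasurements(x=x, y=y))
        slope, ci, intercept, int_ci = pb_bruteforce(list(x), list(y))
        assert res.slope == pytest.approx(slope, abs=0)
        assert res.slope_ci == pytest.approx(ci, abs=0)
        assert res.intercept == pytest.approx(intercept, abs=0)
        assert res.intercept_ci == pytest.approx(int_ci, abs=0)

    def test_small_n_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(InsufficientDataError):
            passing_bablok(PairedMeasurements(x=x, y=x))

    def test_constant_x_rejected(self):
        x = np.full(12, 2.0)
        with pytest.raises(DataError):
            passing_bablok(PairedMeasurements(x=x, y=np.arange(12.0)))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(c=st.floats(0.1, 50), seed=st.integers(0, 10_000))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 2, 15)
        y = x + rng.normal(0, 0.1, 15)
        base = passing_bablok(PairedMeasurements(x=x, y=y))
        scaled = passing_bablok(PairedMeasurements(x=c * x, y=c * y))
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(c * base.intercept, rel=1e-9, abs=1e-12)

    def test_symmetry_under_axis_swap(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(1, 2, 25)
        y = 1.3 * x + rng.normal(0, 0.05, 25)
        forward = passing_bablok(PairedMeasurements(x=x, y=y))
        backward = passing_bablok(PairedMeasurements(x=y, y=x))
        assert backward.slope == pytest.approx(1.0 / forward.slope, rel=0.02)


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        res = icc_2_1(PairedMeasurements(x=x, y=x.copy()))
        assert res.icc == pytest.approx(1.0)

    def test_systematic_offset_penalised(self):
        x = np.array([0.50, 0.55, 0.60, 0.65, 0.70, 0.75])
        shifted = icc_2_1(PairedMeasurements(x=x, y=x + 0.2))
        # consistency ICC of the same data would be 1; absolute agreement
        # must be much lower because the offset is large vs subject spread
        assert shifted.icc < 0.5

    def test_matches_anova_oracle_to_1e10(self):
        x = np.array([9.0, 10.5, 12.0, 6.5, 13.0, 10.0])
        y = np.array([9.5, 10.0, 12.5, 7.0, 12.0, 9.0])
        res = icc_2_1(PairedMeasurements(x=x, y=y))
        assert abs(res.icc - icc_anova_oracle(x, y)) < 1e-10

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(1)
        x = rng.uniform(0.4, 0.9, 40)
        y = x + rng.normal(0, 0.03, 40)
        res = icc_2_1(PairedMeasurements(x=x, y=y))
        df = pd.DataFrame(
            {
                "target": np.tile(np.arange(40), 2),
                "rater": ["ref"] * 40 + ["test"] * 40,
                "score": np.concatenate([x, y]),
            }
        )
        tab = pingouin.intraclass_corr(
            df, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        row = tab.loc["ICC(A,1)"] if "ICC(A,1)" in tab.index else tab.loc["ICC2"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        ci_col = "CI95" if "CI95" in tab.columns else "CI95%"
        lo, hi = row[ci_col]
        # pingouin rounds the CI bounds to two decimals
        assert res.ci[0] == pytest.approx(lo, abs=6e-3)
        assert res.ci[1] == pytest.approx(hi, abs=6e-3)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(c=st.floats(-100, 100), seed=st.integers(0, 10_000))
    def test_invariant_to_common_shift(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 12)
        y = x + rng.normal(0, 0.1, 12)
        a = icc_2_1(PairedMeasurements(x=x, y=y))
        b = icc_2_1(PairedMeasurements(x=x + c, y=y + c))
        assert b.icc == pytest.approx(a.icc, rel=1e-9, abs=1e-9)

    def test_degenerate_data_rejected(self):
        x = np.full(6, 1.0)
        with pytest.raises(DataError):
            icc_2_1(PairedMeasurements(x=x, y=x.copy()))


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(PairedMeasurements(x=x, y=x.copy()))
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)

    def test_plus_minus_one_differences(self):
        x = np.array([2.0, 2.0, 4.0, 4.0])
        y = np.array([1.0, 3.0, 3.0, 5.0])
        res = bland_altman(PairedMeasurements(x=x, y=y))
        assert res.bias == pytest.approx(0.0)
        sd = np.std([1, -1, 1, -1], ddof=1)
        assert res.loa[1] == pytest.approx(1.96 * sd)
        assert res.loa[0] == pytest.approx(-1.96 * sd)

    def test_loa_centred_on_bias(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 1, 50)
        y = x + rng.normal(0.5, 0.2, 50)
        res = bland_altman(PairedMeasurements(x=x, y=y))
        assert (res.loa[0] + res.loa[1]) / 2 == pytest.approx(res.bias, abs=1e-9)

    def test_sign_convention_reference_minus_test(self):
        """A test method reading uniformly high gives a negative bias."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(PairedMeasurements(x=x, y=x + 0.3))
        assert res.bias == pytest.approx(-0.3)

    def test_percent_mode(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([0.9, 2.2, 4.0])
        res = bland_altman(PairedMeasurements(x=x, y=y), mode="percent")
        d0 = 100 * (1.0 - 0.9) / 0.95
        assert res.points["difference"].iloc[0] == pytest.approx(d0)

    def test_nominal_coverage_of_loa(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.65, 0.1, 500)
        y = x + rng.normal(0, 0.02, 500)
        res = bland_altman(PairedMeasurements(x=x, y=y))
        d = res.points["difference"]
        frac = np.mean((d >= res.loa[0]) & (d <= res.loa[1]))
        assert 0.93 <= frac <= 0.97


class TestAgreementReport:
    def _series(self, lengths, times):
        strikes = 1.0 + 0.6 * np.arange(len(lengths))
        sides = ["left" if i % 2 == 0 else "right" for i in range(len(lengths))]
        return StepSeries.from_records(
            list(zip(sides, strikes, times, lengths))
        )

    def test_identical_series_perfect_agreement(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(0.5, 0.8, 30)
        times = rng.uniform(0.5, 0.7, 30)
        s = self._series(lengths, times)
        reports = agreement_report(s, s)
        for rep in reports.values():
            assert rep.pb.slope == pytest.approx(1.0)
            assert rep.pb.intercept == pytest.approx(0.0, abs=1e-12)
            assert rep.icc.icc == pytest.approx(1.0)
            assert rep.ba.bias == pytest.approx(0.0, abs=1e-15)

    def test_report_frame_roundtrips_csv(self, tmp_path):
        rng = np.random.default_rng(1)
        lengths = rng.uniform(0.5, 0.8, 30)
        times = rng.uniform(0.5, 0.7, 30)
        ref = self._series(lengths, times)
        mes = self._series(lengths + rng.normal(0, 0.01, 30),
                           times + rng.normal(0, 0.005, 30))
        frame = report_frame(agreement_report(mes, ref))
        path = tmp_path / "report.csv"
        frame.to_csv(path, index=False)
        import pandas as pd
        back = pd.read_csv(path)
        assert list(back.columns) == list(frame.columns)
        np.testing.assert_allclose(
            back["icc_2_1"].to_numpy(), frame["icc_2_1"].to_numpy(), rtol=1e-12
        )
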