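"""Method-comparison statistics: Passing-Bablok regression, ICC(2,1),
Bland-Altman limits of agreement.

These are the statistics conventionally reported when validating a wearable
gait system against a laboratory reference (pressure walkway or
optoelectronic capture): a nonparametric regression that is robust to
outliers and error distribution, a single-measure absolute-agreement
intraclass correlation from the two-way ANOVA decomposition, and the
bias +/- 1.96 SD interval of paired differences.

Sign convention throughout: differences are reference minus test, so a test
method that reads uniformly high produces a *negative* Bland-Altman bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, InsufficientDataError, StepSeries
from .kinematics import pair_steps

logger = logging.getLogger(__name__)


@dataclass
class PairedMeasurements:
    """Paired reference (x) and test (y) values for one gait parameter."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise DataError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError("paired measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class PBResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]


@dataclass
class BAResult:
    bias: float
    loa: tuple[float, float]
    sd: float
    mode: str
    points: pd.DataFrame = field(repr=False, default=None)


def passing_bablok(data: PairedMeasurements, alpha: float = 0.05) -> PBResult:
    """Passing-Bablok regression of y on x.

    The slope is the shifted median of all pairwise slopes
    S_ij = (y_j - y_i)/(x_j - x_i), i < j, excluding slopes equal to -1,
    with shift K = #{S_ij < -1} (this makes the estimate invariant to
    swapping the roles of x and y up to inversion).  Confidence bounds come
    from the rank statistics M1 = round((N - w)/2), M2 = N - M1 + 1 with
    w = z_(1-alpha/2) * sqrt(n(n-1)(2n+5)/18).  The intercept is
    median(y - slope*x); its CI uses the opposite slope bounds.
    """
    x, y = data.x, data.y
    n = data.n
    if n < 10:
        raise InsufficientDataError(f"Passing-Bablok CIs need n >= 10, got {n}")
    if np.all(x == x[0]):
        raise DataError("x values are all equal; slope undefined")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    defined = dx != 0
    n_pairs = len(dx)
    n_undefined = int(n_pairs - defined.sum())
    if n_undefined == n_pairs:
        raise DataError("all pairwise slopes undefined (x ties everywhere)")
    if n_undefined > 0.10 * n_pairs:
        logger.warning(
            "%d of %d pairwise slopes undefined (x ties); pairs skipped",
            n_undefined, n_pairs,
        )
    s = dy[defined] / dx[defined]
    s = s[s != -1.0]
    if s.size == 0:
        raise DataError("no valid pairwise slopes remain")
    s.sort()
    big_n = s.size
    k_off = int(np.sum(s < -1.0))

    def _shifted_median(offset: int) -> float:
        # median of s with ranks shifted by `offset` (1-based convention)
        if big_n % 2:
            idx = (big_n + 1) // 2 + offset
            return float(s[np.clip(idx - 1, 0, big_n - 1)])
        i1 = big_n // 2 + offset
        i2 = big_n // 2 + 1 + offset
        return 0.5 * (
            float(s[np.clip(i1 - 1, 0, big_n - 1)])
            + float(s[np.clip(i2 - 1, 0, big_n - 1)])
        )

    slope = _shifted_median(k_off)
    z = stats.norm.ppf(1 - alpha / 2)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo = float(s[np.clip(m1 + k_off - 1, 0, big_n - 1)])
    hi = float(s[np.clip(m2 + k_off - 1, 0, big_n - 1)])

    intercept = float(np.median(y - slope * x))
    int_lo = float(np.median(y - hi * x))
    int_hi = float(np.median(y - lo * x))
    return PBResult(
        slope=slope,
        slope_ci=(lo, hi),
        intercept=intercept,
        intercept_ci=(int_lo, int_hi),
    )


def icc_2_1(data: PairedMeasurements, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): single-measure, absolute-agreement, two-way model.

    Treats the reference and test systems as k = 2 raters scoring n
    subjects (steps).  From the two-way ANOVA mean squares (MSR between
    subjects, MSC between raters, MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    The 95% CI is the McGraw-Wong F-based interval for ICC(A,1), using a
    Satterthwaite-approximated denominator df.
    """
    n, k = data.n, 2
    if n < 3:
        raise InsufficientDataError(f"ICC needs n >= 3 pairs, got {n}")
    mat = np.column_stack([data.x, data.y])
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((mat - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0:
        raise DataError("zero between-subject variance; ICC undefined")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(icc=float(icc), ci=(float(lower), float(upper)))


def bland_altman(data: PairedMeasurements, mode: str = "absolute") -> BAResult:
    """Bland-Altman bias and 95% limits of agreement.

    Differences are reference - test.  In percent mode each difference is
    expressed relative to the pair mean (pairs with zero mean are skipped
    with a warning).  LoA = bias +/- 1.96 * SD (sample SD, n-1).
    """
    if mode not in ("absolute", "percent"):
        raise DataError(f"unknown Bland-Altman mode {mode!r}")
    if data.n < 3:
        raise InsufficientDataError(f"Bland-Altman needs n >= 3, got {data.n}")
    d = data.x - data.y
    m = 0.5 * (data.x + data.y)
    if mode == "percent":
        keep = m != 0
        if not keep.all():
            logger.warning(
                "skipping %d pair(s) with zero mean in percent mode",
                int((~keep).sum()),
            )
        d = 100.0 * d[keep] / m[keep]
        m = m[keep]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    points = pd.DataFrame({"mean": m, "difference": d})
    return BAResult(bias=bias, loa=loa, sd=sd, mode=mode, points=points)


@dataclass
class AgreementReport:
    """Machine-readable twin of a validation table row set: per parameter,
    descriptive means/SDs of both systems plus PB, ICC and BA results."""

    parameter: str
    units: str
    n: int
    reference_mean: float
    reference_sd: float
    test_mean: float
    test_sd: float
    pb: PBResult
    icc: ICCResult
    ba: BAResult

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "units": self.units,
            "n": self.n,
            "reference_mean": self.reference_mean,
            "reference_sd": self.reference_sd,
            "test_mean": self.test_mean,
            "test_sd": self.test_sd,
            "pb_slope": self.pb.slope,
            "pb_slope_lo": self.pb.slope_ci[0],
            "pb_slope_hi": self.pb.slope_ci[1],
            "pb_intercept": self.pb.intercept,
            "pb_intercept_lo": self.pb.intercept_ci[0],
            "pb_intercept_hi": self.pb.intercept_ci[1],
            "icc_2_1": self.icc.icc,
            "icc_lo": self.icc.ci[0],
            "icc_hi": self.icc.ci[1],
            "ba_bias": self.ba.bias,
            "ba_loa_lo": self.ba.loa[0],
            "ba_loa_hi": self.ba.loa[1],
        }


_PARAM_UNITS = {"step_length": "m", "step_time": "s"}


def agreement_report(
    measured: StepSeries,
    reference: StepSeries,
    ba_mode: str = "absolute",
    pairing_tol: float = 0.25,
) -> dict[str, AgreementReport]:
    """Full agreement battery for step length and step time.

    Pairs the two series by strike order (see
    :func:`sdistep.kinematics.pair_steps`) and computes, per parameter, the
    descriptive statistics of both systems, Passing-Bablok regression (test
    on reference), ICC(2,1) and Bland-Altman bias/LoA.
    """
    pairs = pair_steps(measured, reference, pairing_tol)
    out: dict[str, AgreementReport] = {}
    for name, units in _PARAM_UNITS.items():
        x = pairs[f"{name}_reference"].to_numpy(float)
        y = pairs[f"{name}_measured"].to_numpy(float)
        data = PairedMeasurements(x=x, y=y, label=f"{name} ({units})")
        out[name] = AgreementReport(
            parameter=name,
            units=units,
            n=data.n,
            reference_mean=float(x.mean()),
            reference_sd=float(x.std(ddof=1)),
            test_mean=float(y.mean()),
            test_sd=float(y.std(ddof=1)),
            pb=passing_bablok(data),
            icc=icc_2_1(data),
            ba=bland_altman(data, mode=ba_mode),
        )
    return out


def report_frame(reports: dict[str, AgreementReport]) -> pd.DataFrame:
    """Stack agreement reports into one DataFrame (CSV-friendly)."""
    return pd.DataFrame([r.to_row() for r in reports.values()])
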