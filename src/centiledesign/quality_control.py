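"""Measurement quality-control battery for anthropometry and ultrasound.

Four standard checks on measurement behaviour:

* **Terminal-digit preference** — observers who round to favoured final
  digits produce heaped distributions; a chi-square test against a
  uniform distribution of the 10 terminal digits (df = 9) quantifies it.
* **Technical error of measurement (TEM)** — the classical anthropometry
  error scale over duplicate pairs, TEM = sqrt(sum d_i^2 / 2n), with the
  relative TEM expressed as a percentage of the grand mean.
* **Bland-Altman agreement** — mean difference (bias) and 95% limits of
  agreement, bias +/- 1.96 SD(differences), between two observers or
  methods.
* **CUSUM monitoring** — one-sided cumulative sums
  S_t = max(0, S_{t-1} + e_t - k) with an alarm when S_t > h, applied to
  standardised measurement errors to detect drift in an observer's
  performance (learning-curve monitoring); conventional defaults
  k = 0.5, h = 4 on the standardised scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import DomainError, SchemaError

__all__ = [
    "DigitPreferenceReport",
    "TEMResult",
    "AgreementResult",
    "CusumPath",
    "digit_preference",
    "technical_error_of_measurement",
    "bland_altman",
    "bland_altman_repeated",
    "cusum_monitor",
]


@dataclass(frozen=True)
class DigitPreferenceReport:
    counts: tuple[int, ...]  # terminal digits 0..9
    proportions: tuple[float, ...]
    chi_square: float
    p_value: float
    df: int
    n: int
    expected_per_digit: float
    flagged_digits: tuple[int, ...]
    low_power: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"digit": range(10), "count": self.counts, "proportion": self.proportions}
        )


def digit_preference(values, resolution: float = 1.0) -> DigitPreferenceReport:
    """Chi-square test of terminal-digit uniformity.

    Values are quantised to the declared instrument ``resolution`` first;
    the terminal digit is the final digit of the value expressed in
    resolution units (e.g. whole millimetres at resolution 1).  Digits
    whose proportion deviates from 0.10 by more than three binomial
    standard errors are flagged.  With n < 50 the report is computed but
    marked low-power.
    """
    if resolution <= 0:
        raise DomainError(f"resolution must be positive, got {resolution}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("no values supplied")
    digits = (np.round(v / resolution).astype(np.int64) % 10).astype(int)
    counts = np.bincount(digits, minlength=10)
    n = int(counts.sum())
    expected = n / 10.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=9))
    props = counts / n
    se = np.sqrt(0.1 * 0.9 / n)
    flagged = tuple(int(d) for d in np.nonzero(np.abs(props - 0.1) > 3 * se)[0])
    return DigitPreferenceReport(
        counts=tuple(int(c) for c in counts),
        proportions=tuple(float(x) for x in props),
        chi_square=chi2,
        p_value=p_value,
        df=9,
        n=n,
        expected_per_digit=expected,
        flagged_digits=flagged,
        low_power=n < 50,
    )


@dataclass(frozen=True)
class TEMResult:
    tem: float
    relative_tem_percent: float
    n_pairs: int


def technical_error_of_measurement(first, second) -> TEMResult:
    """TEM = sqrt(sum d^2 / 2n) over duplicate measurement pairs."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError("duplicate pair lists must be 1-d and of equal length")
    if a.size < 2:
        raise DomainError(f"need >= 2 pairs, got {a.size}")
    d = a - b
    tem = float(np.sqrt((d ** 2).sum() / (2.0 * a.size)))
    grand_mean = float(np.concatenate([a, b]).mean())
    return TEMResult(
        tem=tem,
        relative_tem_percent=100.0 * tem / grand_mean,
        n_pairs=int(a.size),
    )


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    degenerate: bool  # constant differences: limits collapse to the bias
    plot_data: pd.DataFrame = field(repr=False, default=None)  # mean vs difference


def bland_altman(first, second) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError("paired lists must be 1-d and of equal length")
    if a.size < 3:
        raise DomainError(f"need >= 3 pairs, got {a.size}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    plot = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=int(a.size),
        degenerate=sd == 0.0,
        plot_data=plot,
    )


def bland_altman_repeated(first_replicates, second_replicates) -> AgreementResult:
    """Limits of agreement for *single* measurements from replicated data.

    Sensitivity analysis only, off the default QC path: compares
    subject-level replicate means but widens the difference variance by
    the within-subject replicate variances, Var(d_single) =
    Var(d_means) + (1 - 1/m_A) s_A^2 + (1 - 1/m_B) s_B^2, the classical
    repeated-measures correction.  Experience with growth data is that
    this correction overestimates variability, so it is reported for
    comparison and never applied to published charts.
    """
    a = np.asarray(first_replicates, dtype=float)
    b = np.asarray(second_replicates, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise SchemaError(
            "expected 2-d arrays (subjects x replicates) with equal subject counts"
        )
    if a.shape[0] < 3:
        raise DomainError(f"need >= 3 subjects, got {a.shape[0]}")
    ma, mb = a.shape[1], b.shape[1]
    d_means = a.mean(axis=1) - b.mean(axis=1)
    bias = float(d_means.mean())
    s2a = float(a.var(axis=1, ddof=1).mean()) if ma > 1 else 0.0
    s2b = float(b.var(axis=1, ddof=1).mean()) if mb > 1 else 0.0
    var_single = float(d_means.var(ddof=1)) + (1 - 1 / ma) * s2a + (1 - 1 / mb) * s2b
    sd = float(np.sqrt(var_single))
    plot = pd.DataFrame(
        {"mean": (a.mean(axis=1) + b.mean(axis=1)) / 2.0, "difference": d_means}
    )
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=int(a.shape[0]),
        degenerate=sd == 0.0,
        plot_data=plot,
    )


@dataclass(frozen=True)
class CusumPath:
    """Two one-sided CUSUM paths with reset-at-zero recursion.

    ``upper[t] = max(0, upper[t-1] + e_t - k)`` alarms when it exceeds h;
    ``lower`` runs on the negated errors and catches downward drift.
    Alarm indices are 0-based positions into the error sequence (so the
    t-th observation, 1-based, is index t - 1).
    """

    upper: np.ndarray
    lower: np.ndarray
    upper_alarms: tuple[int, ...]
    lower_alarms: tuple[int, ...]
    k: float
    h: float

    @property
    def first_alarm(self) -> int | None:
        alarms = self.upper_alarms + self.lower_alarms
        return min(alarms) if alarms else None


def cusum_monitor(errors, k: float = 0.5, h: float = 4.0) -> CusumPath:
    """One-sided upper and lower CUSUMs of per-measurement errors.

    ``errors`` should be deviations from target, preferably standardised
    (z-score scale), in measurement order; ``k`` is the allowance and
    ``h`` the decision limit in the same units.
    """
    if k <= 0 or h <= 0:
        raise DomainError(f"k and h must be positive, got k={k}, h={h}")
    e = np.asarray(errors, dtype=float)
    upper = np.empty(e.size)
    lower = np.empty(e.size)
    su = sl = 0.0
    for i, x in enumerate(e):
        su = max(0.0, su + x - k)
        sl = max(0.0, sl - x - k)
        upper[i] = su
        lower[i] = sl
    return CusumPath(
        upper=upper,
        lower=lower,
        upper_alarms=tuple(int(i) for i in np.nonzero(upper > h)[0]),
        lower_alarms=tuple(int(i) for i in np.nonzero(lower > h)[0]),
        k=k,
        h=h,
    )
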