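"""Domain types and the normal-theory centile engine for growth-chart studies.

Fetal and neonatal size charts summarise a measurement (biometry in mm,
weight in g) conditional on gestational age (GA).  For conditionally
normal data the whole chart is determined by two smooth curves, the mean
mu(GA) and the standard deviation sigma(GA): the p-th centile is
mu(GA) + z_p * sigma(GA) and the z-score of an observation y is
(y - mu(GA)) / sigma(GA).  This module provides:

* the domain types (:class:`GestationalAge`, :class:`MeasurementRecord`,
  :class:`GrowthCurveModel`, :class:`CentileSpec`, :class:`DatingRecord`);
* the centile/z-score engine (:func:`normal_deviate`,
  :func:`centile_value`, :func:`z_score`, :func:`reference_interval`);
* a polynomial mean/SD-versus-GA fitter (:func:`fit_growth_curve`) with
  goodness-of-fit diagnostics (:func:`goodness_of_fit`);
* reconciliation of LMP and ultrasound pregnancy dating
  (:func:`reconcile_gestational_age`).

GA is stored internally in integer days and exposed in decimal weeks;
"completed weeks" means floor(days / 7).  Polynomial bases are centred at
28 weeks during fitting to reduce collinearity, but every stored and
exported model uses raw-week coefficients so published equations apply
directly to GA in weeks.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import stats

__all__ = [
    "CentileDesignError",
    "DomainError",
    "ExtrapolationError",
    "FitError",
    "SchemaError",
    "MissingDatingError",
    "GestationalAge",
    "MeasurementRecord",
    "GrowthCurveModel",
    "CentileSpec",
    "DatingRecord",
    "DatingSource",
    "DatingResult",
    "MEASUREMENT_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "read_measurements",
    "write_measurements",
    "normal_deviate",
    "centile_value",
    "z_score",
    "reference_interval",
    "fit_growth_curve",
    "fit_growth_curve_xy",
    "goodness_of_fit",
    "GoodnessOfFit",
    "reconcile_gestational_age",
]

#: Fitting/basis centre, in weeks.  28 weeks sits near the middle of the
#: usual fetal scanning window (14-42 weeks).
BASIS_CENTER_WEEKS = 28.0

#: Upper bound on gestational age considered in this package (43 weeks).
MAX_GA_DAYS = 301

#: Column order of the canonical long-format measurement CSV.
MEASUREMENT_COLUMNS = [
    "subject_id",
    "site_id",
    "observer_id",
    "ga_days",
    "visit",
    "replicate",
    "value",
    "unit",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class CentileDesignError(Exception):
    """Base class for all package errors."""


class DomainError(CentileDesignError, ValueError):
    """An argument lies outside its mathematical domain."""


class ExtrapolationError(CentileDesignError, ValueError):
    """A GA outside the model's fitted domain was requested."""


class FitError(CentileDesignError, ValueError):
    """A growth-curve fit failed or produced an invalid model."""


class SchemaError(CentileDesignError, ValueError):
    """Tabular input does not match the expected measurement schema."""


class MissingDatingError(CentileDesignError, ValueError):
    """A dating record lacks one of the two GA estimates."""


# ---------------------------------------------------------------------------
# Gestational age
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GestationalAge:
    """Gestational age stored in integer days.

    Parameters
    ----------
    days:
        Completed days of gestation, ``0 <= days <= 301`` (43 weeks).
    """

    days: int

    def __post_init__(self) -> None:
        if not isinstance(self.days, (int, np.integer)) or isinstance(self.days, bool):
            raise DomainError(f"GA days must be an integer, got {self.days!r}")
        if not 0 <= self.days <= MAX_GA_DAYS:
            raise DomainError(
                f"GA days must lie in [0, {MAX_GA_DAYS}], got {self.days}"
            )
        object.__setattr__(self, "days", int(self.days))

    @property
    def weeks(self) -> float:
        """GA in decimal weeks (days / 7)."""
        return self.days / 7.0

    @property
    def completed_weeks(self) -> int:
        """Completed weeks, floor(days / 7) — the clinical binning unit."""
        return self.days // 7

    @classmethod
    def from_weeks(cls, weeks: float) -> "GestationalAge":
        """Build from decimal weeks, rounding to the nearest day."""
        return cls(int(round(weeks * 7.0)))

    def __str__(self) -> str:  # e.g. "28+3"
        return f"{self.days // 7}+{self.days % 7}"


def _ga_weeks(ga: "GestationalAge | float | int") -> float:
    """Accept a GestationalAge or a plain number of decimal weeks."""
    if isinstance(ga, GestationalAge):
        return ga.weeks
    return float(ga)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementRecord:
    """One replicate measurement of one subject at one visit."""

    subject_id: str
    site_id: str
    observer_id: str
    ga: GestationalAge
    visit_index: int
    replicate_index: int
    value: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DomainError(
                f"measurement value must be positive, got {self.value!r} "
                f"(subject {self.subject_id})"
            )
        if self.visit_index < 1 or self.replicate_index < 1:
            raise DomainError("visit_index and replicate_index are 1-based (>= 1)")


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Convert records to the canonical long-format DataFrame."""
    rows = [
        (
            r.subject_id,
            r.site_id,
            r.observer_id,
            r.ga.days,
            r.visit_index,
            r.replicate_index,
            r.value,
            r.unit,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    """Convert a canonical DataFrame back to records."""
    _require_schema(df)
    return [
        MeasurementRecord(
            subject_id=str(row.subject_id),
            site_id=str(row.site_id),
            observer_id=str(row.observer_id),
            ga=GestationalAge(int(row.ga_days)),
            visit_index=int(row.visit),
            replicate_index=int(row.replicate),
            value=float(row.value),
            unit=str(row.unit),
        )
        for row in df.itertuples(index=False)
    ]


def _require_schema(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"measurement table is missing columns {missing}; "
            f"expected {MEASUREMENT_COLUMNS}"
        )


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV (header required) and validate its schema."""
    df = pd.read_csv(path)
    _require_schema(df)
    if (df["value"] <= 0).any():
        bad = df.loc[df["value"] <= 0, "subject_id"].unique()[:5]
        raise SchemaError(f"non-positive measurement values for subjects {list(bad)}")
    dup = df.duplicated(subset=["subject_id", "visit", "replicate"])
    if dup.any():
        raise SchemaError(
            "duplicate (subject_id, visit, replicate) rows: "
            f"{df.loc[dup, 'subject_id'].unique()[:5].tolist()}"
        )
    sites_per_subject = df.groupby("subject_id")["site_id"].nunique()
    if (sites_per_subject > 1).any():
        bad = sites_per_subject[sites_per_subject > 1].index[:5].tolist()
        raise SchemaError(f"subjects recorded at more than one site: {bad}")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement table with deterministic formatting."""
    _require_schema(df)
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Centile engine
# ---------------------------------------------------------------------------


def normal_deviate(p: float) -> float:
    """Standard-normal deviate z_p with Phi(z_p) = p.

    Raises :class:`DomainError` unless ``0 < p < 1``.
    """
    if not 0.0 < p < 1.0:
        raise DomainError(f"centile probability must lie strictly in (0, 1), got {p}")
    return float(stats.norm.ppf(p))


@dataclass(frozen=True)
class CentileSpec:
    """A centile identified by its probability p, with deviate z_p."""

    p: float

    def __post_init__(self) -> None:
        normal_deviate(self.p)  # domain check

    @property
    def z(self) -> float:
        return normal_deviate(self.p)


@dataclass(frozen=True)
class GrowthCurveModel:
    """Parametric growth chart: polynomial mu(GA) and sigma(GA) in raw weeks.

    Coefficients are in ascending powers of GA in decimal weeks, so
    ``mu(t) = sum_k mean_coefficients[k] * t**k``.  ``ga_domain`` is the
    (min_weeks, max_weeks) range over which the model may be evaluated;
    requests outside it raise :class:`ExtrapolationError` rather than
    silently extrapolating.
    """

    mean_coefficients: tuple[float, ...]
    sd_coefficients: tuple[float, ...]
    ga_domain: tuple[float, float]
    unit: str = "mm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_coefficients", tuple(float(c) for c in self.mean_coefficients))
        object.__setattr__(self, "sd_coefficients", tuple(float(c) for c in self.sd_coefficients))
        object.__setattr__(self, "ga_domain", (float(self.ga_domain[0]), float(self.ga_domain[1])))
        lo, hi = self.ga_domain
        if not lo <= hi:
            raise DomainError(f"ga_domain must be ordered, got {self.ga_domain}")
        grid = np.linspace(lo, hi, 201)
        if np.any(P.polyval(grid, self.sd_coefficients) <= 0):
            raise FitError(
                "sigma(GA) is non-positive somewhere on the GA domain "
                f"{self.ga_domain}; the model is not a valid chart"
            )

    @property
    def mean_degree(self) -> int:
        return len(self.mean_coefficients) - 1

    @property
    def sd_degree(self) -> int:
        return len(self.sd_coefficients) - 1

    def _check_domain(self, weeks: float) -> None:
        lo, hi = self.ga_domain
        if not (lo - 1e-9) <= weeks <= (hi + 1e-9):
            raise ExtrapolationError(
                f"GA {weeks:.2f} weeks is outside the model domain "
                f"[{lo:.2f}, {hi:.2f}] weeks; refusing to extrapolate"
            )

    def mean(self, ga) -> float:
        """mu(GA)."""
        w = _ga_weeks(ga)
        self._check_domain(w)
        return float(P.polyval(w, self.mean_coefficients))

    def sd(self, ga) -> float:
        """sigma(GA)."""
        w = _ga_weeks(ga)
        self._check_domain(w)
        return float(P.polyval(w, self.sd_coefficients))

    # vectorised, domain-checked evaluation used by the fitting/reporting code
    def mean_array(self, weeks: np.ndarray) -> np.ndarray:
        weeks = np.asarray(weeks, dtype=float)
        lo, hi = self.ga_domain
        if np.any(weeks < lo - 1e-9) or np.any(weeks > hi + 1e-9):
            raise ExtrapolationError(
                f"some GA values are outside the model domain [{lo:.2f}, {hi:.2f}]"
            )
        return P.polyval(weeks, self.mean_coefficients)

    def sd_array(self, weeks: np.ndarray) -> np.ndarray:
        weeks = np.asarray(weeks, dtype=float)
        lo, hi = self.ga_domain
        if np.any(weeks < lo - 1e-9) or np.any(weeks > hi + 1e-9):
            raise ExtrapolationError(
                f"some GA values are outside the model domain [{lo:.2f}, {hi:.2f}]"
            )
        return P.polyval(weeks, self.sd_coefficients)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "ga_domain_weeks": list(self.ga_domain),
            "mean_coefficients": list(self.mean_coefficients),
            "sd_coefficients": list(self.sd_coefficients),
            "basis": "polynomial-raw-weeks",
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthCurveModel":
        if d.get("basis") != "polynomial-raw-weeks":
            raise SchemaError(f"unknown model basis {d.get('basis')!r}")
        return cls(
            mean_coefficients=tuple(d["mean_coefficients"]),
            sd_coefficients=tuple(d["sd_coefficients"]),
            ga_domain=tuple(d["ga_domain_weeks"]),
            unit=d["unit"],
        )

    @classmethod
    def from_json(cls, source) -> "GrowthCurveModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def centile_value(model: GrowthCurveModel, ga, p: float) -> float:
    """The p-th centile at GA: mu(GA) + z_p * sigma(GA)."""
    z = normal_deviate(p)
    return model.mean(ga) + z * model.sd(ga)


def z_score(model: GrowthCurveModel, ga, y: float) -> float:
    """Standardised residual (y - mu(GA)) / sigma(GA)."""
    sd = model.sd(ga)
    if sd <= 0:
        raise FitError(f"sigma(GA) = {sd} is not positive; invalid model")
    return (y - model.mean(ga)) / sd


def reference_interval(model: GrowthCurveModel, ga, coverage: float = 0.95) -> tuple[float, float]:
    """Central reference interval containing ``coverage`` of the population.

    ``coverage=0.95`` gives the conventional 95% reference interval from
    the 2.5th to the 97.5th centile.
    """
    if not 0.0 < coverage < 1.0:
        raise DomainError(f"coverage must lie in (0, 1), got {coverage}")
    alpha = (1.0 - coverage) / 2.0
    return centile_value(model, ga, alpha), centile_value(model, ga, 1.0 - alpha)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

#: E|X| = sigma * sqrt(2/pi) for X ~ N(0, sigma^2); regression on absolute
#: residuals is rescaled by the reciprocal factor to estimate sigma.
HALF_NORMAL_FACTOR = math.sqrt(math.pi / 2.0)


def _decenter(coefs_centered: np.ndarray) -> np.ndarray:
    """Re-express a polynomial in (t - 28) as one in raw t."""
    poly = np.polynomial.Polynomial(coefs_centered)
    shifted = poly(np.polynomial.Polynomial([-BASIS_CENTER_WEEKS, 1.0]))
    return shifted.coef if isinstance(shifted, np.polynomial.Polynomial) else np.array([float(shifted)])


def fit_growth_curve_xy(
    ga_weeks: np.ndarray,
    values: np.ndarray,
    mean_degree: int = 2,
    sd_degree: int = 1,
    unit: str = "mm",
) -> GrowthCurveModel:
    """Fit mu(GA) and sigma(GA) polynomials to (GA weeks, value) arrays.

    The mean curve is ordinary least squares on a basis centred at 28
    weeks.  The SD curve is a polynomial regression of the absolute
    residuals scaled by sqrt(pi/2) (half-normal correction), which is
    unbiased for sigma under conditional normality and more resistant to
    outliers than squared-residual regression.  The fitted sigma must be
    strictly positive over the observed GA range or the fit is rejected.
    """
    t = np.asarray(ga_weeks, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise FitError("ga_weeks and values must be 1-d arrays of equal length")
    n_distinct = np.unique(t).size
    if n_distinct < max(mean_degree, sd_degree) + 1:
        raise FitError(
            f"need at least {max(mean_degree, sd_degree) + 1} distinct GA values "
            f"to identify degree-({mean_degree},{sd_degree}) curves, got {n_distinct}"
        )
    if t.size < mean_degree + sd_degree + 2:
        raise FitError(
            f"need at least {mean_degree + sd_degree + 2} observations, got {t.size}"
        )

    tc = t - BASIS_CENTER_WEEKS
    mean_c = P.polyfit(tc, y, mean_degree)
    resid = y - P.polyval(tc, mean_c)
    sd_c = P.polyfit(tc, np.abs(resid), sd_degree) * HALF_NORMAL_FACTOR

    domain = (float(t.min() / 1.0), float(t.max()))
    grid = np.linspace(domain[0] - BASIS_CENTER_WEEKS, domain[1] - BASIS_CENTER_WEEKS, 201)
    sd_on_grid = P.polyval(grid, sd_c)
    if np.any(sd_on_grid <= 0):
        raise FitError(
            "fitted sigma(GA) is non-positive on the observed GA range "
            f"(min {sd_on_grid.min():.4g}); increase data or lower sd_degree"
        )

    return GrowthCurveModel(
        mean_coefficients=tuple(_decenter(mean_c)),
        sd_coefficients=tuple(_decenter(sd_c)),
        ga_domain=domain,
        unit=unit,
    )


def fit_growth_curve(
    data,
    mean_degree: int = 2,
    sd_degree: int = 1,
) -> GrowthCurveModel:
    """Fit a growth chart to measurement records or a canonical DataFrame.

    ``data`` must be pre-aggregated to one value per subject-visit
    (see :mod:`centiledesign.replicates`); replicate rows would make the
    SD curve describe replicate noise instead of population spread.
    """
    if isinstance(data, pd.DataFrame):
        _require_schema(data)
        df = data
    else:
        df = records_to_frame(data)
    reps = df.groupby(["subject_id", "visit"])["replicate"].nunique()
    if (reps > 1).any():
        raise FitError(
            "data contain multiple replicates per subject-visit; aggregate "
            "them first (centiledesign.replicates.aggregate_replicates)"
        )
    unit = str(df["unit"].iloc[0]) if len(df) else "mm"
    return fit_growth_curve_xy(
        df["ga_days"].to_numpy(dtype=float) / 7.0,
        df["value"].to_numpy(dtype=float),
        mean_degree=mean_degree,
        sd_degree=sd_degree,
        unit=unit,
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoodnessOfFit:
    """Diagnostics from :func:`goodness_of_fit`.

    ``per_week``: one row per completed GA week (contiguous, zero rows
    kept) with n, mean z-score and SD of z-scores.  ``centile_props``:
    observed vs nominal proportions below each fitted centile with exact
    (Clopper-Pearson) binomial intervals.  ``plot_data``: raw points with
    superimposed fitted centile curves, ready for plotting.
    """

    per_week: pd.DataFrame
    centile_props: pd.DataFrame
    plot_data: pd.DataFrame
    overall_mean_z: float
    overall_sd_z: float


def goodness_of_fit(
    model: GrowthCurveModel,
    data,
    centiles: Sequence[float] = (0.03, 0.10, 0.50, 0.90, 0.97),
    ci_level: float = 0.99,
) -> GoodnessOfFit:
    """Assess a fitted chart against (aggregated) data.

    Under a correct model the z-scores are standard normal at every GA,
    so per-week mean ~ 0 and SD ~ 1, and the proportion of observations
    below the fitted p-th centile ~ p.
    """
    if isinstance(data, pd.DataFrame):
        _require_schema(data)
        df = data
    else:
        df = records_to_frame(data)

    weeks = df["ga_days"].to_numpy(dtype=float) / 7.0
    y = df["value"].to_numpy(dtype=float)
    mu = model.mean_array(weeks)
    sd = model.sd_array(weeks)
    z = (y - mu) / sd

    completed = (df["ga_days"].to_numpy() // 7).astype(int)
    lo_w, hi_w = int(completed.min()), int(completed.max())
    rows = []
    zs = pd.Series(z, index=completed)
    for w in range(lo_w, hi_w + 1):
        grp = zs[zs.index == w]
        rows.append(
            {
                "week": w,
                "n": int(grp.size),
                "mean_z": float(grp.mean()) if grp.size else np.nan,
                "sd_z": float(grp.std(ddof=1)) if grp.size > 1 else np.nan,
            }
        )
    per_week = pd.DataFrame(rows)

    n = z.size
    prop_rows = []
    for p in centiles:
        zp = normal_deviate(p)
        k = int(np.sum(z < zp))
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=ci_level, method="exact")
        prop_rows.append(
            {
                "p": p,
                "nominal": p,
                "observed": k / n,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
                "n": n,
            }
        )
    centile_props = pd.DataFrame(prop_rows)

    grid = np.linspace(model.ga_domain[0], model.ga_domain[1], 101)
    plot = pd.DataFrame({"ga_weeks": weeks, "value": y, "kind": "observed"})
    curves = []
    for p in centiles:
        zp = normal_deviate(p)
        curves.append(
            pd.DataFrame(
                {
                    "ga_weeks": grid,
                    "value": model.mean_array(grid) + zp * model.sd_array(grid),
                    "kind": f"centile_{p:g}",
                }
            )
        )
    plot_data = pd.concat([plot, *curves], ignore_index=True)

    return GoodnessOfFit(
        per_week=per_week,
        centile_props=centile_props,
        plot_data=plot_data,
        overall_mean_z=float(z.mean()),
        overall_sd_z=float(z.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Pregnancy dating
# ---------------------------------------------------------------------------


class DatingSource(enum.Enum):
    LMP = "LMP"
    ULTRASOUND = "ULTRASOUND"


@dataclass(frozen=True)
class DatingRecord:
    """LMP- and ultrasound-based GA estimates for one pregnancy.

    The agreement rule is intended for first-trimester dating, where
    crown-rump length is reliable (roughly 9+0 to 13+6 weeks, 63-97 days).
    """

    ga_lmp: "GestationalAge | None"
    ga_ultrasound: "GestationalAge | None"
    tolerance_days: int = 7

    def __post_init__(self) -> None:
        if self.tolerance_days <= 0:
            raise DomainError(f"tolerance_days must be positive, got {self.tolerance_days}")


@dataclass(frozen=True)
class DatingResult:
    ga: GestationalAge
    source: DatingSource
    compatible: bool


def reconcile_gestational_age(
    rec: DatingRecord,
    prefer: DatingSource = DatingSource.LMP,
) -> DatingResult:
    """Combine LMP and ultrasound dating under an agreement tolerance.

    If the two estimates agree to within ``tolerance_days`` the preferred
    source (LMP by default, following common standard-building practice)
    is kept and the record is flagged compatible; otherwise the ultrasound
    estimate is used, since LMP recall is the unreliable component.
    """
    if rec.ga_lmp is None or rec.ga_ultrasound is None:
        raise MissingDatingError(
            "both LMP and ultrasound GA estimates are required for reconciliation"
        )
    diff = abs(rec.ga_lmp.days - rec.ga_ultrasound.days)
    if diff <= rec.tolerance_days:
        chosen = rec.ga_lmp if prefer is DatingSource.LMP else rec.ga_ultrasound
        return DatingResult(ga=chosen, source=prefer, compatible=True)
    return DatingResult(ga=rec.ga_ultrasound, source=DatingSource.ULTRASOUND, compatible=False)
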