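"""Efficiency of longitudinal versus cross-sectional chart designs.

A longitudinal study measures each fetus at m visits; treating those
correlated measurements as if they were independent overstates the
information they carry.  The design factor D is the number of
cross-sectional subjects that buy the same centile precision as one
longitudinally measured subject:

    D = Var_CS(centile estimate) / Var_long(centile estimate)

at equal numbers of *subjects*.  D lies between 1 (perfect within-subject
correlation: extra visits add nothing at a fixed GA) and m (independent
visits).  Published simulation work on biparietal diameter puts D around
2.3 for realistic fetal designs, i.e. a longitudinal study needs roughly
half to a third the subjects of a cross-sectional one.

:func:`simulate_design_factor` estimates D by simulation: correlation is
induced by a subject-level random intercept (exchangeable structure, the
structure name is recorded in the result), both designs are fitted with
the same mean/SD polynomial machinery as real charts, and the variance of
the fitted centile at a reference GA is compared across many replicate
studies.  :func:`analytic_design_factor_exchangeable` provides the
closed-form special case D = m / (1 + (m - 1) rho), exact for the
precision of a mean — hence for the median centile — when all visits fall
at one GA.  For p != 0.5 the centile estimate also carries the variance
of the fitted SD, whose longitudinal/cross-sectional ratio differs from
the mean's once rho > 0, so the closed form is an oracle for the median
and a magnitude guide elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    DomainError,
    GestationalAge,
    GrowthCurveModel,
    fit_growth_curve_xy,
    normal_deviate,
)

__all__ = [
    "LongitudinalDesign",
    "DesignFactorResult",
    "default_fetal_design",
    "simulate_design_factor",
    "analytic_design_factor_exchangeable",
]


@dataclass(frozen=True)
class LongitudinalDesign:
    """A longitudinal study design against a known truth model.

    ``rho`` is the exchangeable within-subject correlation of the
    measurements (after GA-standardisation); ``visit_ga`` the common
    visit schedule.
    """

    visit_ga: tuple[GestationalAge, ...]
    rho: float
    n_subjects: int
    truth: GrowthCurveModel

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise DomainError(f"rho must lie in [0, 1), got {self.rho}")
        if self.n_subjects < 2:
            raise DomainError("need at least 2 subjects")
        days = [g.days for g in self.visit_ga]
        # non-decreasing: repeated GAs are allowed so the degenerate
        # single-GA schedule (the closed-form oracle's case) is expressible
        if len(days) >= 2 and any(b < a for a, b in zip(days, days[1:])):
            raise DomainError("visit GAs must be non-decreasing")
        lo, hi = self.truth.ga_domain
        for g in self.visit_ga:
            if not lo - 1e-9 <= g.weeks <= hi + 1e-9:
                raise DomainError(
                    f"visit GA {g.weeks:.2f} wk outside truth domain [{lo}, {hi}]"
                )

    @property
    def m(self) -> int:
        return len(self.visit_ga)


@dataclass(frozen=True)
class DesignFactorResult:
    D: float
    mc_error: float
    reference_ga: GestationalAge
    p: float
    m: int
    rho: float
    reps: int
    correlation_structure: str = "exchangeable-random-intercept"
    var_cross_sectional: float = float("nan")
    var_longitudinal: float = float("nan")


def analytic_design_factor_exchangeable(m: int, rho: float) -> float:
    """Closed-form D = m / (1 + (m - 1) rho) for exchangeable visits.

    The variance ratio of one measurement versus the mean of m
    exchangeable measurements; exact for mean (median-centile) precision
    at a single GA.
    """
    if m < 1:
        raise DomainError(f"m must be >= 1, got {m}")
    if not 0.0 <= rho < 1.0:
        raise DomainError(f"rho must lie in [0, 1), got {rho}")
    return m / (1.0 + (m - 1) * rho)


def default_fetal_design(
    truth: GrowthCurveModel | None = None,
    n_subjects: int = 150,
    rho: float = 0.6,
) -> LongitudinalDesign:
    """A fetal-biometry-like default: four scans at 20/24/28/32 weeks,
    within-subject correlation 0.6 (typical of serial biometry z-scores).
    """
    if truth is None:
        # quadratic mean, linearly increasing SD — the package's default
        # biometry-like truth (see synthetic_data.default_truth)
        from .synthetic_data import default_truth

        truth = default_truth()
    visits = tuple(GestationalAge.from_weeks(w) for w in (20, 24, 28, 32))
    return LongitudinalDesign(visit_ga=visits, rho=rho, n_subjects=n_subjects, truth=truth)


def _var_and_error(estimates: np.ndarray) -> tuple[float, float]:
    """Sample variance and its Monte-Carlo SE from the fourth moment."""
    r = estimates.size
    v = float(estimates.var(ddof=1))
    m4 = float(((estimates - estimates.mean()) ** 4).mean())
    var_of_var = max(0.0, (m4 - (r - 3) / (r - 1) * v * v) / r)
    return v, math.sqrt(var_of_var)


def simulate_design_factor(
    design: LongitudinalDesign,
    p: float = 0.975,
    reference_ga: GestationalAge | None = None,
    reps: int = 1000,
    seed: int | None = None,
    mean_degree: int = 2,
    sd_degree: int = 1,
) -> DesignFactorResult:
    """Estimate D by replicate simulation of both designs.

    Each replicate simulates (i) a longitudinal study — every subject
    measured at all visit GAs, with a subject random intercept carrying a
    fraction rho of the GA-standardised variance — and (ii) a
    cross-sectional study with the same number of subjects, one
    measurement each, GAs balanced over the visit schedule (the
    longitudinal design's marginal GA distribution).  Both are fitted
    with the standard chart fitter and the p-th centile read off at
    ``reference_ga``; D is the ratio of the across-replicate variances.

    Polynomial degrees are capped at (number of distinct visit GAs - 1)
    so that degenerate schedules (all visits at one GA) fit constants.
    """
    if reps < 100:
        raise DomainError(f"reps must be >= 100, got {reps}")
    truth = design.truth
    if reference_ga is None:
        reference_ga = GestationalAge.from_weeks(28)
    reference_ga.weeks  # touch; domain checked below by model evaluation
    truth.mean(reference_ga)

    m = design.m
    if m == 1:
        return DesignFactorResult(
            D=1.0,
            mc_error=0.0,
            reference_ga=reference_ga,
            p=p,
            m=1,
            rho=design.rho,
            reps=0,
        )

    rng = np.random.default_rng(seed)
    n = design.n_subjects
    visit_weeks = np.array([g.weeks for g in design.visit_ga])
    n_distinct = np.unique(visit_weeks).size
    mean_degree = min(mean_degree, n_distinct - 1)
    sd_degree = min(sd_degree, n_distinct - 1)

    mu_v = truth.mean_array(visit_weeks)
    sd_v = truth.sd_array(visit_weeks)
    rho = design.rho
    z_ref = normal_deviate(p)
    ref_w = reference_ga.weeks

    # cross-sectional GA assignment: balanced over the visit schedule
    cs_weeks = visit_weeks[np.arange(n) % m]
    cs_mu = truth.mean_array(cs_weeks)
    cs_sd = truth.sd_array(cs_weeks)

    long_t = np.tile(visit_weeks, n)
    est_long = np.empty(reps)
    est_cs = np.empty(reps)
    sqrt_rho = math.sqrt(rho)
    sqrt_1mrho = math.sqrt(1.0 - rho)
    for r in range(reps):
        b = rng.standard_normal(n)[:, None]  # subject intercept
        e = rng.standard_normal((n, m))
        y_long = mu_v[None, :] + sd_v[None, :] * (sqrt_rho * b + sqrt_1mrho * e)
        model_l = fit_growth_curve_xy(long_t, y_long.ravel(), mean_degree, sd_degree)
        est_long[r] = model_l.mean(ref_w) + z_ref * model_l.sd(ref_w)

        y_cs = cs_mu + cs_sd * rng.standard_normal(n)
        model_c = fit_growth_curve_xy(cs_weeks, y_cs, mean_degree, sd_degree)
        est_cs[r] = model_c.mean(ref_w) + z_ref * model_c.sd(ref_w)

    v_cs, se_cs = _var_and_error(est_cs)
    v_long, se_long = _var_and_error(est_long)
    D = v_cs / v_long
    mc_error = D * math.sqrt((se_cs / v_cs) ** 2 + (se_long / v_long) ** 2)
    return DesignFactorResult(
        D=D,
        mc_error=mc_error,
        reference_ga=reference_ga,
        p=p,
        m=m,
        rho=rho,
        reps=reps,
        var_cross_sectional=v_cs,
        var_longitudinal=v_long,
    )
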