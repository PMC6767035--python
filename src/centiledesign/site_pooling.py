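"""Multicentre combinability under a prespecified standardized-difference rule.

International growth standards pool data from several study sites only
after showing that no site's centile curves stray too far from the
pooled curves.  The working criterion, fixed before any analysis, is a
standardized difference: at every GA on a grid and for a set of centiles,

    delta(site, GA, p) = (site centile - pooled centile) / pooled sigma(GA)

and a site is poolable when max |delta| over the grid stays below a
threshold (0.5 SD by convention — Cohen's "medium" difference).  The
criterion is deliberately an effect-size rule, not a significance test:
with site samples in the hundreds, trivial differences are significant
while the question is whether they are *large*.  Differences are
standardized by the pooled model's sigma(GA), since the criterion guards
the pooled standard.

A leave-one-site-out analysis complements the rule: each site is dropped
in turn and the pooled curves refitted, quantifying how much any single
site pulls the standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DomainError,
    FitError,
    GestationalAge,
    GrowthCurveModel,
    fit_growth_curve_xy,
    normal_deviate,
)

__all__ = [
    "PoolingCriterion",
    "SiteComparisonResult",
    "fit_site_and_pooled",
    "standardized_differences",
    "leave_one_site_out",
]


@dataclass(frozen=True)
class PoolingCriterion:
    """Prespecified combinability rule.

    ``threshold_sd`` defaults to the conventional 0.5 SD; ``ga_grid``
    defaults to every completed week of the models' common domain;
    ``centiles`` to the chart-defining 3rd/50th/97th.
    """

    threshold_sd: float = 0.5
    ga_grid: tuple[GestationalAge, ...] | None = None
    centiles: tuple[float, ...] = (0.03, 0.50, 0.97)

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise DomainError(f"threshold_sd must be positive, got {self.threshold_sd}")
        for p in self.centiles:
            normal_deviate(p)

    def grid_weeks(self, models: list[GrowthCurveModel]) -> np.ndarray:
        lo = max(m.ga_domain[0] for m in models)
        hi = min(m.ga_domain[1] for m in models)
        if self.ga_grid is not None:
            return np.array([g.weeks for g in self.ga_grid])
        weeks = np.arange(int(np.ceil(lo - 1e-9)), int(np.floor(hi + 1e-9)) + 1, dtype=float)
        if weeks.size == 0:
            raise DomainError("models share no completed GA week")
        return weeks

    def provenance(self) -> dict:
        return {
            "threshold_sd": self.threshold_sd,
            "centiles": list(self.centiles),
            "ga_grid_weeks": None
            if self.ga_grid is None
            else [g.weeks for g in self.ga_grid],
            "standardized_by": "pooled sigma(GA)",
            "note": "criterion prespecified before analysis; no significance testing",
        }


@dataclass(frozen=True)
class SiteComparisonResult:
    """Per-cell standardized differences and per-site verdicts."""

    table: pd.DataFrame  # site_id, ga_weeks, p, delta (NaN marks unfittable cells)
    per_site: pd.DataFrame  # site_id, max_abs_delta, poolable
    all_poolable: bool
    provenance: dict = field(default_factory=dict)


def fit_site_and_pooled(
    data: pd.DataFrame,
    mean_degree: int = 2,
    sd_degree: int = 1,
) -> tuple[dict[str, GrowthCurveModel], GrowthCurveModel, list[str]]:
    """Fit one model per site plus the pooled model, same degrees for all.

    Returns (site models, pooled model, names of sites excluded because
    they were too small or degenerate to fit).  Requires at least two
    sites; data must be pre-aggregated (one value per subject-visit).
    """
    sites = sorted(data["site_id"].unique())
    if len(sites) < 2:
        raise DomainError(
            f"need at least 2 sites to compare, found {len(sites)}: {sites}"
        )
    unit = str(data["unit"].iloc[0])

    def _fit(df: pd.DataFrame) -> GrowthCurveModel:
        return fit_growth_curve_xy(
            df["ga_days"].to_numpy(dtype=float) / 7.0,
            df["value"].to_numpy(dtype=float),
            mean_degree=mean_degree,
            sd_degree=sd_degree,
            unit=unit,
        )

    pooled = _fit(data)
    site_models: dict[str, GrowthCurveModel] = {}
    excluded: list[str] = []
    for s in sites:
        try:
            site_models[s] = _fit(data[data["site_id"] == s])
        except FitError as exc:
            excluded.append(s)
            import warnings

            warnings.warn(f"site {s} excluded from comparison: {exc}", stacklevel=2)
    if not site_models:
        raise FitError("no site could be fitted")
    return site_models, pooled, excluded


def standardized_differences(
    site_models: dict[str, GrowthCurveModel],
    pooled_model: GrowthCurveModel,
    criterion: PoolingCriterion | None = None,
) -> SiteComparisonResult:
    """Standardized site-vs-pooled centile differences over the GA grid."""
    if criterion is None:
        criterion = PoolingCriterion()
    weeks = criterion.grid_weeks([pooled_model, *site_models.values()])
    zs = np.array([normal_deviate(p) for p in criterion.centiles])

    pooled_mu = pooled_model.mean_array(weeks)
    pooled_sd = pooled_model.sd_array(weeks)
    pooled_cent = pooled_mu[None, :] + zs[:, None] * pooled_sd[None, :]

    rows = []
    for site_id in sorted(site_models):
        model = site_models[site_id]
        lo, hi = model.ga_domain
        inside = (weeks >= lo - 1e-9) & (weeks <= hi + 1e-9)
        mu = np.full_like(weeks, np.nan)
        sd = np.full_like(weeks, np.nan)
        if inside.any():
            mu[inside] = model.mean_array(weeks[inside])
            sd[inside] = model.sd_array(weeks[inside])
        site_cent = mu[None, :] + zs[:, None] * sd[None, :]
        delta = (site_cent - pooled_cent) / pooled_sd[None, :]
        for i, p in enumerate(criterion.centiles):
            for j, w in enumerate(weeks):
                rows.append(
                    {
                        "site_id": site_id,
                        "ga_weeks": float(w),
                        "p": float(p),
                        "delta": float(delta[i, j]),
                        "unfittable": bool(~inside[j]),
                    }
                )
    table = pd.DataFrame(rows)

    per_site = (
        table.groupby("site_id")["delta"]
        .apply(lambda d: float(np.nanmax(np.abs(d))))
        .rename("max_abs_delta")
        .reset_index()
    )
    per_site["poolable"] = per_site["max_abs_delta"] < criterion.threshold_sd
    return SiteComparisonResult(
        table=table,
        per_site=per_site,
        all_poolable=bool(per_site["poolable"].all()),
        provenance=criterion.provenance(),
    )


def leave_one_site_out(
    data: pd.DataFrame,
    criterion: PoolingCriterion | None = None,
    mean_degree: int = 2,
    sd_degree: int = 1,
) -> pd.DataFrame:
    """Impact of excluding each site from the pooled fit.

    For each site s the pooled model is refitted without s and the
    maximum standardized centile change over the grid,
    max |centile_without_s - centile_all| / pooled sigma, is reported.
    Requires at least three sites (two must remain after exclusion).
    """
    if criterion is None:
        criterion = PoolingCriterion()
    sites = sorted(data["site_id"].unique())
    if len(sites) < 3:
        raise DomainError(f"leave-one-site-out needs >= 3 sites, found {len(sites)}")

    def _fit(df: pd.DataFrame) -> GrowthCurveModel:
        return fit_growth_curve_xy(
            df["ga_days"].to_numpy(dtype=float) / 7.0,
            df["value"].to_numpy(dtype=float),
            mean_degree=mean_degree,
            sd_degree=sd_degree,
        )

    full = _fit(data)
    weeks = criterion.grid_weeks([full])
    zs = np.array([normal_deviate(p) for p in criterion.centiles])
    full_cent = full.mean_array(weeks)[None, :] + zs[:, None] * full.sd_array(weeks)[None, :]
    full_sd = full.sd_array(weeks)

    rows = []
    for s in sites:
        reduced = _fit(data[data["site_id"] != s])
        lo, hi = reduced.ga_domain
        inside = (weeks >= lo - 1e-9) & (weeks <= hi + 1e-9)
        cent = np.full((zs.size, weeks.size), np.nan)
        cent[:, inside] = (
            reduced.mean_array(weeks[inside])[None, :]
            + zs[:, None] * reduced.sd_array(weeks[inside])[None, :]
        )
        impact = float(np.nanmax(np.abs((cent - full_cent) / full_sd[None, :])))
        rows.append({"site_id": s, "max_abs_impact": impact})
    return pd.DataFrame(rows)
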