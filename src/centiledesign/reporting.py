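"""Reporting artifacts for chart publications.

A publishable chart study reports (i) a table of included observations —
how many subject-visits fall in each completed GA week, with the mean and
SD of the measurement; (ii) a table of selected fitted centiles (10th /
50th / 90th by default, with the 3rd / 97th extremes alongside since
charts are mostly consulted at the extremes); and (iii) the regression
equations for both the mean *and* the SD, so any centile or z-score can
be computed by readers — SD equations are the piece most often missing
from published charts, and they are mandatory here.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .core_model import (
    DomainError,
    GrowthCurveModel,
    SchemaError,
    centile_value,
    normal_deviate,
    z_score,
)

__all__ = [
    "ga_window_table",
    "centile_table",
    "equation_export",
    "model_from_equations",
    "DEFAULT_REPORT_CENTILES",
    "EXTREME_REPORT_CENTILES",
]

DEFAULT_REPORT_CENTILES = (0.10, 0.50, 0.90)
EXTREME_REPORT_CENTILES = (0.03, 0.97)


def ga_window_table(data: pd.DataFrame) -> pd.DataFrame:
    """Included observations per completed GA week.

    Expects aggregated data (one value per subject-visit); weeks are
    contiguous over the observed range with explicit n = 0 rows, and the
    n column sums to the total number of included subject-visits.
    """
    reps = data.groupby(["subject_id", "visit"])["replicate"].nunique()
    if (reps > 1).any():
        raise SchemaError(
            "data contain unaggregated replicates; aggregate first "
            "(centiledesign.replicates.aggregate_replicates)"
        )
    week = (data["ga_days"].to_numpy() // 7).astype(int)
    values = pd.Series(data["value"].to_numpy(dtype=float), index=week)
    rows = []
    for w in range(int(week.min()), int(week.max()) + 1):
        grp = values[values.index == w]
        rows.append(
            {
                "week": w,
                "n": int(grp.size),
                "mean": float(grp.mean()) if grp.size else np.nan,
                "sd": float(grp.std(ddof=1)) if grp.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def centile_table(
    model: GrowthCurveModel,
    weeks,
    centiles=DEFAULT_REPORT_CENTILES,
) -> pd.DataFrame:
    """Fitted centile values per GA week; columns ordered by probability.

    Rows outside the model domain are rejected; columns are checked to be
    strictly increasing in p at every GA (a sanity guarantee the normal
    engine provides as long as sigma > 0).
    """
    ps = sorted(centiles)
    weeks = list(weeks)
    table = pd.DataFrame({"week": weeks})
    for p in ps:
        table[f"P{100 * p:g}"] = [centile_value(model, float(w), p) for w in weeks]
    cols = table.columns[1:]
    vals = table[cols].to_numpy()
    if vals.shape[1] > 1 and not np.all(np.diff(vals, axis=1) > 0):
        raise DomainError("centile columns are not monotone; invalid model")
    return table


def equation_export(model: GrowthCurveModel, path=None) -> dict:
    """Export the chart equations as a self-verifying JSON block.

    Coefficients are raw-week ascending polynomials for both the mean and
    the SD.  A worked example (the z-score of the fitted 90th centile
    value at mid-domain GA) is embedded so importers can confirm their
    evaluation matches.  ``model_from_equations(equation_export(m))``
    reproduces centiles bit-exactly.
    """
    mid = 0.5 * (model.ga_domain[0] + model.ga_domain[1])
    y90 = centile_value(model, mid, 0.90)
    block = {
        "model": model.to_dict(),
        "equations": {
            "mean": _poly_text(model.mean_coefficients),
            "sd": _poly_text(model.sd_coefficients),
            "centile": "centile(p, t) = mean(t) + z_p * sd(t)",
            "z_score": "z(y, t) = (y - mean(t)) / sd(t)",
        },
        "worked_example": {
            "ga_weeks": mid,
            "p": 0.90,
            "centile_value": y90,
            "z_score_check": z_score(model, mid, y90),
            "expected_z": normal_deviate(0.90),
        },
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(block, fh, indent=2)
            fh.write("\n")
    return block


def _poly_text(coefs) -> str:
    terms = [f"{c!r}*t^{k}" if k else f"{c!r}" for k, c in enumerate(coefs)]
    return " + ".join(terms)


def model_from_equations(block: dict) -> GrowthCurveModel:
    """Rebuild a model from an exported equations block."""
    return GrowthCurveModel.from_dict(block["model"])
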