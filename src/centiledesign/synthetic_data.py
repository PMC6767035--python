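"""Seeded generator of multicentre longitudinal fetal-biometry studies.

The generator realises the data structure a chart-building study
collects: several sites, each recruiting subjects who are scanned at a
series of gestational ages, with replicate measurements per visit taken
by (possibly biased) observers.  The observation model for a replicate
of subject i at gestational age t in site s is

    value = mu(t) + shift_s * sigma(t) + c_b * sigma(t) * d_i
            + bias(observer) + eps,      eps ~ N(0, w^2)

where mu and sigma are the truth :class:`~centiledesign.core_model.GrowthCurveModel`
curves, shift_s a site-level offset in SD units, d_i ~ N(0,1) the
subject's (GA-stable) biological deviation, c_b the between-subject
scale (1.0 by default, so the population SD of error-free single
measurements is exactly sigma(t)), and w the within-replicate
measurement-error SD in absolute units.  Optional contaminations:
terminal-digit heaping (rounding toward digits 0 and 5 in ratio 3:1),
attrition (a seeded subset of subjects loses its later visits), and an
LMP dating-error model for the companion dating table.

Identical scenario + seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DatingRecord,
    DomainError,
    GestationalAge,
    GrowthCurveModel,
    MEASUREMENT_COLUMNS,
)

__all__ = [
    "StudyScenario",
    "default_truth",
    "default_scenario",
    "pooling_scenario",
    "generate_study",
    "generate_dating",
    "dating_records",
]


def default_truth() -> GrowthCurveModel:
    """Default biometry-like truth: quadratic mean, SD linear in weeks.

    mu(t) = -30 + 9 t - 0.05 t^2 mm and sigma(t) = 1 + 0.2 t mm over
    14-42 weeks — head-circumference-scale values with the variability
    increasing with GA, as fetal size data show.
    """
    return GrowthCurveModel(
        mean_coefficients=(-30.0, 9.0, -0.05),
        sd_coefficients=(1.0, 0.2),
        ga_domain=(14.0, 42.0),
        unit="mm",
    )


@dataclass(frozen=True)
class StudyScenario:
    """Full specification of a synthetic multicentre study."""

    n_sites: int = 8
    n_subjects_per_site: int = 300
    n_visits: int = 5
    entry_window_weeks: tuple[float, float] = (14.0, 22.0)
    visit_spacing_weeks: float = 5.0
    replicates_per_visit: int = 3
    truth: GrowthCurveModel = field(default_factory=default_truth)
    site_shifts_sd: tuple[float, ...] = ()  # per-site shift in SD units; pads with 0
    between_subject_scale: float = 1.0
    within_replicate_sd: float = 2.0
    observer_biases: tuple[tuple[str, float], ...] = ()
    digit_heaping_strength: float = 0.0
    resolution: float = 1.0
    attrition_rate: float = 0.0
    lmp_error_sd_days: float = 7.0
    dating_tolerance_days: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_subjects_per_site < 1 or self.n_visits < 1:
            raise DomainError("scenario sizes must be positive")
        if self.replicates_per_visit < 1:
            raise DomainError("replicates_per_visit must be >= 1")
        if min(self.between_subject_scale, self.within_replicate_sd) < 0:
            raise DomainError("variance components must be non-negative")
        if not 0.0 <= self.digit_heaping_strength <= 1.0:
            raise DomainError("digit_heaping_strength must lie in [0, 1]")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise DomainError("attrition_rate must lie in [0, 1)")
        lo, hi = self.truth.ga_domain
        last = self.entry_window_weeks[1] + (self.n_visits - 1) * self.visit_spacing_weeks
        if self.entry_window_weeks[0] < lo - 1e-9 or last > hi + 1e-9:
            raise DomainError(
                f"visit schedule (entry {self.entry_window_weeks}, "
                f"{self.n_visits} visits every {self.visit_spacing_weeks} wk) "
                f"leaves the truth GA domain [{lo}, {hi}]"
            )

    def site_shift(self, site_index: int) -> float:
        if site_index < len(self.site_shifts_sd):
            return float(self.site_shifts_sd[site_index])
        return 0.0

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"] = self.truth.to_dict()
        d["observer_biases"] = dict(self.observer_biases)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyScenario":
        d = dict(d)
        d["truth"] = GrowthCurveModel.from_dict(d["truth"])
        d["entry_window_weeks"] = tuple(d["entry_window_weeks"])
        d["site_shifts_sd"] = tuple(d.get("site_shifts_sd", ()))
        d["observer_biases"] = tuple(sorted(dict(d.get("observer_biases", {})).items()))
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "StudyScenario":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def default_scenario(seed: int = 0, **overrides) -> StudyScenario:
    """The package's default study: 8 sites x 300 subjects, 5 visits at
    5-week spacing from a uniform 14-22 week entry, triplicate
    measurements with 2 mm replicate error."""
    return StudyScenario(seed=seed, **overrides)


def pooling_scenario(
    seed: int = 0,
    n_subjects_per_site: int = 500,
    shifted_site_sd: float = 0.0,
    **overrides,
) -> StudyScenario:
    """Multicentre poolability scenario: 8 sites, single clean measurement
    per visit, optionally with the first site shifted by ``shifted_site_sd``
    SD units."""
    shifts = (shifted_site_sd,) if shifted_site_sd else ()
    return StudyScenario(
        seed=seed,
        n_subjects_per_site=n_subjects_per_site,
        replicates_per_visit=1,
        site_shifts_sd=shifts,
        **overrides,
    )


def _heap_digits(values: np.ndarray, strength: float, resolution: float, rng) -> np.ndarray:
    """Round a seeded fraction of values toward terminal digit 0 or 5.

    Digit 0 is targeted three times as often as digit 5, mimicking the
    dominant whole-ten heaping seen in real anthropometry audits.
    """
    if strength <= 0:
        return values
    out = values.copy()
    heap = rng.random(values.size) < strength
    to_zero = rng.random(values.size) < 0.75
    step = 10.0 * resolution
    idx0 = heap & to_zero
    idx5 = heap & ~to_zero
    out[idx0] = np.round(values[idx0] / step) * step
    out[idx5] = np.round((values[idx5] - 5.0 * resolution) / step) * step + 5.0 * resolution
    return out


def generate_study(scenario: StudyScenario) -> tuple[pd.DataFrame, dict]:
    """Generate one study realisation.

    Returns the long-format measurement table (canonical schema) and a
    truth bundle holding every generating parameter, for parameter-
    recovery tests.
    """
    rng = np.random.default_rng(scenario.seed)
    truth = scenario.truth
    m = scenario.n_visits
    r = scenario.replicates_per_visit
    observers = dict(scenario.observer_biases)
    obs_ids = sorted(observers)

    frames = []
    for s in range(scenario.n_sites):
        site_id = f"S{s + 1:02d}"
        n = scenario.n_subjects_per_site
        shift = scenario.site_shift(s)

        entry_lo_d = int(round(scenario.entry_window_weeks[0] * 7))
        entry_hi_d = int(round(scenario.entry_window_weeks[1] * 7))
        entry_days = rng.integers(entry_lo_d, entry_hi_d + 1, size=n)
        spacing_d = int(round(scenario.visit_spacing_weeks * 7))
        ga_days = entry_days[:, None] + spacing_d * np.arange(m)[None, :]  # (n, m)
        ga_weeks = ga_days / 7.0

        d_subject = rng.standard_normal(n)
        mu = truth.mean_array(ga_weeks)
        sd = truth.sd_array(ga_weeks)
        center = mu + (shift + scenario.between_subject_scale * d_subject[:, None]) * sd

        if obs_ids:
            obs_idx = rng.integers(0, len(obs_ids), size=(n, m))
            obs_name = np.array(obs_ids, dtype=object)[obs_idx]
            obs_bias = np.array([observers[o] for o in obs_ids])[obs_idx]
        else:
            obs_name = np.full((n, m), f"{site_id}-O1", dtype=object)
            obs_bias = np.zeros((n, m))

        eps = rng.normal(0.0, scenario.within_replicate_sd, size=(n, m, r))
        values = center[:, :, None] + obs_bias[:, :, None] + eps
        flat = _heap_digits(
            values.ravel(), scenario.digit_heaping_strength, scenario.resolution, rng
        ).reshape(n, m, r)

        # attrition: a seeded subject subset loses visits from a uniformly
        # chosen dropout visit (>= 2) onward
        keep = np.ones((n, m), dtype=bool)
        if scenario.attrition_rate > 0 and m > 1:
            drops = rng.random(n) < scenario.attrition_rate
            dropout_visit = rng.integers(2, m + 1, size=n)  # 1-based visit index
            keep = ~(drops[:, None] & (np.arange(1, m + 1)[None, :] >= dropout_visit[:, None]))

        subj = np.array([f"{site_id}-{i + 1:04d}" for i in range(n)], dtype=object)
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(subj, m * r),
                "site_id": site_id,
                "observer_id": np.repeat(obs_name.ravel(), r),
                "ga_days": np.repeat(ga_days.ravel(), r),
                "visit": np.repeat(np.tile(np.arange(1, m + 1), n), r),
                "replicate": np.tile(np.arange(1, r + 1), n * m),
                "value": flat.ravel(),
                "unit": truth.unit,
            }
        )
        df = df[np.repeat(keep.ravel(), r)]
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)[MEASUREMENT_COLUMNS]
    truth_bundle = {
        "scenario": scenario.to_dict(),
        "truth_model": truth.to_dict(),
        "site_shifts_sd": [scenario.site_shift(s) for s in range(scenario.n_sites)],
    }
    return data, truth_bundle


def generate_dating(
    scenario: StudyScenario,
    n: int | None = None,
) -> pd.DataFrame:
    """Generate first-trimester dating records for the scenario's subjects.

    The ultrasound (CRL) estimate is taken as the reference (equal to the
    true GA at the dating scan, uniform over the CRL-valid 63-97 day
    window); the LMP estimate adds a rounded normal recall error with SD
    ``scenario.lmp_error_sd_days``.
    """
    rng = np.random.default_rng(scenario.seed + 1_000_003)
    if n is None:
        n = scenario.n_sites * scenario.n_subjects_per_site
    true_days = rng.integers(63, 98, size=n)
    err = np.round(rng.normal(0.0, scenario.lmp_error_sd_days, size=n)).astype(int)
    lmp_days = np.clip(true_days + err, 0, 301)
    return pd.DataFrame(
        {
            "subject_id": [f"D-{i + 1:05d}" for i in range(n)],
            "ga_true_days": true_days,
            "ga_ultrasound_days": true_days,
            "ga_lmp_days": lmp_days,
            "tolerance_days": scenario.dating_tolerance_days,
        }
    )


def dating_records(df: pd.DataFrame) -> list[DatingRecord]:
    """Convert a dating table to :class:`DatingRecord` objects."""
    return [
        DatingRecord(
            ga_lmp=GestationalAge(int(row.ga_lmp_days)),
            ga_ultrasound=GestationalAge(int(row.ga_ultrasound_days)),
            tolerance_days=int(row.tolerance_days),
        )
        for row in df.itertuples(index=False)
    ]
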