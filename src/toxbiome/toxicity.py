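"""Hematologic adverse-event grading and the hematologic toxicity index.

Weekly blood counts are graded per CTCAE v5.0 laboratory bands (shipped as
an editable YAML config), each patient's per-AE maximum grade over treatment
is collapsed into a single hematologic toxicity index (HTI), and cohort
characteristics are compared across toxicity strata with the usual 2x2 and
two-sample tests.

The HTI is an order-weighted sum of a patient's AE grades

    HTI = X(1) + X(2)/(1+X(1)) + X(3)/((1+X(1))(1+X(2))) + ...

with the grades X(1) >= X(2) >= ... sorted in descending order, so the index
is dominated by the worst toxicity and, whenever the maximum grade g >= 1,
satisfies g <= HTI < g+1.  A patient with five grade-2 AEs scores
2 + 2/3 + 2/9 + 2/27 + 2/81 = 2.9877.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "AE_TYPES",
    "GradeThresholds",
    "AEProfile",
    "grade_series",
    "grade_value",
    "compute_hti",
    "chisq_2x2",
    "fisher_exact_2x2",
    "cohort_table",
]

#: The five hematologic AE types, in the order they are reported.
AE_TYPES = ("leukopenia", "lymphopenia", "neutropenia", "anemia", "thrombocytopenia")


class GradingError(ValueError):
    """A lab record cannot be graded (negative/missing value, bad config)."""


@dataclass(frozen=True)
class GradeThresholds:
    """Per-AE value bands mapping an analyte measurement to a grade 0-4.

    ``bands[ae]`` is a list of ``(lower, upper, grade)`` half-open intervals
    ``[lower, upper)`` in the analyte's units (10^9/L for counts, g/L for
    hemoglobin).  Bands must be contiguous, non-overlapping, cover (0, inf),
    and the grade must strictly increase as the value decreases.
    """

    analytes: Mapping[str, str]
    bands: Mapping[str, Sequence[tuple[float, float, int]]]
    source: str = "ctcae_v5"

    def __post_init__(self) -> None:
        for ae, bands in self.bands.items():
            ordered = sorted(bands, key=lambda b: -b[0])
            if ordered[0][1] != np.inf or ordered[-1][0] != 0.0:
                raise GradingError(f"{ae}: bands must cover (0, inf)")
            for (lo, hi, g), (lo2, hi2, g2) in zip(ordered, ordered[1:]):
                if hi2 != lo:
                    raise GradingError(f"{ae}: bands not contiguous at {lo}")
                if g2 <= g:
                    raise GradingError(f"{ae}: grade must increase as value decreases")
            if {g for _, _, g in bands} - {0, 1, 2, 3, 4}:
                raise GradingError(f"{ae}: grades must lie in 0..4")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "GradeThresholds":
        """Load thresholds from YAML; default is the bundled CTCAE v5.0 config."""
        if path is None:
            text = (resources.files("toxbiome.data") / "ctcae_v5.yaml").read_text()
            source = "ctcae_v5(bundled)"
        else:
            text = Path(path).read_text()
            source = str(path)
        raw = yaml.safe_load(text)
        analytes = {ae: cfg["analyte"] for ae, cfg in raw.items()}
        bands = {
            ae: [(float(lo), float(hi), int(g)) for lo, hi, g in cfg["bands"]]
            for ae, cfg in raw.items()
        }
        obj = cls(analytes=analytes, bands=bands, source=source)
        object.__setattr__(obj, "_hash", hashlib.sha256(text.encode()).hexdigest()[:12])
        return obj

    @property
    def config_hash(self) -> str:
        """Short digest of the YAML the thresholds were loaded from."""
        return getattr(self, "_hash", "unhashed")


@dataclass
class AEProfile:
    """Per-patient maximum grade (0-4) for each hematologic AE."""

    patient_id: str
    grades: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {ae: g for ae, g in self.grades.items() if g not in (0, 1, 2, 3, 4)}
        if bad:
            raise ValueError(f"grades must be integers 0-4, got {bad}")

    def grade_list(self) -> list[int]:
        return [self.grades.get(ae, 0) for ae in AE_TYPES]


def grade_value(value: float, bands: Sequence[tuple[float, float, int]]) -> int:
    """Grade a single analyte value against ``[lower, upper)`` bands."""
    if not np.isfinite(value) or value < 0:
        raise GradingError(f"analyte value {value!r} is negative or missing")
    for lo, hi, g in bands:
        if lo <= value < hi:
            return g
    raise GradingError(f"value {value} not covered by any band")  # pragma: no cover


def grade_series(
    series: pd.DataFrame,
    thresholds: GradeThresholds,
    include_baseline: bool = True,
) -> AEProfile:
    """Grade one patient's weekly lab series into a per-AE maximum-grade profile.

    Parameters
    ----------
    series
        Long-format frame with columns ``patient_id, week, analyte, value``;
        week 0 is the pre-treatment baseline.
    thresholds
        Grading bands; every analyte the bands reference must be present.
    include_baseline
        Whether week 0 enters the maximum-grade scan (default yes).
    """
    if series.empty:
        raise GradingError("empty lab series")
    pid = str(series["patient_id"].iloc[0])
    if not include_baseline:
        series = series[series["week"] > 0]
    grades: dict[str, int] = {}
    for ae, analyte in thresholds.analytes.items():
        sub = series[series["analyte"] == analyte]
        if sub.empty:
            raise GradingError(f"patient {pid}: analyte {analyte!r} absent from series")
        bad = sub[~np.isfinite(sub["value"]) | (sub["value"] < 0)]
        if not bad.empty:
            weeks = bad["week"].tolist()
            raise GradingError(
                f"patient {pid}: negative or missing {analyte} at weeks {weeks}"
            )
        grades[ae] = max(grade_value(v, thresholds.bands[ae]) for v in sub["value"])
    return AEProfile(patient_id=pid, grades=grades)


def compute_hti(profile: AEProfile | Iterable[int]) -> float:
    """Hematologic toxicity index: order-weighted sum of AE grades.

    Grades are sorted descending; each successive grade is down-weighted by
    the product of (1 + previous grades).  Zero grades contribute nothing and
    leave the denominators unchanged, so the index is a pure function of the
    grade multiset and lies in [g, g+1) where g is the maximum grade (or is
    exactly 0 when all grades are 0).
    """
    grades = profile.grade_list() if isinstance(profile, AEProfile) else list(profile)
    if any(g not in (0, 1, 2, 3, 4) for g in grades):
        raise ValueError(f"grades must be integers 0-4, got {grades}")
    total, denom = 0.0, 1.0
    for g in sorted(grades, reverse=True):
        total += g / denom
        denom *= 1 + g
    return total


def _check_2x2(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("undefined test: a row or column margin is zero")
    return t


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns ``(statistic, two-sided p)``.  The statistic equals the squared
    two-proportion z statistic.
    """
    t = _check_2x2(table)
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities, over all tables with the observed
    margins, whose point probability does not exceed the observed table's.
    """
    t = _check_2x2(table)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


# Table-1 dichotomizations: grade 0 vs >=1 except lymphopenia (0-2 vs 3-4).
_AE_SPLIT = {ae: 1 for ae in AE_TYPES} | {"lymphopenia": 3}


def cohort_table(
    profiles: Sequence[AEProfile],
    hti: Mapping[str, float],
    metadata: pd.DataFrame,
    stratifiers: Sequence[str] = ("sex", "location", "t_stage", "n_stage", "oxaliplatin"),
    use_fisher: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Cohort-characteristics table: stratified counts and p per AE outcome.

    For each AE the cohort is dichotomized at grade >= 1 (lymphopenia at
    grade >= 3) and additionally by HTI <= median vs > median (ties to the
    lower group); each clinical stratifier is cross-tabulated against each
    outcome and tested by Pearson chi-square (default) or Fisher's exact
    test; ``age`` is compared by a two-sample t test (Student by default,
    Welch with ``welch=True``).  Stratifiers with a single observed level are
    skipped with a warning.
    """
    meta = metadata.set_index(metadata["patient_id"].astype(str))
    grades = pd.DataFrame(
        {ae: {p.patient_id: p.grades.get(ae, 0) for p in profiles} for ae in AE_TYPES}
    )
    grades = grades.loc[meta.index]
    hti_vals = pd.Series({str(k): v for k, v in hti.items()}).loc[meta.index]

    outcomes: dict[str, pd.Series] = {
        ae: (grades[ae] >= cut).astype(int) for ae, cut in _AE_SPLIT.items()
    }
    outcomes["hti_group"] = (hti_vals > hti_vals.median()).astype(int)

    rows = []
    for outcome_name, outcome in outcomes.items():
        for var in stratifiers:
            levels = meta[var].astype(str)
            uniq = sorted(levels.unique())
            if len(uniq) < 2:
                warnings.warn(f"stratifier {var!r} has a single level; skipped")
                continue
            ct = pd.crosstab(levels, outcome).reindex(columns=[0, 1], fill_value=0)
            if ct.shape == (2, 2):
                if use_fisher:
                    p = fisher_exact_2x2(ct.values)
                    test = "fisher"
                else:
                    _, p = chisq_2x2(ct.values)
                    test = "chi2"
            else:  # r x 2 table
                stat, p, _, _ = stats.chi2_contingency(ct.values, correction=False)
                test = "chi2"
            for lvl in uniq:
                rows.append(
                    {
                        "outcome": outcome_name,
                        "variable": var,
                        "level": lvl,
                        "n_low": int(ct.loc[lvl, 0]),
                        "n_high": int(ct.loc[lvl, 1]),
                        "test": test,
                        "p": p,
                    }
                )
        if "age" in meta.columns:
            a = meta.loc[outcome == 0, "age"].astype(float)
            b = meta.loc[outcome == 1, "age"].astype(float)
            _, p = stats.ttest_ind(a, b, equal_var=not welch)
            rows.append(
                {
                    "outcome": outcome_name,
                    "variable": "age",
                    "level": "mean",
                    "n_low": round(a.mean(), 1),
                    "n_high": round(b.mean(), 1),
                    "test": "welch_t" if welch else "student_t",
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
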