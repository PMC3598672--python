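"""Cohort demographics and challenge-response summaries.

Summarises an allergen-inhalation-challenge cohort: per-group age mean +/- SE,
geometric means of pre/post methacholine PC20 (the provocative concentration
producing a 20% FEV1 fall; log-normally distributed, hence the geometric
mean), the per-subject allergen-induced shift pre-PC20/post-PC20, and
one-way ANOVA comparisons of blood-count analytes among groups.

'ND' (not determined) entries propagate as missing values: a shift is only
defined when both PC20 measurements exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "allergen_shift",
    "geometric_mean",
    "mean_se",
    "compare_groups_anova",
    "read_subjects",
    "summarize_cohort",
    "CohortSummary",
    "demo_subjects",
    "demo_differentials",
]


class CohortError(ValueError):
    pass


# Bundled example cohort (synthetic-free printed inputs): seven mild atopic
# asthmatics challenged with cat allergen plus four healthy controls, with
# pre/post methacholine PC20 in mg/ml. 'ND' = not determined.
_DEMO_SUBJECTS_CSV = """\
subject_id,group,age,sex,allergen,pc20_pre,pc20_post
1,asthmatic,28,F,Cat Pelt,12.8,ND
2,asthmatic,34,F,Cat Pelt,2.7,6.1
3,asthmatic,27,M,Cat Pelt,4.5,1.8
4,asthmatic,42,F,Cat Hair,5.3,8.6
5,asthmatic,23,F,Cat Hair,0.3,0.2
6,asthmatic,26,F,Cat Hair,5.1,1.5
7,asthmatic,49,F,Cat Hair,3.6,1
HC1,HC,33,F,ND,,
HC2,HC,43,F,ND,,
HC3,HC,21,M,ND,,
HC4,HC,43,M,ND,,
"""

# Matching leukocyte differentials (group mean percentages, SE in
# parentheses omitted -> separate columns) for the same kind of cohort.
_DEMO_DIFFERENTIALS_CSV = """\
analyte,HC_mean,HC_se,pre_mean,pre_se,post_mean,post_se
neutrophils,56.4,7.8,57.9,4.5,65.0,2.6
lymphocytes,29.6,5.5,29.5,4.4,25.6,2.6
monocytes,4.5,0.7,7.4,0.7,5.7,0.8
eosinophils,2.1,0.6,4.7,0.8,3.3,0.7
basophils,5.6,5.5,0.5,0.1,0.4,0.1
"""


def demo_subjects() -> pd.DataFrame:
    """The bundled example demographics table."""
    return _parse_subjects(pd.read_csv(StringIO(_DEMO_SUBJECTS_CSV)))


def demo_differentials() -> pd.DataFrame:
    """Bundled example leukocyte differentials (group mean/SE percentages)."""
    return pd.read_csv(StringIO(_DEMO_DIFFERENTIALS_CSV), index_col=0)


def _parse_subjects(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("pc20_pre", "pc20_post"):
        df[col] = pd.to_numeric(df[col].replace("ND", np.nan), errors="coerce")
        neg = df[col] <= 0
        if neg.any():
            raise CohortError(f"non-positive PC20 in column {col}")
    hc_with_pc20 = (df["group"] == "HC") & df[["pc20_pre", "pc20_post"]].notna().any(axis=1)
    if hc_with_pc20.any():
        raise CohortError("healthy-control records must not carry PC20 values")
    return df


def read_subjects(path) -> pd.DataFrame:
    """Read a subject table (subject_id, group, age, sex, allergen,
    pc20_pre, pc20_post); 'ND' and blanks become missing."""
    return _parse_subjects(pd.read_csv(path))


def allergen_shift(pc20_pre, pc20_post) -> float:
    """Allergen-induced shift = pre PC20 / post PC20 (ND in -> ND out)."""
    if pc20_pre is None or pc20_post is None:
        return math.nan
    pre, post = float(pc20_pre), float(pc20_post)
    if math.isnan(pre) or math.isnan(post):
        return math.nan
    if pre <= 0 or post <= 0:
        raise CohortError("PC20 values must be > 0")
    return pre / post


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (table display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def geometric_mean(values) -> float:
    """exp(mean(ln x)) over the non-missing values."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size == 0:
        raise CohortError("no values for geometric mean")
    if (x <= 0).any():
        raise CohortError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def mean_se(values, convention: str = "population") -> tuple[float, float]:
    """Mean and standard error; the sd denominator is n (``population``,
    default) or n-1 (``sample``)."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size < 2:
        raise CohortError("mean_se needs n >= 2")
    ddof = 0 if convention == "population" else 1
    if convention not in ("population", "sample"):
        raise CohortError("convention must be 'population' or 'sample'")
    return float(x.mean()), float(x.std(ddof=ddof) / np.sqrt(x.size))


def compare_groups_anova(values, labels) -> float:
    """One-way ANOVA p-value across the label groups (equals the two-sided
    equal-variance t-test p for two groups)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise CohortError("need >= 2 groups")
    for g, arr in zip(pd.unique(labels), groups):
        if arr.size < 2:
            raise CohortError(f"group {g!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*groups)
    if np.isnan(p) and np.allclose(f, 0):
        return 1.0
    return float(p)


@dataclass
class CohortSummary:
    age_mean_se: dict
    pc20_pre_geomean: float
    pc20_post_geomean: float
    shifts: pd.Series
    shift_mean_se: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for grp, (m, se) in self.age_mean_se.items():
            rows.append({"quantity": f"age_mean_{grp}", "value": m})
            rows.append({"quantity": f"age_se_{grp}", "value": se})
        rows += [
            {"quantity": "pc20_pre_geomean", "value": self.pc20_pre_geomean},
            {"quantity": "pc20_post_geomean", "value": self.pc20_post_geomean},
            {"quantity": "shift_mean", "value": self.shift_mean_se[0]},
            {"quantity": "shift_se", "value": self.shift_mean_se[1]},
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Cohort summary", "=============="]
        for grp, (m, se) in self.age_mean_se.items():
            lines.append(f"age ({grp}): {m:.1f} +/- {se:.1f}")
        lines.append(f"geometric mean PC20 pre:  {self.pc20_pre_geomean:.1f} mg/ml")
        lines.append(f"geometric mean PC20 post: {self.pc20_post_geomean:.1f} mg/ml")
        shifts = ", ".join(f"{round_sig(v, 2):g}" for v in self.shifts.dropna())
        lines.append(f"allergen-induced shifts (pre/post): {shifts}")
        m, se = self.shift_mean_se
        lines.append(f"shift mean +/- SE: {m:.1f} +/- {se:.1f}")
        return "\n".join(lines)


def summarize_cohort(subjects: pd.DataFrame, se_convention: str = "population") -> CohortSummary:
    """Derived demographics: per-group age mean/SE, PC20 geometric means,
    per-subject shifts and their mean/SE. Display rounding is applied only in
    ``summary()``; all stored values are unrounded."""
    subjects = _parse_subjects(subjects)
    ages = {
        grp: mean_se(sub["age"], convention=se_convention)
        for grp, sub in subjects.groupby("group", sort=True)
    }
    asthma = subjects[subjects["group"] != "HC"]
    shifts = pd.Series(
        [allergen_shift(a, b) for a, b in zip(asthma["pc20_pre"], asthma["pc20_post"])],
        index=asthma["subject_id"].to_numpy(),
        name="shift",
    )
    return CohortSummary(
        age_mean_se=ages,
        pc20_pre_geomean=geometric_mean(asthma["pc20_pre"]),
        pc20_post_geomean=geometric_mean(asthma["pc20_post"]),
        shifts=shifts,
        shift_mean_se=mean_se(shifts, convention=se_convention),
    )
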