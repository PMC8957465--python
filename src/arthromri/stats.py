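"""Study statistics from first principles.

Implements the study's inferential stage: a two-sample paired t-test for
the pre/post synovial-volume comparison, one-way ANOVA for the bleed
frequencies, and a df-1 chi-square comparison of per-level detection rates
between a measurement arm and pathology.  Tail probabilities for t and F
come from the package's own continued-fraction regularized incomplete beta
function; the chi-square(1) tail uses the closed form ``erfc(sqrt(x/2))``.
All tests are two-sided with significance declared at alpha = 0.05 and no
multiple-testing correction (a deliberate mirror of the emulated study —
see docs/methods.md for the caveat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .cohort import ARMS, CohortTable

__all__ = [
    "TestResult",
    "ContingencyTable",
    "DegenerateDataError",
    "regularized_incomplete_beta",
    "student_t_p_two_sided",
    "f_p_value",
    "chi2_df1_p_value",
    "paired_t_test",
    "one_way_anova",
    "detection_rate_comparison",
    "agreement_summary",
]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """The test statistic is undefined on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: Union[float, tuple]
    p_value: float
    test_name: str
    n: Union[int, tuple]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = raters (method, pathology), columns =
    (grades == level, grades != level)."""

    a: int
    b: int
    c: int
    d: int
    level: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


# ---------------------------------------------------------------- special

def _betacf(a: float, b: float, x: float, tol: float = 1e-12,
            max_iter: int = 500) -> float:
    """Continued fraction for the incomplete beta (modified Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < tol:
            return h
    raise RuntimeError(f"incomplete beta did not converge for a={a}, b={b}, x={x}")


def regularized_incomplete_beta(a: float, b: float, x: float) -> float:
    """``I_x(a, b)``, the regularized incomplete beta function.

    Continued-fraction evaluation with the symmetry
    ``I_x(a,b) = 1 - I_{1-x}(b,a)`` applied outside the rapidly convergent
    region; relative accuracy ~1e-12.
    """
    if not 0 <= x <= 1:
        raise ValueError(f"x must be in [0, 1], got {x}")
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be > 0")
    if x == 0.0:
        return 0.0
    if x == 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def student_t_p_two_sided(t: float, df: float) -> float:
    """Two-sided p-value of Student's t: ``I_{df/(df+t^2)}(df/2, 1/2)``."""
    if df <= 0:
        raise ValueError(f"df must be > 0, got {df}")
    if t == 0:
        return 1.0
    x = df / (df + t * t)
    return min(1.0, regularized_incomplete_beta(df / 2.0, 0.5, x))


def f_p_value(f: float, df1: float, df2: float) -> float:
    """Upper-tail p-value of the F distribution."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be > 0")
    if f <= 0:
        return 1.0
    x = df2 / (df2 + df1 * f)
    return min(1.0, regularized_incomplete_beta(df2 / 2.0, df1 / 2.0, x))


def chi2_df1_p_value(x: float) -> float:
    """Upper-tail p-value of chi-square with 1 df: ``erfc(sqrt(x/2))``."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    return math.erfc(math.sqrt(x / 2.0))


# ------------------------------------------------------------------ tests

def paired_t_test(pre, post) -> TestResult:
    """Two-sided paired t-test on matched samples.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = pre - post`` and sample
    (n-1) standard deviation; df = n - 1.
    """
    a = np.asarray(pre, dtype=np.float64)
    b = np.asarray(post, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D samples")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return TestResult(0.0, n - 1, 1.0, "paired_t", n)
        raise DegenerateDataError("degenerate: all differences equal")
    t = mean / (sd / math.sqrt(n))
    return TestResult(float(t), n - 1, student_t_p_two_sided(t, n - 1),
                      "paired_t", n)


def one_way_anova(groups) -> TestResult:
    """One-way (one-factor) analysis of variance across k groups.

    ``F = (SSB / (k-1)) / (SSW / (N-k))`` with the usual between/within sum
    of squares decomposition.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    k = len(arrays)
    N = all_values.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ssw == 0:
        raise DegenerateDataError("degenerate: zero within-group variance")
    f = (ssb / (k - 1)) / (ssw / (N - k))
    return TestResult(float(f), (k - 1, N - k), f_p_value(f, k - 1, N - k),
                      "one_way_anova", tuple(g.size for g in arrays))


def detection_rate_comparison(
    method_grades, pathology_grades, level: int, yates: bool = False
) -> tuple[TestResult, ContingencyTable]:
    """Compare one arm's detection rate of a score level against pathology.

    Builds the 2x2 table (rater x grades-at-level-or-not) over the jointly
    graded assessments and returns the df-1 chi-square
    ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, Yates-corrected on request.
    """
    if level not in (0, 1, 2, 3):
        raise ValueError(f"level must be a grade 0-3, got {level}")
    m = np.asarray(method_grades, dtype=np.float64)
    p = np.asarray(pathology_grades, dtype=np.float64)
    if m.shape != p.shape or m.ndim != 1:
        raise ValueError("grade vectors must be aligned 1-D arrays")
    ok = ~(np.isnan(m) | np.isnan(p))
    m, p = m[ok], p[ok]
    n_joints = m.size
    if n_joints == 0:
        raise DegenerateDataError("no jointly graded assessments")
    a = int((m == level).sum())
    b = n_joints - a
    c = int((p == level).sum())
    d = n_joints - c
    table = ContingencyTable(a=a, b=b, c=c, d=d, level=level)
    if (a + c) == 0 or (b + d) == 0:
        raise DegenerateDataError(
            f"level {level} absent (or universal) in both raters; test undefined"
        )
    N = table.n
    det = abs(a * d - b * c)
    if yates:
        det = max(0.0, det - N / 2.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = N * det**2 / denom
    return (
        TestResult(float(chi2), 1, chi2_df1_p_value(chi2), "chi2_detection_rate",
                   (n_joints, n_joints)),
        table,
    )


def agreement_summary(cohort: CohortTable, lesion: str,
                      yates: bool = False) -> dict:
    """Per-level counts and method-vs-pathology tests for one lesion class.

    Returns ``{"counts": DataFrame, "tests": {(arm, level): TestResult}}``;
    a level whose comparison is undefined (absent everywhere) maps to None.
    """
    present = set(cohort.assessments["lesion"].unique())
    if lesion not in present:
        raise ValueError(f"lesion {lesion!r} not in cohort ({sorted(present)})")
    for arm in ARMS:
        if arm not in cohort.assessments.columns:
            raise ValueError(f"cohort is missing arm {arm!r}")
    levels = sorted(
        int(l) for l in np.unique(cohort.arm_grades(lesion, "pathology"))
        if not np.isnan(l)
    )
    counts = pd.DataFrame(
        {arm: pd.Series(cohort.grade_counts(lesion, arm)) for arm in ARMS}
    ).reindex(levels).fillna(0).astype(int)
    counts.index.name = "level"
    pathology = cohort.arm_grades(lesion, "pathology")
    tests = {}
    for arm in ("conventional_mri", "canny_mri"):
        grades = cohort.arm_grades(lesion, arm)
        for level in levels:
            try:
                result, _ = detection_rate_comparison(
                    grades, pathology, level, yates=yates
                )
            except DegenerateDataError:
                result = None
            tests[(arm, level)] = result
    return {"counts": counts, "tests": tests}
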