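"""Cohort summaries and unpaired two-sample t-tests.

The group comparisons of the original study can be reproduced both from
raw cohorts and from printed summary statistics (n, mean, SD), so the
t-test is implemented directly from the textbook formulas:

pooled (Student):
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)
    t = (m1 - m2) / sqrt(s_p^2 (1/n1 + 1/n2)),  df = n1 + n2 - 2

Welch:
    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
    df by Welch-Satterthwaite.

Two-sided p-values come from the t distribution (scipy.stats.t).  Fed a
raw sample's own summaries, the result is identical to a raw-data
t-test — a property the test suite verifies against
``scipy.stats.ttest_ind`` as an independent oracle.

Percentages in reports are rounded half-up to whole percent, matching
the presentation convention of the derivation study (e.g. 21/46 = 45.65%
→ 46%).  No multiple-testing correction is applied (none was used in
the derivation study); reports state the number of tests performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core import ValidationError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "t_test_from_summary",
    "t_test_raw",
    "compare_remission_groups",
    "round_half_up_percent",
]


def round_half_up_percent(fraction: float) -> int:
    """Round a fraction to a whole percentage, halves up (0.4565 → 46)."""
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD (n-1 denominator), min and max of one group."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("a group summary needs n >= 1")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("min <= mean <= max must hold")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TTestResult:
    """Two-sided unpaired t-test result, labelled with its variant."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str  # "pooled" | "welch"

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(values: Sequence[float]) -> GroupSummary:
    """Sample mean, SD (n-1 denominator; 0 for n = 1), min and max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty list")
    if not np.isfinite(arr).all():
        raise ValidationError("values must be finite")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def t_test_from_summary(
    g1: GroupSummary, g2: GroupSummary, variant: str = "welch"
) -> TTestResult:
    """Unpaired two-sided t-test from two group summaries.

    ``variant`` selects pooled (classic Student) or Welch (unequal
    variances; the default).  Degenerate case: if both SDs are zero and
    the means are equal, t = 0 and p = 1 by convention; if both SDs are
    zero and the means differ, t is signed infinity and p = 0.
    """
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if g1.n < 2 or g2.n < 2:
        raise ValidationError("t-test needs n >= 2 in both groups")

    diff = g1.mean - g2.mean
    v1, v2 = g1.sd**2, g2.sd**2
    if g1.sd == 0.0 and g2.sd == 0.0:
        df = float(g1.n + g2.n - 2)
        if diff == 0:
            return TTestResult(0.0, df, 1.0, variant)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, variant)

    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    else:
        a, b = v1 / g1.n, v2 / g2.n
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (g1.n - 1) + b**2 / (g2.n - 1))

    t = diff / se
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, variant)


def t_test_raw(x: Sequence[float], y: Sequence[float], variant: str = "welch") -> TTestResult:
    """Unpaired t-test on raw samples via their summaries."""
    return t_test_from_summary(summarize(x), summarize(y), variant)


def compare_remission_groups(
    cohort: "pd.DataFrame | Iterable",
    variant: str = "welch",
) -> Dict[str, dict]:
    """Compare DRS between remitters and non-remitters, per procedure.

    ``cohort`` is a DataFrame (or iterable of objects) with at least
    ``drs_total`` and ``observed_remission``; rows are stratified by
    ``procedure`` when present (a missing procedure column forms a
    single ``"all"`` stratum).  Each stratum reports group summaries,
    the remission rate (exact fraction and half-up whole percent) and a
    two-sided t-test; strata with fewer than two patients in either
    group skip the test with an explicit flag.
    """
    if not isinstance(cohort, pd.DataFrame):
        rows = []
        for rec in cohort:
            rows.append(
                {
                    "drs_total": getattr(rec, "drs_total"),
                    "observed_remission": getattr(rec, "observed_remission"),
                    "procedure": getattr(getattr(rec, "procedure", None), "value", None),
                }
            )
        cohort = pd.DataFrame(rows)
    if "observed_remission" not in cohort and "remission" in cohort:
        cohort = cohort.rename(columns={"remission": "observed_remission"})
    if "drs_total" not in cohort or "observed_remission" not in cohort:
        raise ValidationError("cohort needs 'drs_total' and 'observed_remission' columns")
    if cohort["drs_total"].isna().any() or cohort["observed_remission"].isna().any():
        raise ValidationError("every record needs drs_total and observed_remission")

    work = cohort.copy()
    if "procedure" not in work or work["procedure"].isna().all():
        work["procedure"] = "all"

    report: Dict[str, dict] = {"strata": {}, "n_tests": 0, "t_test_variant": variant}
    for proc, grp in work.groupby("procedure", sort=True):
        remit = grp.loc[grp["observed_remission"].astype(bool), "drs_total"]
        non = grp.loc[~grp["observed_remission"].astype(bool), "drs_total"]
        n = len(grp)
        stratum: dict = {
            "n": int(n),
            "n_remitters": int(len(remit)),
            "remission_rate": float(len(remit) / n),
            "remission_rate_percent": round_half_up_percent(len(remit) / n),
            "remitters": summarize(remit).to_dict() if len(remit) else None,
            "non_remitters": summarize(non).to_dict() if len(non) else None,
        }
        if len(remit) >= 2 and len(non) >= 2:
            test = t_test_from_summary(summarize(remit), summarize(non), variant)
            stratum["t_test"] = test.to_dict()
            stratum["t_test_skipped"] = False
            report["n_tests"] += 1
        else:
            stratum["t_test"] = None
            stratum["t_test_skipped"] = True
        report["strata"][str(proc)] = stratum
    return report
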