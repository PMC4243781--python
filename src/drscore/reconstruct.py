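"""Brute-force reconstruction of per-score patient counts from printed aggregates.

No per-patient data were deposited for the derivation cohort, but its
printed aggregates (n, mean ± SD, observed range, remission counts,
band rules, remitter/non-remitter summaries) constrain the integer
count of patients at each DRS value tightly.  This module enumerates
*every* count vector over the observed score range that satisfies a
constraint set within stated tolerances — exhaustive search, so an
empty result is a proof of infeasibility for that set, not a search
failure.

Tolerances default to ±0.05 on means and SDs, mirroring the one-decimal
rounding of the printed values.  Whether the printed SDs used the n−1
or n denominator is unknowable, so a solution is accepted if either
matches, and each solution records which denominators fit.

Two presets ship per procedure:

* ``printed_constraints(proc)`` — every printed aggregate.  This set is
  *infeasible* for both procedures: for IISG the "35 % of DRS-9
  patients remitted" ratio forces at least 11 non-remitting DRS-9
  patients, pushing the non-remitter group far from its printed
  10.2 ± 0.9; for IIDSG the observed maximum score 14 places one
  non-remitter 2.0 above the printed non-remitter mean 12.0, so the
  printed SD 0.5 is arithmetically impossible (4 > (n−1)·0.55²).
* ``default_constraints(proc)`` — the same set without the
  remitter/non-remitter summaries (the aggregates the study itself
  prints twice under two different labels, hence the least
  trustworthy).  This set is feasible for both procedures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import Procedure, ValidationError
from .stats import round_half_up_percent
from . import published

__all__ = [
    "ConstraintSet",
    "ReconstructionSolution",
    "reconstruct_score_distribution",
    "check_solution",
    "solution_to_cohort",
    "printed_constraints",
    "default_constraints",
]

_MAX_N = 200
_MAX_WIDTH = 8


@dataclass(frozen=True)
class ConstraintSet:
    """Aggregate constraints on an integer score distribution.

    Only ``n``, the score range and the mean/SD are mandatory; the
    remission-structure and subgroup-summary constraints are optional
    and simply not enforced when ``None``.
    """

    n: int
    score_min: int
    score_max: int
    mean: float
    sd: float
    mean_tol: float = 0.05
    sd_tol: float = 0.05
    #: require at least one patient at each end of the range (an
    #: observed range implies occupied endpoints)
    require_endpoints: bool = True
    remission_total: Optional[int] = None
    all_remit_max_score: Optional[int] = None
    none_remit_min_score: Optional[int] = None
    partial_score: Optional[int] = None
    partial_percent: Optional[int] = None
    remitter_summary: Optional[Tuple[float, float]] = None  # (mean, sd)
    non_remitter_summary: Optional[Tuple[float, float]] = None
    subgroup_mean_tol: float = 0.05
    subgroup_sd_tol: float = 0.05

    @property
    def scores(self) -> List[int]:
        return list(range(self.score_min, self.score_max + 1))

    def has_remission_structure(self) -> bool:
        return self.remission_total is not None


@dataclass(frozen=True)
class ReconstructionSolution:
    """One feasible integer count vector, with its remission split.

    ``sd_denominators`` (and the subgroup analogues) record which SD
    convention(s) the solution matches: ``"n-1"``, ``"n"`` or both.
    """

    counts: Dict[int, int]
    remission_counts: Optional[Dict[int, int]]
    mean: float
    sd_n1: float
    sd_n: float
    sd_denominators: Tuple[str, ...]
    remitter_sd_denominators: Tuple[str, ...] = ()
    non_remitter_sd_denominators: Tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def remission_total(self) -> Optional[int]:
        if self.remission_counts is None:
            return None
        return sum(self.remission_counts.values())


def _matching_denominators(ss: float, n: int, target_sd: float, tol: float) -> Tuple[str, ...]:
    out = []
    if n > 1 and abs(math.sqrt(ss / (n - 1)) - target_sd) <= tol + 1e-12:
        out.append("n-1")
    if n > 0 and abs(math.sqrt(ss / n) - target_sd) <= tol + 1e-12:
        out.append("n")
    return tuple(out)


def _remission_split(
    counts: List[int], scores: List[int], cs: ConstraintSet
) -> Optional[Dict[int, int]]:
    """Derive the per-score remitter counts implied by the band rules.

    Returns None when the band structure cannot place exactly
    ``remission_total`` remitters.
    """
    idx = {s: i for i, s in enumerate(scores)}
    split = {s: 0 for s in scores}
    full = 0
    for s in scores:
        if cs.all_remit_max_score is not None and s <= cs.all_remit_max_score:
            split[s] = counts[idx[s]]
            full += counts[idx[s]]
    assert cs.remission_total is not None
    partial = cs.remission_total - full
    if cs.partial_score is not None and cs.partial_score in idx:
        cap = counts[idx[cs.partial_score]]
        if not (0 <= partial <= cap):
            return None
        split[cs.partial_score] = partial
        if cs.partial_percent is not None:
            if cap == 0 or round_half_up_percent(partial / cap) != cs.partial_percent:
                return None
    elif partial != 0:
        return None
    if cs.none_remit_min_score is not None:
        # by construction no remitters were placed at or above this score
        assert all(split[s] == 0 for s in scores if s >= cs.none_remit_min_score)
    return split


def _subgroup_ok(
    values: List[int], target: Optional[Tuple[float, float]], mean_tol: float, sd_tol: float
) -> Optional[Tuple[str, ...]]:
    """Check one subgroup summary; return matching SD denominators or None."""
    if target is None:
        return ()
    t_mean, t_sd = target
    n = len(values)
    if n == 0:
        return None
    m = sum(values) / n
    if abs(m - t_mean) > mean_tol + 1e-12:
        return None
    ss = sum((v - m) ** 2 for v in values)
    denoms = _matching_denominators(ss, n, t_sd, sd_tol)
    return denoms or None


def reconstruct_score_distribution(
    constraints: ConstraintSet, max_solutions: Optional[int] = None
) -> List[ReconstructionSolution]:
    """Enumerate every feasible count vector, in lexicographic order.

    The search is a depth-first enumeration of compositions of ``n``
    over the score range, pruned by bounds on the achievable score sum;
    every surviving vector is checked against the full constraint set.
    Raises before searching when ``n`` or the range width would make
    exhaustive enumeration intractable.
    """
    cs = constraints
    if cs.n > _MAX_N:
        raise ValidationError(f"n = {cs.n} exceeds the exhaustive-search limit {_MAX_N}")
    if cs.score_max < cs.score_min:
        raise ValidationError("score_max must be >= score_min")
    width = cs.score_max - cs.score_min + 1
    if width > _MAX_WIDTH:
        raise ValidationError(f"score range width {width} exceeds the limit {_MAX_WIDTH}")

    scores = cs.scores
    k = len(scores)
    sum_lo = cs.n * (cs.mean - cs.mean_tol) - 1e-9
    sum_hi = cs.n * (cs.mean + cs.mean_tol) + 1e-9
    min_count_end = 1 if cs.require_endpoints else 0

    solutions: List[ReconstructionSolution] = []
    counts = [0] * k

    def emit(counts: List[int]) -> None:
        total = sum(c * s for c, s in zip(counts, scores))
        m = total / cs.n
        ss = sum(c * (s - m) ** 2 for c, s in zip(counts, scores))
        denoms = _matching_denominators(ss, cs.n, cs.sd, cs.sd_tol)
        if not denoms:
            return
        remission: Optional[Dict[int, int]] = None
        rem_denoms: Tuple[str, ...] = ()
        non_denoms: Tuple[str, ...] = ()
        if cs.has_remission_structure():
            remission = _remission_split(counts, scores, cs)
            if remission is None:
                return
            remit_vals: List[int] = []
            non_vals: List[int] = []
            idx = {s: i for i, s in enumerate(scores)}
            for s in scores:
                remit_vals += [s] * remission[s]
                non_vals += [s] * (counts[idx[s]] - remission[s])
            r = _subgroup_ok(remit_vals, cs.remitter_summary, cs.subgroup_mean_tol, cs.subgroup_sd_tol)
            if r is None:
                return
            nr = _subgroup_ok(
                non_vals, cs.non_remitter_summary, cs.subgroup_mean_tol, cs.subgroup_sd_tol
            )
            if nr is None:
                return
            rem_denoms, non_denoms = r, nr
        solutions.append(
            ReconstructionSolution(
                counts={s: c for s, c in zip(scores, counts)},
                remission_counts=remission,
                mean=m,
                sd_n1=math.sqrt(ss / (cs.n - 1)) if cs.n > 1 else 0.0,
                sd_n=math.sqrt(ss / cs.n),
                sd_denominators=denoms,
                remitter_sd_denominators=rem_denoms,
                non_remitter_sd_denominators=non_denoms,
            )
        )

    def dfs(pos: int, used: int, partial_sum: float) -> None:
        if max_solutions is not None and len(solutions) >= max_solutions:
            return
        remaining = cs.n - used
        if pos == k - 1:
            if remaining < min_count_end:
                return
            total = partial_sum + remaining * scores[pos]
            if sum_lo <= total <= sum_hi:
                counts[pos] = remaining
                emit(counts.copy())
            return
        # bounds on the final sum given all remaining mass goes low/high
        if partial_sum + remaining * scores[pos] > sum_hi:
            return
        if partial_sum + remaining * scores[k - 1] < sum_lo:
            return
        lo_c = min_count_end if pos == 0 else 0
        for c in range(lo_c, remaining + 1):
            counts[pos] = c
            dfs(pos + 1, used + c, partial_sum + c * scores[pos])
        counts[pos] = 0

    if k == 1:
        counts[0] = cs.n
        if sum_lo <= cs.n * scores[0] <= sum_hi:
            emit(counts)
    else:
        dfs(0, 0, 0.0)
    return solutions


def check_solution(solution: ReconstructionSolution, constraints: ConstraintSet) -> bool:
    """Re-validate a solution against the constraints, independently of the search.

    Expands the counts into an explicit multiset and re-derives every
    statistic with numpy — double-entry bookkeeping for the solver.
    """
    cs = constraints
    values = np.array(
        [s for s, c in sorted(solution.counts.items()) for _ in range(c)], dtype=float
    )
    if values.size != cs.n:
        return False
    if any(c < 0 for c in solution.counts.values()):
        return False
    if set(solution.counts) != set(cs.scores):
        return False
    if cs.require_endpoints:
        if solution.counts[cs.score_min] < 1 or solution.counts[cs.score_max] < 1:
            return False
    if abs(values.mean() - cs.mean) > cs.mean_tol + 1e-9:
        return False
    if not (
        abs(values.std(ddof=1) - cs.sd) <= cs.sd_tol + 1e-9
        or abs(values.std(ddof=0) - cs.sd) <= cs.sd_tol + 1e-9
    ):
        return False

    if not cs.has_remission_structure():
        return True
    rem = solution.remission_counts
    if rem is None:
        return False
    if any(rem.get(s, 0) < 0 or rem.get(s, 0) > solution.counts[s] for s in cs.scores):
        return False
    if sum(rem.values()) != cs.remission_total:
        return False
    if cs.all_remit_max_score is not None:
        if any(rem[s] != solution.counts[s] for s in cs.scores if s <= cs.all_remit_max_score):
            return False
    if cs.none_remit_min_score is not None:
        if any(rem[s] != 0 for s in cs.scores if s >= cs.none_remit_min_score):
            return False
    if cs.partial_percent is not None and cs.partial_score is not None:
        cap = solution.counts[cs.partial_score]
        if cap == 0 or round_half_up_percent(rem[cs.partial_score] / cap) != cs.partial_percent:
            return False
    for target, tol_key, member in (
        (cs.remitter_summary, cs.subgroup_mean_tol, True),
        (cs.non_remitter_summary, cs.subgroup_mean_tol, False),
    ):
        if target is None:
            continue
        sub = np.array(
            [
                s
                for s in cs.scores
                for _ in range(rem[s] if member else solution.counts[s] - rem[s])
            ],
            dtype=float,
        )
        if sub.size == 0:
            return False
        if abs(sub.mean() - target[0]) > cs.subgroup_mean_tol + 1e-9:
            return False
        if not (
            abs(sub.std(ddof=1) - target[1]) <= cs.subgroup_sd_tol + 1e-9
            or abs(sub.std(ddof=0) - target[1]) <= cs.subgroup_sd_tol + 1e-9
        ):
            return False
    return True


def solution_to_cohort(
    solution: ReconstructionSolution, procedure: "Procedure | str"
) -> pd.DataFrame:
    """Expand a solution into a minimal per-patient table.

    Columns: patient_id, procedure, drs_total, observed_remission —
    exactly what :func:`drscore.stats.compare_remission_groups` needs.
    """
    procedure = Procedure.coerce(procedure)
    rows = []
    i = 0
    for score in sorted(solution.counts):
        n_rem = (solution.remission_counts or {}).get(score, 0)
        for j in range(solution.counts[score]):
            i += 1
            rows.append(
                {
                    "patient_id": f"{procedure.value}-R{i:03d}",
                    "procedure": procedure.value,
                    "drs_total": score,
                    "observed_remission": j < n_rem,
                }
            )
    return pd.DataFrame(rows)


def _base_constraints(procedure: "Procedure | str") -> ConstraintSet:
    proc = Procedure.coerce(procedure)
    agg = published.COHORTS[proc]
    return ConstraintSet(
        n=agg["n"],
        score_min=agg["drs_range"][0],
        score_max=agg["drs_range"][1],
        mean=agg["drs_mean"],
        sd=agg["drs_sd"],
        remission_total=agg["remitters"],
        all_remit_max_score=agg["all_remit_max_score"],
        none_remit_min_score=agg["none_remit_min_score"],
        partial_score=agg["partial_score"],
        partial_percent=agg["partial_percent"],
    )


def printed_constraints(procedure: "Procedure | str") -> ConstraintSet:
    """Every printed aggregate, including the remitter/non-remitter summaries.

    Demonstrably infeasible for both procedures (see module docstring);
    kept as a preset precisely so that the infeasibility is a computed,
    reproducible fact rather than an assertion.
    """
    proc = Procedure.coerce(procedure)
    agg = published.COHORTS[proc]
    return replace(
        _base_constraints(proc),
        remitter_summary=(agg["remitter_summary"]["mean"], agg["remitter_summary"]["sd"]),
        non_remitter_summary=(
            agg["non_remitter_summary"]["mean"],
            agg["non_remitter_summary"]["sd"],
        ),
    )


def default_constraints(procedure: "Procedure | str") -> ConstraintSet:
    """The feasible preset: all printed aggregates except the subgroup summaries."""
    return _base_constraints(procedure)
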