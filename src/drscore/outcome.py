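"""Remission-probability bands over the DRS and the procedure recommendation.

The derivation cohort's observed remission pattern is a step function of
the total DRS within each procedure:

* IISG:  DRS 7-8 → 1.00, DRS 9 → 0.35, DRS >= 10 → 0.00
* IIDSG: DRS 8-10 → 1.00, DRS 11 → 0.55, DRS >= 12 → 0.00

DRS 7 was never observed under IIDSG (observed range 8-14); evaluating
it extrapolates the adjacent all-remit band and raises
:class:`OutsideObservedRangeWarning` rather than returning silently.

The bands live in a JSON config shipped with the package
(``data/outcome_bands.json``); users may load a modified copy, with the
derivation cohort's values as defaults.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

from .core import Grade, Procedure, ValidationError, grade_for_total, SCORE_MAX, SCORE_MIN

__all__ = [
    "OutcomeModel",
    "OutsideObservedRangeWarning",
    "predict_remission",
    "recommend_procedure",
    "load_default_model",
]


class OutsideObservedRangeWarning(UserWarning):
    """The requested score lies outside the procedure's observed DRS range."""


@dataclass(frozen=True, order=True)
class _Band:
    lo: int
    hi: int
    probability: float


class OutcomeModel:
    """Per-procedure ordered (score interval → remission probability) bands.

    Bands must be disjoint, cover DRS 7-14, and be non-increasing in the
    score within each procedure.
    """

    def __init__(
        self,
        bands: Dict[Procedure, List[Tuple[int, int, float]]],
        observed_range: Dict[Procedure, Tuple[int, int]],
    ) -> None:
        self._bands: Dict[Procedure, List[_Band]] = {}
        for proc, spec in bands.items():
            parsed = sorted(_Band(lo, hi, p) for lo, hi, p in spec)
            covered = [s for b in parsed for s in range(b.lo, b.hi + 1)]
            if sorted(covered) != list(range(SCORE_MIN, SCORE_MAX + 1)):
                raise ValidationError(
                    f"{proc.value}: bands must partition DRS {SCORE_MIN}-{SCORE_MAX}"
                )
            probs = [b.probability for b in parsed]
            if any(not 0 <= p <= 1 for p in probs):
                raise ValidationError(f"{proc.value}: probabilities must lie in [0, 1]")
            if any(a < b for a, b in zip(probs, probs[1:])):
                raise ValidationError(
                    f"{proc.value}: remission probability must be non-increasing in DRS"
                )
            self._bands[proc] = parsed
        self.observed_range = dict(observed_range)

    @classmethod
    def from_config(cls, config: dict) -> "OutcomeModel":
        bands = {
            Procedure.coerce(proc): [(b["scores"][0], b["scores"][1], b["probability"]) for b in spec]
            for proc, spec in config["bands"].items()
        }
        observed = {
            Procedure.coerce(proc): (lo, hi)
            for proc, (lo, hi) in config.get("observed_range", {}).items()
        }
        return cls(bands, observed)

    def predict_remission(
        self, drs_total: int, procedure: "Procedure | str", *, warn_extrapolation: bool = True
    ) -> float:
        """Remission probability for a DRS total under one procedure.

        Warns with :class:`OutsideObservedRangeWarning` when the score
        was never observed under that procedure in the derivation cohort.
        """
        procedure = Procedure.coerce(procedure)
        if drs_total != int(drs_total) or not (SCORE_MIN <= drs_total <= SCORE_MAX):
            raise ValidationError(
                f"drs_total must be an integer in [{SCORE_MIN}, {SCORE_MAX}], got {drs_total!r}"
            )
        drs_total = int(drs_total)
        rng = self.observed_range.get(procedure)
        if warn_extrapolation and rng is not None and not (rng[0] <= drs_total <= rng[1]):
            warnings.warn(
                f"DRS {drs_total} is outside the observed {procedure.value} range "
                f"{rng[0]}-{rng[1]}; the returned probability is an extrapolation",
                OutsideObservedRangeWarning,
                stacklevel=2,
            )
        for band in self._bands[procedure]:
            if band.lo <= drs_total <= band.hi:
                return band.probability
        raise AssertionError("bands cover 7-14 by construction")  # pragma: no cover

    def recommend_procedure(self, drs_total: int) -> Optional[Procedure]:
        """Procedure recommendation from the DRS grade.

        Mild disease (DRS 7-8) → IISG only; moderate (9-11) → IIDSG;
        severe (12-14) → ``None``: remission is not expected under
        either studied procedure.
        """
        grade = grade_for_total(int(drs_total))
        if grade is Grade.grade1:
            return Procedure.IISG
        if grade is Grade.grade2:
            return Procedure.IIDSG
        return None


def load_default_model() -> OutcomeModel:
    """Load the band config shipped with the package."""
    text = resources.files("drscore.data").joinpath("outcome_bands.json").read_text()
    return OutcomeModel.from_config(json.loads(text))


_default: Optional[OutcomeModel] = None


def _model() -> OutcomeModel:
    global _default
    if _default is None:
        _default = load_default_model()
    return _default


def predict_remission(
    drs_total: int, procedure: "Procedure | str", *, warn_extrapolation: bool = True
) -> float:
    """Module-level convenience over the default :class:`OutcomeModel`."""
    return _model().predict_remission(drs_total, procedure, warn_extrapolation=warn_extrapolation)


def recommend_procedure(drs_total: int) -> Optional[Procedure]:
    """Module-level convenience over the default :class:`OutcomeModel`."""
    return _model().recommend_procedure(drs_total)
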