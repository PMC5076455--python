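"""Plate-matched case/reference designs for compound-perturbation data.

Perturbation screens (LINCS L1000-style) confound treatment with RNA
plate; the reference for each compound is therefore restricted to vehicle
(DMSO) wells that sit on the same plate(s) as the treated wells, which
cancels plate effects in the case-reference comparison.
"""

from __future__ import annotations

import logging
from typing import Sequence

from geroscope.io import GroupDesign, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)

#: relative tolerance for dose matching; annotation files round doses
#: inconsistently (e.g. 70.07 uM)
DOSE_RTOL = 0.01


def _dose_matches(dose: float | None, wanted: float | None) -> bool:
    if wanted is None:
        return True
    if dose is None:
        return False
    return abs(dose - wanted) <= DOSE_RTOL * abs(wanted)


def filter_cell_type(annotations: Sequence[SampleAnnotation], cell_type: str) -> list[SampleAnnotation]:
    """Restrict annotations to one cell line (a pre-step, not hard-coded)."""
    return [a for a in annotations if a.cell_type == cell_type]


def build_plate_matched_design(
    annotations: Sequence[SampleAnnotation],
    compound: str,
    dose: float | None = None,
    duration: float | None = None,
    vehicle: str = "DMSO",
) -> GroupDesign:
    """Case = samples treated with ``compound`` at the given dose/duration;
    reference = vehicle wells on the same plate(s) as the case wells.

    Dose is matched with 1% relative tolerance; ``dose``/``duration`` of
    None match any value.
    """
    case = [
        a
        for a in annotations
        if a.perturbagen == compound
        and _dose_matches(a.dose_um, dose)
        and (duration is None or a.duration_h == duration)
    ]
    if not case:
        raise ValidationError(
            f"no case samples for compound {compound!r} at dose {dose} uM, duration {duration} h"
        )
    case_plates = {a.plate for a in case if a.plate is not None}
    reference = [a for a in annotations if a.perturbagen == vehicle and a.plate in case_plates]
    if not reference:
        raise ValidationError(
            f"no {vehicle} reference wells on case plate(s) {sorted(case_plates)} for compound {compound!r}"
        )
    return GroupDesign(
        name=compound,
        case_ids=frozenset(a.sample_id for a in case),
        reference_ids=frozenset(a.sample_id for a in reference),
    )


def build_all_designs(
    annotations: Sequence[SampleAnnotation],
    compounds: Sequence[str],
    dose: float | None = None,
    duration: float | None = None,
    vehicle: str = "DMSO",
    dose_overrides: dict[str, float] | None = None,
) -> list[GroupDesign]:
    """Build one plate-matched design per compound, skipping (and logging)
    compounds that lack case samples or same-plate vehicle wells.

    ``dose_overrides`` maps compound name to a non-default dose.
    """
    dose_overrides = dose_overrides or {}
    designs = []
    for compound in compounds:
        try:
            designs.append(
                build_plate_matched_design(
                    annotations,
                    compound,
                    dose=dose_overrides.get(compound, dose),
                    duration=duration,
                    vehicle=vehicle,
                )
            )
        except ValidationError as exc:
            logger.warning("skipping compound %s: %s", compound, exc)
    if not designs:
        raise ValidationError("no compound yielded a valid plate-matched design")
    return designs
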