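"""Pathway Activation Strength (PAS).

PAS summarizes a case-reference comparison at the pathway level:

    PAS_p = sum over member genes n of  ARR_n * BTIF_n * log(CNR_n)

with ARR the member's signed activator/repressor weight, BTIF the binary
FDR-significance gate from the differential-expression step, CNR the
case-to-normal expression ratio, and the logarithm taken base 10 by
default.  Positive PAS means the pathway is up-regulated in the case
state, negative means down-regulated.

Case entities may be a whole group (group-level CNR and BTIF) or single
case samples; per-sample scoring reuses the group-level BTIF because a
single sample cannot support a t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from geroscope.diffexpr import (
    DEFAULT_ALPHA,
    DEFAULT_EPSILON,
    DEResult,
    differential_expression,
    per_sample_cnr,
)
from geroscope.io import ExpressionMatrix, GroupDesign, Pathway, PathwayDB, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_LOG_BASE = 10.0


@dataclass
class PASProfile:
    """PAS values for case entities (rows) across pathways (columns).

    ``no_coverage`` marks cells where no pathway member was measured at
    all: such cells hold a placeholder 0 that is distinct from a measured
    zero activation.
    """

    values: pd.DataFrame
    no_coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.no_coverage.columns) or list(
            self.values.index
        ) != list(self.no_coverage.index):
            raise ValidationError("PAS values and no-coverage flags must share shape and labels")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValidationError("PAS values must be finite")

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path, flags_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "entity"
        out.to_csv(path, sep="\t")
        if flags_path is not None:
            flags = self.no_coverage.astype(int).copy()
            flags.index.name = "entity"
            flags.to_csv(flags_path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, flags_path: str | Path | None = None) -> "PASProfile":
        values = pd.read_csv(path, sep="\t", index_col=0)
        if flags_path is not None:
            flags = pd.read_csv(flags_path, sep="\t", index_col=0).astype(bool)
        else:
            flags = pd.DataFrame(False, index=values.index, columns=values.columns)
        return cls(values=values, no_coverage=flags)


def _pas_one(cnr: pd.Series, btif: pd.Series, pathway: Pathway, log_base: float) -> tuple[float, bool]:
    """PAS for one case entity and one pathway; returns (value, no_coverage)."""
    log_denom = math.log(log_base)
    total = 0.0
    measured = 0
    for gene, arr in pathway.members.items():
        if gene not in cnr.index:
            continue
        c = cnr[gene]
        if c is None or (isinstance(c, float) and math.isnan(c)):
            continue
        measured += 1
        flag = btif.get(gene, 0)
        if flag:
            total += arr * math.log(c) / log_denom
    if measured == 0:
        return 0.0, True
    return total, False


def compute_pas(
    de: DEResult | pd.Series,
    pathway: Pathway,
    log_base: float = DEFAULT_LOG_BASE,
    btif: pd.Series | None = None,
) -> float:
    """PAS of one pathway for one case entity.

    ``de`` is either a :class:`DEResult` (group-level CNR and BTIF) or a
    per-entity CNR series, in which case a companion ``btif`` series is
    required.  Unmeasured member genes are skipped with a warning; a
    pathway with no measured member scores 0 (flagged no-coverage in the
    profile builders).
    """
    if isinstance(de, DEResult):
        cnr, flags = de.cnr, de.btif
    else:
        if btif is None:
            raise ValidationError("per-entity CNR input requires a companion btif series")
        cnr, flags = de, btif
    unmeasured = [g for g in pathway.members if g not in cnr.index]
    if unmeasured:
        logger.warning(
            "pathway %s: %d member gene(s) unmeasured, skipped", pathway.pathway_id, len(unmeasured)
        )
    value, no_cov = _pas_one(cnr, flags, pathway, log_base)
    if no_cov:
        logger.warning("pathway %s: no member gene measured; PAS reported as 0", pathway.pathway_id)
    return value


def group_pas_profile(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    db: PathwayDB,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
) -> PASProfile:
    """Single-row PAS profile for a whole case group vs its reference."""
    de = differential_expression(matrix, design, alpha=alpha, epsilon=epsilon)
    values, flags = {}, {}
    for pathway in db:
        v, f = _pas_one(de.cnr, de.btif, pathway, log_base)
        values[pathway.pathway_id] = v
        flags[pathway.pathway_id] = f
    return PASProfile(
        values=pd.DataFrame([values], index=[design.name]),
        no_coverage=pd.DataFrame([flags], index=[design.name]),
    )


def per_sample_pas_profile(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    db: PathwayDB,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
) -> PASProfile:
    """One PAS row per individual case sample.

    Significance (BTIF) is computed once at the group level from the full
    design; only the CNR is sample-specific.
    """
    de = differential_expression(matrix, design, alpha=alpha, epsilon=epsilon)
    rows_v, rows_f = [], []
    samples = sorted(design.case_ids)
    for sample in samples:
        cnr = per_sample_cnr(matrix, sample, design.reference_ids, epsilon=epsilon)
        values, flags = {}, {}
        for pathway in db:
            v, f = _pas_one(cnr, de.btif, pathway, log_base)
            values[pathway.pathway_id] = v
            flags[pathway.pathway_id] = f
        rows_v.append(values)
        rows_f.append(flags)
    return PASProfile(
        values=pd.DataFrame(rows_v, index=samples),
        no_coverage=pd.DataFrame(rows_f, index=samples),
    )


def filter_zero_pas_samples(profile: PASProfile) -> PASProfile:
    """Drop case entities whose PAS is exactly 0 for every pathway.

    Such samples carry no significant pathway-level signal (insignificantly
    perturbed) and are excluded from scoring.  Removing every row is an
    error.
    """
    all_zero = (profile.values == 0).all(axis=1)
    removed = list(profile.values.index[all_zero])
    if removed:
        logger.info("excluding %d insignificantly perturbed sample(s): %s", len(removed), removed)
    if all_zero.all():
        raise ValidationError("all samples have zero PAS for every pathway; nothing left to score")
    keep = ~all_zero
    return PASProfile(values=profile.values.loc[keep], no_coverage=profile.no_coverage.loc[keep])
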