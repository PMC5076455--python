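"""GeroScore: pathway-level drug efficacy scoring and ranking.

For drug d and case entity g the score is

    GS_d^g = sum over targets t of DTI_dt *
             sum over pathways p of NII_tp * ARR_tp * PAS_p^g * PAR_p

where DTI is the drug-target index (+1 inhibits, -1 activates), NII the
boolean pathway-membership indicator of the target, ARR the target's
signed activator/repressor weight in that pathway, PAS the pathway
activation strength of the case entity, and PAR the pathway aging role
(+1 pro-aging, -1 anti-aging).  A drug scores high when it counteracts
activated pro-aging pathways and restores suppressed anti-aging ones —
i.e. when it pushes an old signalome toward the young state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from geroscope.io import Drug, DrugDB, Pathway, PathwayDB, ValidationError, normalize_gene
from geroscope.pas import PASProfile

logger = logging.getLogger(__name__)


@dataclass
class GeroScoreTable:
    """Per-drug scores: one column per case entity, plus aggregate and rank.

    ``scores`` is drugs x entities; ``aggregate`` is the mean (or median)
    over entities; ``rank`` assigns 1..n by descending aggregate with ties
    broken lexicographically by drug id.
    """

    scores: pd.DataFrame
    aggregate: pd.Series
    rank: pd.Series

    @property
    def drug_ids(self) -> list[str]:
        return list(self.scores.index)

    def by_rank(self) -> pd.DataFrame:
        out = pd.DataFrame({"aggregate_score": self.aggregate, "rank": self.rank})
        return out.sort_values("rank")

    def write(self, path: str | Path) -> None:
        out = pd.concat(
            [self.aggregate.rename("aggregate_score"), self.rank.rename("rank"), self.scores],
            axis=1,
        ).sort_values("rank")
        out.index.name = "drug_id"
        out.to_csv(path, sep="\t")


def nii(target_gene: str, pathway: Pathway) -> int:
    """Node involvement index: 1 iff the target gene is a pathway member."""
    return int(pathway.contains(target_gene))


def _drug_pathway_weights(drug: Drug, db: PathwayDB) -> np.ndarray:
    """Per-pathway weight sum_t DTI_dt * NII_tp * ARR_tp for one drug."""
    weights = np.zeros(len(db))
    orphan_targets = []
    for gene, dti in drug.targets.items():
        hit = False
        for j, pathway in enumerate(db):
            arr = pathway.members.get(gene)
            if arr is not None:
                weights[j] += dti * arr
                hit = True
        if not hit:
            orphan_targets.append(gene)
    if orphan_targets:
        logger.info(
            "drug %s: %d target(s) absent from every pathway contribute 0: %s",
            drug.drug_id,
            len(orphan_targets),
            orphan_targets,
        )
    return weights


def geroscore(drug: Drug, pas_row: pd.Series, db: PathwayDB) -> float:
    """GeroScore of one drug against one entity's PAS row.

    ``pas_row`` must cover every pathway in ``db``.  Targets not present in
    any pathway contribute 0 (logged).
    """
    missing = [p.pathway_id for p in db if p.pathway_id not in pas_row.index]
    if missing:
        raise ValidationError(f"PAS row does not cover pathway(s): {missing}")
    pas = pas_row.reindex([p.pathway_id for p in db]).to_numpy(dtype=float)
    par = np.array([p.par for p in db], dtype=float)
    weights = _drug_pathway_weights(drug, db)
    return float(np.dot(weights, pas * par))


def geroscore_table(
    drug_db: DrugDB,
    profile: PASProfile,
    db: PathwayDB,
    aggregation: Literal["mean", "median"] = "mean",
) -> GeroScoreTable:
    """Score every drug against every case entity of a (filtered) PAS
    profile; aggregate over entities and rank by descending aggregate,
    ties broken lexicographically by drug id."""
    if len(drug_db) == 0:
        raise ValidationError("empty drug database")
    pathway_ids = [p.pathway_id for p in db]
    missing = [pid for pid in pathway_ids if pid not in profile.values.columns]
    if missing:
        raise ValidationError(f"profile does not cover pathway(s): {missing}")
    pas = profile.values[pathway_ids].to_numpy(dtype=float)  # entities x pathways
    par = np.array([p.par for p in db], dtype=float)
    weight_matrix = np.vstack([_drug_pathway_weights(d, db) for d in drug_db])  # drugs x pathways
    score_matrix = weight_matrix @ (pas * par).T  # drugs x entities
    scores = pd.DataFrame(score_matrix, index=drug_db.drug_ids, columns=profile.entities)
    if aggregation == "mean":
        aggregate = scores.mean(axis=1)
    elif aggregation == "median":
        aggregate = scores.median(axis=1)
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    order = sorted(scores.index, key=lambda d: (-aggregate[d], d))
    rank = pd.Series({d: i + 1 for i, d in enumerate(order)}, name="rank").reindex(scores.index)
    return GeroScoreTable(scores=scores, aggregate=aggregate.rename("aggregate_score"), rank=rank)


def shortlist(table: GeroScoreTable, n: int = 10) -> list[str]:
    """Top ``n`` drug ids by rank (rank 1 first)."""
    if n > len(table.drug_ids):
        raise ValidationError(f"shortlist size {n} exceeds {len(table.drug_ids)} drugs")
    return list(table.by_rank().index[:n])
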