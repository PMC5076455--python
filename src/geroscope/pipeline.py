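"""End-to-end workflows: the aging screen and the perturbation analysis.

Both workflows are deterministic given their inputs and parameters; every
run writes a manifest (all parameters plus SHA-256 checksums of the input
files) sufficient to reproduce its outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

from geroscope import io as gio
from geroscope.pas import (
    PASProfile,
    filter_zero_pas_samples,
    group_pas_profile,
    per_sample_pas_profile,
)
from geroscope.perturbation import build_all_designs
from geroscope.scoring import GeroScoreTable, geroscore_table, shortlist

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a screen run; mirrors the CLI flags."""

    expression: str
    annotations: str
    pathway_db: str
    drug_db: str | None = None
    alpha: float = 0.05
    log_base: float = 10.0
    epsilon: float = 1e-6
    young_min: float = 15.0
    young_max: float = 30.0
    old_min: float = 60.0
    shortlist_n: int = 10
    aggregation: Literal["mean", "median"] = "mean"
    seed: int = 0
    outdir: str = "geroscope_out"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise gio.ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.log_base <= 1.0:
            raise gio.ValidationError(f"log_base must be > 1, got {self.log_base}")
        if self.epsilon <= 0.0:
            raise gio.ValidationError(f"epsilon must be > 0, got {self.epsilon}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, stage: str) -> None:
    inputs = {}
    for key in ("expression", "annotations", "pathway_db", "drug_db"):
        path = getattr(config, key)
        if path is not None and Path(path).exists():
            inputs[key] = {"path": str(path), "sha256": _sha256(path)}
    manifest = {"stage": stage, "parameters": asdict(config), "inputs": inputs}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_aging_screen(config: RunConfig) -> tuple[GeroScoreTable, PASProfile]:
    """Old-vs-young screen: per-sample PAS, zero-PAS filtering, GeroScore
    ranking and shortlist, all written under ``config.outdir``.

    Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        matrix = gio.read_expression_table(config.expression)
        annotations = gio.read_sample_annotations(config.annotations)
        db = gio.read_pathway_db(config.pathway_db)
        if config.drug_db is None:
            raise gio.ValidationError("aging screen requires a drug database")
        drug_db = gio.read_drug_db(config.drug_db)

        stage = "age-grouping"
        design = gio.assign_age_groups(
            annotations, young_min=config.young_min, young_max=config.young_max, old_min=config.old_min
        )
        logger.info(
            "[%s] %d old case vs %d young reference samples", stage, len(design.case_ids), len(design.reference_ids)
        )

        stage = "pas"
        profile = per_sample_pas_profile(
            matrix, design, db, alpha=config.alpha, epsilon=config.epsilon, log_base=config.log_base
        )
        profile.write(outdir / "pas_per_sample.tsv", outdir / "pas_no_coverage.tsv")

        stage = "filter"
        filtered = filter_zero_pas_samples(profile)
        filtered.write(outdir / "pas_filtered.tsv")

        stage = "score"
        table = geroscore_table(drug_db, filtered, db, aggregation=config.aggregation)
        table.write(outdir / "geroscore_table.tsv")
        top = shortlist(table, n=min(config.shortlist_n, len(table.drug_ids)))
        (outdir / "shortlist.txt").write_text("\n".join(top) + "\n")

        _write_manifest(config, outdir, "screen")
        return table, filtered
    except Exception as exc:
        raise gio.ValidationError(f"aging screen failed at stage {stage!r}: {exc}") from exc


def run_perturbation_analysis(
    config: RunConfig,
    compounds: Sequence[str],
    dose: float | None = None,
    duration: float | None = None,
    vehicle: str = "DMSO",
    cell_type: str | None = None,
) -> PASProfile:
    """Group-level PAS profile per compound against plate-matched vehicle
    references; compounds whose case group scores zero on every pathway
    are excluded (insignificantly perturbed) and logged."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        matrix = gio.read_expression_table(config.expression)
        annotations = gio.read_sample_annotations(config.annotations)
        db = gio.read_pathway_db(config.pathway_db)
        if cell_type is not None:
            annotations = [a for a in annotations if a.cell_type == cell_type]

        stage = "design"
        designs = build_all_designs(annotations, compounds, dose=dose, duration=duration, vehicle=vehicle)
        gio.write_designs(designs, outdir / "perturbation_designs.tsv")

        stage = "pas"
        import pandas as pd

        rows_v, rows_f = [], []
        for design in designs:
            prof = group_pas_profile(
                matrix, design, db, alpha=config.alpha, epsilon=config.epsilon, log_base=config.log_base
            )
            rows_v.append(prof.values.iloc[0])
            rows_f.append(prof.no_coverage.iloc[0])
        profile = PASProfile(values=pd.DataFrame(rows_v), no_coverage=pd.DataFrame(rows_f))

        stage = "filter"
        profile = filter_zero_pas_samples(profile)
        profile.write(outdir / "pas_per_compound.tsv", outdir / "pas_compound_no_coverage.tsv")

        _write_manifest(config, outdir, "perturb")
        return profile
    except Exception as exc:
        raise gio.ValidationError(f"perturbation analysis failed at stage {stage!r}: {exc}") from exc
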