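"""Synthetic expression matrices, pathway DBs and drug DBs with planted
structure.

The generator emulates a two-group (old vs young) screen: reference
samples draw log10 intensities from a Gaussian baseline (log-normal on the
linear scale), case samples carry a planted fold-change on the member
genes of selected pathways, applied in the direction that gives a planted
pathway an expected PAS whose sign equals its aging role (pro-aging
pathways activated in the old state, anti-aging pathways suppressed).
The drug DB plants one ideal geroprotector — a compound whose targets
exactly oppose the planted shift — among random decoys, so the end-to-end
ranking can be validated by rank-1 recovery of the planted drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from geroscope.io import (
    Drug,
    DrugDB,
    ExpressionMatrix,
    GroupDesign,
    Pathway,
    PathwayDB,
    ValidationError,
)
from geroscope.pas import filter_zero_pas_samples, per_sample_pas_profile
from geroscope.scoring import geroscore_table

#: ARR weights sampled for simulated pathway members: strong/weak
#: activators and repressors
_ARR_CHOICES = (1.0, -1.0, 0.5, -0.5)

#: number of random targets per decoy drug
_DECOY_TARGETS = 5

PLANTED_DRUG_ID = "GEROPROTECTOR"


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic screen.

    Defaults: 2000 genes, 10 disjoint pathways of 15 genes, the first 3
    planted at fold-change 4, log10-scale noise sd 0.1 around a baseline of
    2 (linear intensities around 100), 8 case vs 8 reference samples.
    """

    n_genes: int = 2000
    n_pathways: int = 10
    genes_per_pathway: int = 15
    n_reference: int = 8
    n_case: int = 8
    n_planted: int = 3
    fold_change: float = 4.0
    planted_pathways: dict[str, float] | None = None
    noise_sd: float = 0.1
    baseline_log10_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pathways", "genes_per_pathway", "n_reference", "n_case"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.planted_pathways is not None and any(fc <= 0 for fc in self.planted_pathways.values()):
            raise ValidationError("planted fold changes must be > 0")

    def pathway_ids(self) -> list[str]:
        return [f"PW_{i + 1:02d}" for i in range(self.n_pathways)]

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"GENE_{i + 1:0{width}d}" for i in range(self.n_genes)]

    def resolved_planted(self) -> dict[str, float]:
        """Planted pathway -> fold-change map; defaults to the first
        ``n_planted`` pathways at ``fold_change``."""
        if self.planted_pathways is not None:
            return dict(self.planted_pathways)
        return {pid: self.fold_change for pid in self.pathway_ids()[: self.n_planted]}


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent streams per generator stage so adding one stage does not
    # perturb the others
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_pathway_db(config: SimulationConfig) -> PathwayDB:
    """Disjoint-membership pathway DB: PAR drawn +/-1, member ARR drawn
    from strong/weak activator/repressor weights; deterministic per seed."""
    needed = config.n_pathways * config.genes_per_pathway
    if needed > config.n_genes:
        raise ValidationError(
            f"{config.n_pathways} pathways x {config.genes_per_pathway} genes need "
            f"{needed} genes, matrix has {config.n_genes}"
        )
    rng = _rng(config.seed, 1)
    genes = config.gene_ids()
    pathways = []
    for i, pid in enumerate(config.pathway_ids()):
        members_genes = genes[i * config.genes_per_pathway : (i + 1) * config.genes_per_pathway]
        par = int(rng.choice((1, -1)))
        members = {g: float(rng.choice(_ARR_CHOICES)) for g in members_genes}
        pathways.append(Pathway(pathway_id=pid, name=f"Simulated pathway {i + 1}", par=par, members=members))
    return PathwayDB(pathways)


def simulate_expression(
    config: SimulationConfig, db: PathwayDB
) -> tuple[ExpressionMatrix, GroupDesign]:
    """Log-normal expression for reference and case groups.

    Reference intensity per gene/sample: ``10 ** (baseline + N(0, sd))``.
    Case samples multiply each planted-pathway member by
    ``fold_change ** (sign(arr) * par)`` so the planted pathway's expected
    PAS sign equals its PAR: pro-aging pathways come out activated in the
    case (old) state, anti-aging pathways suppressed.
    """
    rng = _rng(config.seed, 2)
    genes = config.gene_ids()
    n_samples = config.n_reference + config.n_case
    log10_expr = config.baseline_log10_mean + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    gene_index = {g: i for i, g in enumerate(genes)}
    planted = config.resolved_planted()
    case_cols = np.arange(config.n_reference, n_samples)
    for pid, fold_change in planted.items():
        pathway = db.get(pid)
        for gene, arr in pathway.members.items():
            i = gene_index.get(gene)
            if i is None:
                continue
            shift = np.sign(arr) * pathway.par * np.log10(fold_change)
            log10_expr[i, case_cols] += shift

    ref_ids = [f"YOUNG_{i + 1:02d}" for i in range(config.n_reference)]
    case_ids = [f"OLD_{i + 1:02d}" for i in range(config.n_case)]
    matrix = ExpressionMatrix(
        pd.DataFrame(10.0 ** log10_expr, index=genes, columns=ref_ids + case_ids)
    )
    design = GroupDesign(name="old_vs_young", case_ids=frozenset(case_ids), reference_ids=frozenset(ref_ids))
    return matrix, design


def simulate_drug_db(
    db: PathwayDB,
    planted_pathways: dict[str, float] | list[str],
    n_decoys: int,
    seed: int,
) -> tuple[DrugDB, str]:
    """Drug DB with one ideal geroprotector among ``n_decoys`` decoys.

    The planted drug targets every member of the planted pathways with
    DTI = sign(ARR): it inhibits activators and activates repressors,
    which opposes the planted expression shift regardless of the
    pathway's aging role.  Decoys get random targets (drawn from pathway
    member genes, so they do interact with the signalome) with random DTI.
    Returns the DB and the planted drug's id.
    """
    planted_ids = list(planted_pathways)
    missing = [pid for pid in planted_ids if pid not in {p.pathway_id for p in db}]
    if missing:
        raise ValidationError(f"planted pathway(s) absent from DB: {missing}")
    rng = _rng(seed, 3)
    targets: dict[str, int] = {}
    for pid in planted_ids:
        for gene, arr in db.get(pid).members.items():
            targets[gene] = 1 if arr > 0 else -1
    drugs = [Drug(drug_id=PLANTED_DRUG_ID, targets=targets)]
    member_pool = sorted({g for p in db for g in p.members})
    width = len(str(max(n_decoys, 1)))
    for i in range(n_decoys):
        k = min(_DECOY_TARGETS, len(member_pool))
        decoy_genes = rng.choice(member_pool, size=k, replace=False)
        decoy_targets = {g: int(rng.choice((1, -1))) for g in decoy_genes}
        drugs.append(Drug(drug_id=f"DECOY_{i + 1:0{width}d}", targets=decoy_targets))
    return DrugDB(drugs), PLANTED_DRUG_ID


def simulate_bundle(config: SimulationConfig, n_decoys: int = 30):
    """Generate the full synthetic screen: pathway DB, expression matrix,
    design, drug DB and the planted drug id."""
    db = simulate_pathway_db(config)
    matrix, design = simulate_expression(config, db)
    drug_db, planted_drug = simulate_drug_db(db, config.resolved_planted(), n_decoys, config.seed)
    return db, matrix, design, drug_db, planted_drug


def run_recovery_benchmark(
    config: SimulationConfig | None = None,
    n_decoys: int = 30,
    n_seeds: int = 100,
    alpha: float = 0.05,
) -> float:
    """Fraction of seeded replicates in which the planted geroprotector is
    ranked 1 by the end-to-end pipeline (simulate -> differential
    expression -> PAS -> zero-PAS filter -> GeroScore -> rank).

    A replicate where the zero-PAS filter removes every case sample (no
    significant signal anywhere, typical under a null fold-change of 1)
    yields no ranking and counts as a failure to recover.
    """
    if config is None:
        config = SimulationConfig()
    hits = 0
    for i in range(n_seeds):
        cfg = replace(config, seed=config.seed + i)
        db, matrix, design, drug_db, planted_drug = simulate_bundle(cfg, n_decoys=n_decoys)
        profile = per_sample_pas_profile(matrix, design, db, alpha=alpha)
        try:
            profile = filter_zero_pas_samples(profile)
        except ValidationError:
            continue
        table = geroscore_table(drug_db, profile, db)
        if table.rank[planted_drug] == 1:
            hits += 1
    return hits / n_seeds
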