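import numpy as np
import pandas as pd
import pytest

from geroscope.io import Drug, DrugDB, ExpressionMatrix, GroupDesign, Pathway, PathwayDB


@pytest.fixture
def small_matrix():
    """4 genes x 6 samples with a clean 10x shift on MAP2K1 in the case
    group (C1-C3) vs reference (R1-R3)."""
    data = pd.DataFrame(
        {
            "R1": [10.0, 5.0, 100.0, 1.0],
            "R2": [11.0, 5.5, 101.0, 1.1],
            "R3": [9.0, 4.5, 99.0, 0.9],
            "C1": [100.0, 5.0, 100.0, 1.0],
            "C2": [110.0, 5.5, 101.0, 1.1],
            "C3": [90.0, 4.5, 99.0, 0.9],
        },
        index=["MAP2K1", "DUSP1", "ACTB", "TP53"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_design():
    return GroupDesign(name="test", case_ids={"C1", "C2", "C3"}, reference_ids={"R1", "R2", "R3"})


@pytest.fixture
def mapk_pathway():
    return Pathway(
        pathway_id="MAPK",
        name="MAPK signaling",
        par=1,
        members={"MAP2K1": 1.0, "DUSP1": -1.0},
    )


@pytest.fixture
def small_pathway_db(mapk_pathway):
    other = Pathway(pathway_id="P53", name="p53 signaling", par=-1, members={"TP53": 1.0})
    return PathwayDB([mapk_pathway, other])


@pytest.fixture
def small_drug_db():
    return DrugDB(
        [
            Drug(drug_id="PD-98059", targets={"MAP2K1": 1}),
            Drug(drug_id="ACTIVATOR-X", targets={"MAP2K1": -1}),
            Drug(drug_id="NO-TARGETS", targets={}),
        ]
    )


def random_pathway_db(rng, n_pathways=3, genes_per_pathway=6, gene_pool=None):
    """Random pathway DB for oracle-equivalence checks; overlapping
    membership allowed."""
    if gene_pool is None:
        gene_pool = [f"G{i:03d}" for i in range(40)]
    pathways = []
    for k in range(n_pathways):
        genes = rng.choice(gene_pool, size=genes_per_pathway, replace=False)
        members = {g: float(rng.choice([1.0, -1.0, 0.5, -0.5])) for g in genes}
        pathways.append(
            Pathway(pathway_id=f"PW{k}", name=f"pw {k}", par=int(rng.choice([1, -1])), members=members)
        )
    return PathwayDB(pathways)


def random_drug(rng, gene_pool, n_targets=4, drug_id="D0"):
    genes = rng.choice(gene_pool, size=n_targets, replace=False)
    return Drug(drug_id=drug_id, targets={g: int(rng.choice([1, -1])) for g in genes})
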