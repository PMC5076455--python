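"""Domain types and TSV readers/writers.

All tabular interchange is UTF-8 TSV with ``.`` as the decimal separator.
Gene symbols are matched case-insensitively by uppercasing on ingest, since
public pathway and drug-target sources mix symbol capitalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: annotation columns with a dedicated field; anything else is preserved
#: as an opaque attribute
_ANNOTATION_FIELDS = (
    "sample_id",
    "age",
    "cell_type",
    "plate",
    "perturbagen",
    "dose_um",
    "duration_h",
)


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


def normalize_gene(symbol: str) -> str:
    """Case-normalize a gene symbol (HGNC-style symbols are uppercase)."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of linear-scale, non-negative intensities.

    ``data`` is indexed by case-normalized gene symbol with one column per
    sample id.  Missing measurements are NaN; negative values are invalid.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = [normalize_gene(g) for g in df.index]
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols after case normalization: {dups}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = df.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValidationError("expression intensities must be >= 0")
        df = df.astype(float)
        df.index.name = "gene_symbol"
        self.data = df

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return self.data[ids]


@dataclass
class SampleAnnotation:
    """Per-sample metadata: donor age and/or perturbation descriptors."""

    sample_id: str
    age: float | None = None
    cell_type: str | None = None
    plate: str | None = None
    perturbagen: str | None = None
    dose_um: float | None = None
    duration_h: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValidationError(f"sample {self.sample_id}: age must be >= 0, got {self.age}")


@dataclass
class GroupDesign:
    """One case-vs-reference comparison, e.g. old-vs-young or drug-vs-DMSO."""

    name: str
    case_ids: frozenset[str]
    reference_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.case_ids = frozenset(self.case_ids)
        self.reference_ids = frozenset(self.reference_ids)
        if not self.case_ids or not self.reference_ids:
            raise ValidationError(f"design {self.name!r}: case and reference sets must be non-empty")
        overlap = self.case_ids & self.reference_ids
        if overlap:
            raise ValidationError(f"design {self.name!r}: case/reference overlap: {sorted(overlap)}")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.samples)
        missing = (self.case_ids | self.reference_ids) - known
        if missing:
            raise ValidationError(f"design {self.name!r}: samples absent from matrix: {sorted(missing)}")


@dataclass
class Pathway:
    """A signaling pathway with an aging role and weighted member genes.

    ``par`` is the pathway aging role: +1 pro-aging, -1 anti-aging.
    ``members`` maps gene symbol to its activator/repressor role (ARR), a
    signed weight in [-1, 1] excluding 0 (positive = pathway activator,
    negative = repressor; magnitude < 1 marks a weak role).
    """

    pathway_id: str
    name: str
    par: int
    members: dict[str, float]

    def __post_init__(self) -> None:
        if self.par not in (1, -1):
            raise ValidationError(f"pathway {self.pathway_id}: PAR must be +1 or -1, got {self.par}")
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id}: no member genes")
        normalized: dict[str, float] = {}
        for gene, arr in self.members.items():
            arr = float(arr)
            if not (-1.0 <= arr <= 1.0) or arr == 0.0:
                raise ValidationError(
                    f"pathway {self.pathway_id}, gene {gene}: ARR must lie in [-1,1] and be nonzero, got {arr}"
                )
            normalized[normalize_gene(gene)] = arr
        self.members = normalized

    def contains(self, gene: str) -> bool:
        return normalize_gene(gene) in self.members


@dataclass
class PathwayDB:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate pathway ids")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass
class Drug:
    """A compound and its protein targets.

    ``targets`` maps gene symbol to the drug-target index (DTI): -1 if the
    drug activates the target, +1 if it inhibits it.  Non-interacting
    targets (DTI 0) are simply absent.
    """

    drug_id: str
    targets: dict[str, int]

    def __post_init__(self) -> None:
        normalized: dict[str, int] = {}
        for gene, dti in self.targets.items():
            dti = int(dti)
            if dti not in (-1, 1):
                raise ValidationError(
                    f"drug {self.drug_id}, target {gene}: stored DTI must be -1 or +1, got {dti}"
                )
            normalized[normalize_gene(gene)] = dti
        self.targets = normalized


@dataclass
class DrugDB:
    drugs: list[Drug]

    def __post_init__(self) -> None:
        ids = [d.drug_id for d in self.drugs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate drug ids")

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    def get(self, drug_id: str) -> Drug:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene symbol, header row
    of sample ids).  Duplicate gene rows are collapsed by their mean with a
    logged warning; ``NA`` cells become missing values."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty expression table") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression table")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
    df.index = [normalize_gene(g) for g in df.index]
    if df.index.has_duplicates:
        dup = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing %d duplicate gene row(s) by mean: %s", len(dup), dup)
        df = df.groupby(level=0, sort=False).mean()
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    return ExpressionMatrix(df)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# sample annotation I/O
# ---------------------------------------------------------------------------


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the annotation TSV; ``sample_id`` is mandatory, all other
    columns optional.  Unknown columns are kept as opaque attributes."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing mandatory column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = sorted(df["sample_id"][df["sample_id"].duplicated()])
        raise ValidationError(f"{path}: duplicate sample_id(s): {dup}")
    extra_cols = [c for c in df.columns if c not in _ANNOTATION_FIELDS]
    annotations = []
    for _, row in df.iterrows():
        annotations.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                age=_opt_float(row.get("age")),
                cell_type=_opt_str(row.get("cell_type")),
                plate=_opt_str(row.get("plate")),
                perturbagen=_opt_str(row.get("perturbagen")),
                dose_um=_opt_float(row.get("dose_um")),
                duration_h=_opt_float(row.get("duration_h")),
                extra={c: row[c] for c in extra_cols if row[c] != ""},
            )
        )
    return annotations


def write_sample_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    extra_cols = sorted({k for a in annotations for k in a.extra})
    rows = []
    for a in annotations:
        row = {
            "sample_id": a.sample_id,
            "age": a.age,
            "cell_type": a.cell_type,
            "plate": a.plate,
            "perturbagen": a.perturbagen,
            "dose_um": a.dose_um,
            "duration_h": a.duration_h,
        }
        for c in extra_cols:
            row[c] = a.extra.get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# pathway DB I/O
# ---------------------------------------------------------------------------


def read_pathway_db(path: str | Path) -> PathwayDB:
    """Read a long-format pathway TSV: pathway_id, pathway_name, par,
    gene_symbol, arr.  PAR must be consistent within a pathway."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"pathway_id", "pathway_name", "par", "gene_symbol", "arr"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    pathways = []
    for pid, grp in df.groupby("pathway_id", sort=False):
        pars = set(int(v) for v in grp["par"])
        if len(pars) > 1:
            raise ValidationError(f"{path}: conflicting PAR values for pathway {pid}: {sorted(pars)}")
        names = set(grp["pathway_name"])
        if len(names) > 1:
            raise ValidationError(f"{path}: conflicting names for pathway {pid}: {sorted(names)}")
        members = {g: float(a) for g, a in zip(grp["gene_symbol"], grp["arr"])}
        pathways.append(Pathway(pathway_id=str(pid), name=names.pop(), par=pars.pop(), members=members))
    return PathwayDB(pathways)


def write_pathway_db(db: PathwayDB, path: str | Path) -> None:
    rows = [
        {"pathway_id": p.pathway_id, "pathway_name": p.name, "par": p.par, "gene_symbol": g, "arr": arr}
        for p in db
        for g, arr in p.members.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug DB I/O
# ---------------------------------------------------------------------------


def read_drug_db(path: str | Path) -> DrugDB:
    """Read a drug-target TSV: drug_id, target_gene, dti.

    DTI 0 rows (no interaction) are dropped with a warning since they carry
    no information; DTI outside {-1, 0, +1} is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"drug_id", "target_gene", "dti"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df[~df["dti"].isin([-1, 0, 1])]
    if len(bad):
        raise ValidationError(f"{path}: DTI must be -1, 0 or +1; offending rows: {bad.index.tolist()}")
    n_zero = int((df["dti"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d drug-target row(s) with DTI 0 (no interaction)", n_zero)
    drugs = []
    for did, grp in df.groupby("drug_id", sort=False):
        targets = {g: int(d) for g, d in zip(grp["target_gene"], grp["dti"]) if d != 0}
        drugs.append(Drug(drug_id=str(did), targets=targets))
    return DrugDB(drugs)


def write_drug_db(db: DrugDB, path: str | Path) -> None:
    rows = [
        {"drug_id": d.drug_id, "target_gene": g, "dti": dti}
        for d in db
        for g, dti in d.targets.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design I/O and donor-age grouping
# ---------------------------------------------------------------------------


def write_designs(designs: Sequence[GroupDesign], path: str | Path) -> None:
    rows = []
    for d in designs:
        rows += [{"design_name": d.name, "role": "case", "sample_id": s} for s in sorted(d.case_ids)]
        rows += [{"design_name": d.name, "role": "reference", "sample_id": s} for s in sorted(d.reference_ids)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_designs(path: str | Path) -> list[GroupDesign]:
    df = pd.read_csv(path, sep="\t")
    designs = []
    for name, grp in df.groupby("design_name", sort=False):
        designs.append(
            GroupDesign(
                name=str(name),
                case_ids=frozenset(grp.loc[grp["role"] == "case", "sample_id"]),
                reference_ids=frozenset(grp.loc[grp["role"] == "reference", "sample_id"]),
            )
        )
    return designs


def assign_age_groups(
    annotations: Sequence[SampleAnnotation],
    young_min: float = 15.0,
    young_max: float = 30.0,
    old_min: float = 60.0,
    name: str = "old_vs_young",
) -> GroupDesign:
    """Split samples into an old case group and a young reference group.

    Young donors span ``young_min <= age <= young_max`` (default 15-30,
    inclusive); old donors are strictly over ``old_min`` (default 60).
    Samples outside both windows, or lacking an age, are excluded.
    """
    young = {a.sample_id for a in annotations if a.age is not None and young_min <= a.age <= young_max}
    old = {a.sample_id for a in annotations if a.age is not None and a.age > old_min}
    if not young or not old:
        raise ValidationError(
            f"empty age group: young [{young_min}, {young_max}] has {len(young)} sample(s), "
            f"old > {old_min} has {len(old)} sample(s)"
        )
    return GroupDesign(name=name, case_ids=frozenset(old), reference_ids=frozenset(young))
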