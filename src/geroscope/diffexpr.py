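"""Case-reference differential expression.

Per gene: the case-to-normal expression ratio (CNR) of arithmetic means on
the linear intensity scale, a two-sided equal-variance Student's t-test,
Benjamini-Hochberg FDR adjustment, and a binary significance flag (BTIF)
at an FDR threshold ``alpha`` (default 0.05).  BTIF gates a gene's
contribution to pathway activation scoring downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from geroscope.io import ExpressionMatrix, GroupDesign, ValidationError

#: floor applied to group means before forming ratios, to avoid division
#: by zero on all-zero intensities
DEFAULT_EPSILON = 1e-6

DEFAULT_ALPHA = 0.05


@dataclass
class DEResult:
    """Per-gene differential-expression summary.

    ``table`` is indexed by gene symbol with columns:

    cnr
        case/reference ratio of mean intensities (> 0).
    p
        two-sided Student's t p-value; NaN for untestable genes
        (fewer than two non-missing values on a side).
    q
        BH-adjusted p; untestable genes are excluded from the family.
    btif
        1 if ``q < alpha`` else 0 (always 0 for untestable genes).
    """

    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        required = {"cnr", "p", "q", "btif"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DEResult table missing column(s) {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def cnr(self) -> pd.Series:
        return self.table["cnr"]

    @property
    def btif(self) -> pd.Series:
        return self.table["btif"]

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_symbol"
        out.to_csv(path, sep="\t", na_rep="NA")


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def gene_cnr(
    case_values: Sequence[float],
    reference_values: Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Case-to-normal ratio: ``max(mean(case), eps) / max(mean(ref), eps)``.

    Means are arithmetic, on the linear intensity scale; missing values are
    dropped first.
    """
    case = _clean(case_values)
    ref = _clean(reference_values)
    if case.size == 0 or ref.size == 0:
        raise ValidationError("CNR needs at least one value on each side")
    return max(case.mean(), epsilon) / max(ref.mean(), epsilon)


def gene_ttest(case_values: Sequence[float], reference_values: Sequence[float]) -> float:
    """Two-sided equal-variance (classic Student) two-sample t-test p-value.

    Degenerate zero-variance groups: if both sides are constant with equal
    means the test is uninformative and p = 1; constant but different means
    give p = 0.  Returns NaN when a side has fewer than two values.
    """
    case = _clean(case_values)
    ref = _clean(reference_values)
    if case.size < 2 or ref.size < 2:
        return float("nan")
    if case.var(ddof=1) == 0.0 and ref.var(ddof=1) == 0.0:
        return 1.0 if case.mean() == ref.mean() else 0.0
    t, p = stats.ttest_ind(case, ref, equal_var=True)
    return float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and within [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_expression(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
) -> DEResult:
    """Per-gene CNR, Student's t p-value, BH q and significance flag for
    one case-vs-reference design.

    Genes with fewer than two non-missing values on either side are
    untestable: they keep their CNR but get p = q = NaN and btif = 0, and
    are excluded from the BH family.
    """
    design.validate_against(matrix)
    if len(matrix.genes) == 0:
        raise ValidationError("empty gene set")
    case = matrix.subset_samples(sorted(design.case_ids)).to_numpy()
    ref = matrix.subset_samples(sorted(design.reference_ids)).to_numpy()

    case_n = np.sum(~np.isnan(case), axis=1)
    ref_n = np.sum(~np.isnan(ref), axis=1)
    # nanmean warns on all-NaN rows; compute guarded means instead
    with np.errstate(invalid="ignore"):
        case_mean = np.nansum(case, axis=1) / np.maximum(case_n, 1)
        ref_mean = np.nansum(ref, axis=1) / np.maximum(ref_n, 1)
    cnr = np.maximum(case_mean, epsilon) / np.maximum(ref_mean, epsilon)
    cnr = np.where((case_n == 0) | (ref_n == 0), np.nan, cnr)

    testable = (case_n >= 2) & (ref_n >= 2)
    p = np.full(len(matrix.genes), np.nan)
    if testable.any():
        idx = np.flatnonzero(testable)
        # vectorized path for complete rows, scalar fallback where NaNs remain
        complete = idx[(case_n[idx] == case.shape[1]) & (ref_n[idx] == ref.shape[1])]
        if complete.size:
            t_stat, p_vec = stats.ttest_ind(case[complete], ref[complete], axis=1, equal_var=True)
            p[complete] = p_vec
        for i in np.setdiff1d(idx, complete):
            p[i] = gene_ttest(case[i], ref[i])
        # zero-pooled-variance rows come back NaN from scipy; resolve them
        nan_after = np.flatnonzero(testable & np.isnan(p))
        for i in nan_after:
            p[i] = gene_ttest(case[i], ref[i])

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    btif = np.where(tested & (q < alpha), 1, 0)

    table = pd.DataFrame({"cnr": cnr, "p": p, "q": q, "btif": btif}, index=matrix.genes)
    return DEResult(table=table, alpha=alpha)


def per_sample_cnr(
    matrix: ExpressionMatrix,
    sample_id: str,
    reference_ids: Sequence[str] | frozenset[str],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.Series:
    """Per-gene ratio of one sample's intensity to the reference-group
    mean, both floored at ``epsilon``.  Used for sample-indexed pathway
    activation scores."""
    reference_ids = sorted(reference_ids)
    if sample_id in reference_ids:
        raise ValidationError(f"sample {sample_id!r} is in the reference set")
    if sample_id not in matrix.data.columns:
        raise KeyError(f"unknown sample id: {sample_id!r}")
    sample = matrix.data[sample_id].to_numpy()
    ref = matrix.subset_samples(reference_ids).to_numpy()
    ref_n = np.sum(~np.isnan(ref), axis=1)
    with np.errstate(invalid="ignore"):
        ref_mean = np.nansum(ref, axis=1) / np.maximum(ref_n, 1)
    cnr = np.maximum(sample, epsilon) / np.maximum(ref_mean, epsilon)
    cnr = np.where(np.isnan(sample) | (ref_n == 0), np.nan, cnr)
    return pd.Series(cnr, index=matrix.genes, name=sample_id)
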