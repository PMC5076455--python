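"""Pathway activation strength: formula, profiles, zero-PAS filter."""

import numpy as np
import pandas as pd
import pytest

from geroscope.diffexpr import differential_expression, per_sample_cnr
from geroscope.io import ExpressionMatrix, GroupDesign, Pathway, PathwayDB, ValidationError
from geroscope.pas import (
    PASProfile,
    compute_pas,
    filter_zero_pas_samples,
    group_pas_profile,
    per_sample_pas_profile,
)
from conftest import random_pathway_db
from oracles import pas_brute


def _series(d):
    return pd.Series(d)


class TestComputePAS:
    def test_all_insignificant_is_zero(self, mapk_pathway):
        cnr = _series({"MAP2K1": 5.0, "DUSP1": 0.2})
        btif = _series({"MAP2K1": 0, "DUSP1": 0})
        assert compute_pas(cnr, mapk_pathway, btif=btif) == 0.0

    def test_single_activator_tenfold(self):
        pw = Pathway(pathway_id="P", name="p", par=1, members={"G1": 1.0})
        assert compute_pas(_series({"G1": 10.0}), pw, btif=_series({"G1": 1})) == pytest.approx(1.0)

    def test_activator_repressor_cancellation(self):
        pw = Pathway(pathway_id="P", name="p", par=1, members={"A": 1.0, "R": -1.0})
        cnr = _series({"A": 100.0, "R": 100.0})
        assert compute_pas(cnr, pw, btif=_series({"A": 1, "R": 1})) == pytest.approx(0.0)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            db = random_pathway_db(rng, n_pathways=1, genes_per_pathway=6)
            pw = db.pathways[0]
            cnr = {g: float(rng.uniform(0.05, 20)) for g in pw.members}
            btif = {g: int(rng.integers(0, 2)) for g in pw.members}
            got = compute_pas(_series(cnr), pw, btif=_series(btif))
            assert got == pytest.approx(pas_brute(cnr, btif, pw), abs=1e-12)

    def test_no_coverage_scores_zero(self):
        pw = Pathway(pathway_id="P", name="p", par=1, members={"UNMEASURED": 1.0})
        assert compute_pas(_series({"OTHER": 5.0}), pw, btif=_series({"OTHER": 1})) == 0.0

    def test_additive_over_member_partition(self):
        rng = np.random.default_rng(23)
        genes = [f"G{i}" for i in range(8)]
        members = {g: float(rng.choice([1.0, -1.0, 0.5, -0.5])) for g in genes}
        cnr = _series({g: float(rng.uniform(0.1, 10)) for g in genes})
        btif = _series({g: 1 for g in genes})
        whole = Pathway(pathway_id="W", name="w", par=1, members=members)
        left = Pathway(pathway_id="L", name="l", par=1, members={g: members[g] for g in genes[:4]})
        right = Pathway(pathway_id="R", name="r", par=1, members={g: members[g] for g in genes[4:]})
        assert compute_pas(cnr, whole, btif=btif) == pytest.approx(
            compute_pas(cnr, left, btif=btif) + compute_pas(cnr, right, btif=btif)
        )


class TestGroupProfile:
    def test_planted_upregulation_positive(self, small_matrix, small_design, small_pathway_db):
        # MAP2K1 (activator) is 10x up in the case group
        profile = group_pas_profile(small_matrix, small_design, small_pathway_db)
        assert profile.values.loc["test", "MAPK"] > 0
        assert not profile.no_coverage.loc["test", "MAPK"]

    def test_null_mean_pas_near_zero(self):
        rng = np.random.default_rng(31)
        pas_values = []
        for _ in range(50):
            values = 10 ** rng.normal(2.0, 0.2, size=(60, 10))
            samples = [f"R{i}" for i in range(5)] + [f"C{i}" for i in range(5)]
            matrix = ExpressionMatrix(
                pd.DataFrame(values, index=[f"G{i}" for i in range(60)], columns=samples)
            )
            design = GroupDesign(name="null", case_ids=set(samples[5:]), reference_ids=set(samples[:5]))
            db = PathwayDB([Pathway(pathway_id="P", name="p", par=1,
                                    members={f"G{i}": 1.0 for i in range(20)})])
            pas_values.append(group_pas_profile(matrix, design, db).values.iloc[0, 0])
        pas_values = np.asarray(pas_values)
        se = pas_values.std(ddof=1) / np.sqrt(len(pas_values)) if pas_values.std() > 0 else 0.0
        assert abs(pas_values.mean()) <= 3 * se + 1e-12

    def test_no_coverage_pathway_flagged(self, small_matrix, small_design):
        db = PathwayDB([Pathway(pathway_id="X", name="x", par=1, members={"ABSENT": 1.0})])
        profile = group_pas_profile(small_matrix, small_design, db)
        assert profile.values.iloc[0, 0] == 0.0
        assert bool(profile.no_coverage.iloc[0, 0])

    def test_antisymmetry_under_group_swap(self, small_matrix, small_design, small_pathway_db):
        flipped = GroupDesign(name="test", case_ids=small_design.reference_ids,
                              reference_ids=small_design.case_ids)
        p1 = group_pas_profile(small_matrix, small_design, small_pathway_db)
        p2 = group_pas_profile(small_matrix, flipped, small_pathway_db)
        assert np.allclose(p1.values.to_numpy(), -p2.values.to_numpy(), atol=1e-12)

    def test_scale_invariance(self, small_matrix, small_design, small_pathway_db):
        scaled = ExpressionMatrix(small_matrix.data * 37.0)
        p1 = group_pas_profile(small_matrix, small_design, small_pathway_db)
        p2 = group_pas_profile(scaled, small_design, small_pathway_db)
        assert np.allclose(p1.values.to_numpy(), p2.values.to_numpy(), atol=1e-9)


class TestPerSampleProfile:
    def test_shape_and_single_sample_equivalence(self, small_matrix, small_design, small_pathway_db):
        profile = per_sample_pas_profile(small_matrix, small_design, small_pathway_db)
        assert profile.values.shape == (3, 2)
        # single-sample row equals compute_pas on that sample's CNR with group BTIF
        de = differential_expression(small_matrix, small_design)
        cnr = per_sample_cnr(small_matrix, "C1", sorted(small_design.reference_ids))
        for pw in small_pathway_db:
            expected = compute_pas(cnr, pw, btif=de.btif)
            assert profile.values.loc["C1", pw.pathway_id] == pytest.approx(expected)

    def test_sample_equal_to_reference_mean_scores_zero(self, small_pathway_db):
        ref = pd.DataFrame(
            {"R1": [10.0, 4.0, 2.0, 6.0], "R2": [10.0, 4.0, 2.0, 6.0], "R3": [10.0, 4.0, 2.0, 6.0]},
            index=["MAP2K1", "DUSP1", "ACTB", "TP53"],
        )
        # case group contains one strongly shifted sample (so BTIF can fire)
        # and one sample identical to the reference mean
        data = ref.copy()
        data["C_SHIFT"] = [1000.0, 4.0, 2.0, 6.0]
        data["C_SAME"] = [10.0, 4.0, 2.0, 6.0]
        design = GroupDesign(name="d", case_ids={"C_SHIFT", "C_SAME"}, reference_ids={"R1", "R2", "R3"})
        profile = per_sample_pas_profile(ExpressionMatrix(data), design, small_pathway_db)
        assert np.allclose(profile.values.loc["C_SAME"].to_numpy(), 0.0)

    def test_mean_of_rows_near_group_pas(self):
        rng = np.random.default_rng(41)
        genes = [f"G{i}" for i in range(30)]
        base = 10 ** rng.normal(2.0, 0.05, size=(30, 16))
        base[:10, 8:] *= 4.0  # planted up-shift on a 10-gene pathway
        samples = [f"R{i}" for i in range(8)] + [f"C{i}" for i in range(8)]
        matrix = ExpressionMatrix(pd.DataFrame(base, index=genes, columns=samples))
        design = GroupDesign(name="d", case_ids=set(samples[8:]), reference_ids=set(samples[:8]))
        db = PathwayDB([Pathway(pathway_id="P", name="p", par=1, members={g: 1.0 for g in genes[:10]})])
        group = group_pas_profile(matrix, design, db).values.iloc[0, 0]
        per_sample = per_sample_pas_profile(matrix, design, db).values.iloc[:, 0].mean()
        # arithmetic-mean CNR vs per-sample mean of log ratios differ only
        # by sampling noise at this noise level
        assert per_sample == pytest.approx(group, rel=0.05)


class TestZeroPASFilter:
    def _profile(self, rows, index):
        values = pd.DataFrame(rows, index=index, columns=["P1", "P2"], dtype=float)
        flags = pd.DataFrame(False, index=values.index, columns=values.columns)
        return PASProfile(values=values, no_coverage=flags)

    def test_removes_exactly_all_zero_rows(self):
        profile = self._profile([[1.0, 0.0], [0.0, 0.0], [0.0, -2.0]], ["S1", "S2", "S3"])
        filtered = filter_zero_pas_samples(profile)
        assert filtered.entities == ["S1", "S3"]

    def test_identity_when_no_zero_rows(self):
        profile = self._profile([[1.0, 2.0], [0.5, -0.5]], ["S1", "S2"])
        filtered = filter_zero_pas_samples(profile)
        pd.testing.assert_frame_equal(filtered.values, profile.values)

    def test_all_zero_rows_error(self):
        profile = self._profile([[0.0, 0.0], [0.0, 0.0]], ["S1", "S2"])
        with pytest.raises(ValidationError):
            filter_zero_pas_samples(profile)
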