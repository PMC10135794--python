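import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from matriq import (
    CONTRASTS,
    GROUPS,
    normalize_channels,
    percent_change,
    phospho_fold_change,
    propagate_cv,
    protein_fold_change,
    protein_t_test,
    quantify_phospho,
    quantify_proteins,
)
from matriq.quant import PAIN

from conftest import peptide_table, phospho_table


# ---------------------------------------------------------------------------
# channel normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_hand_computed_median_offsets(self):
        # group medians 10 / 12 / 11 / 11, grand median 11 -> offsets +1/-1/0/0
        table = peptide_table(
            {
                "P1": {
                    "NoSNI": [9, 10, 11],
                    "NoSCS": [11, 12, 13],
                    "DTMP": [10, 11, 12],
                    "LRSCS": [10, 11, 12],
                }
            }
        )
        out = normalize_channels(table)
        got = out.groupby("group")["log2_intensity"].apply(list)
        assert got["NoSNI"] == [10, 11, 12]
        assert got["NoSCS"] == [10, 11, 12]
        assert got["DTMP"] == [10, 11, 12]
        assert got["LRSCS"] == [10, 11, 12]

    def test_idempotent_on_aligned_table(self, balanced_peptides):
        once = normalize_channels(balanced_peptides)
        twice = normalize_channels(once)
        assert np.allclose(once["log2_intensity"], twice["log2_intensity"], atol=1e-12)

    def test_per_group_shift_invariance(self):
        # shifting a whole channel is undone exactly by median re-centering
        table = peptide_table(
            {
                "P1": {
                    "NoSNI": [9, 10, 11],
                    "NoSCS": [11, 12, 13],
                    "DTMP": [10, 11, 12],
                    "LRSCS": [10, 11, 12],
                }
            }
        )
        shifted = table.copy()
        mask = shifted["group"] == "NoSCS"
        shifted.loc[mask, "log2_intensity"] += 3.7
        a = normalize_channels(table)["log2_intensity"]
        b = normalize_channels(shifted)["log2_intensity"]
        assert np.allclose(a, b, atol=1e-12)

    def test_arbitrary_shifts_do_not_change_contrasts(self, balanced_peptides):
        # any per-group constant offsets cancel in every peptide delta
        shifted = balanced_peptides.copy()
        for g, c in zip(GROUPS, (1.3, -0.4, 2.2, 0.05)):
            shifted.loc[shifted["group"] == g, "log2_intensity"] += c
        qa = quantify_proteins(normalize_channels(balanced_peptides))
        qb = quantify_proteins(normalize_channels(shifted))
        assert np.allclose(qa["log2_fc"], qb["log2_fc"], atol=1e-10)

    def test_missing_group_is_named(self, balanced_peptides):
        broken = balanced_peptides[balanced_peptides["group"] != "DTMP"]
        with pytest.raises(ValueError, match="DTMP"):
            normalize_channels(broken)


# ---------------------------------------------------------------------------
# protein fold change and t-test
# ---------------------------------------------------------------------------

class TestProteinQuant:
    def test_identical_channels_give_zero_fc(self):
        table = peptide_table({"P1": {g: [10.0, 11.0, 12.0] for g in GROUPS}})
        frag = protein_fold_change(table, "P1", PAIN)
        assert frag["log2_fc"] == 0.0
        assert frag["linear_ratio"] == 1.0

    def test_mean_of_peptide_deltas(self):
        table = peptide_table(
            {"P1": {"NoSNI": [10.0, 10.0, 10.0], "NoSCS": [10.5, 10.7, 10.6]}}
        )
        frag = protein_fold_change(table, "P1", PAIN)
        assert frag["log2_fc"] == pytest.approx(0.6)
        assert frag["linear_ratio"] == pytest.approx(2**0.6)  # ~1.5157
        assert frag["n_peptides"] == 3

    def test_non_unique_peptides_excluded(self):
        table = peptide_table(
            {"P1": {"NoSNI": [10, 10, 10, 10], "NoSCS": [11, 11, 11, 20]}},
            unique={"P1_pep4": False},
        )
        frag = protein_fold_change(table, "P1", PAIN)
        assert frag["n_peptides"] == 3
        assert frag["log2_fc"] == pytest.approx(1.0)

    def test_t_test_reference_values(self):
        p = protein_t_test([0.2, 0.3, 0.25, 0.15])
        # t = 0.225 / (0.0645497/2) = 6.9714 on 3 df
        assert p == pytest.approx(0.0060568, abs=5e-6)

    def test_t_test_symmetric_deltas(self):
        assert protein_t_test([-0.4, 0.4]) == pytest.approx(1.0)

    def test_t_test_undefined_cases(self):
        assert math.isnan(protein_t_test([0.3]))
        assert math.isnan(protein_t_test([0.3, 0.3, 0.3]))
        with pytest.raises(ValueError):
            protein_t_test([])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=12))
    def test_t_test_matches_manual_formula(self, deltas):
        d = np.asarray(deltas)
        sd = d.std(ddof=1)
        p = protein_t_test(d)
        if sd < 1e-9:
            assert math.isnan(p)
        else:
            t = d.mean() / (sd / math.sqrt(len(d)))
            assert p == pytest.approx(2 * stats.t.sf(abs(t), len(d) - 1), abs=1e-9)

    def test_table_quant_matches_per_protein_path(self, balanced_peptides):
        table = normalize_channels(balanced_peptides)
        q = quantify_proteins(table)
        for _, row in q.iterrows():
            contrast = next(c for c in CONTRASTS if c.name == row["contrast"])
            frag = protein_fold_change(table, row["entity_id"], contrast)
            assert row["log2_fc"] == pytest.approx(frag["log2_fc"], abs=1e-12)
            deltas = table_deltas(table, row["entity_id"], contrast)
            p_ref = protein_t_test(deltas)
            if math.isnan(p_ref):
                assert math.isnan(row["p_value"])
            else:
                assert row["p_value"] == pytest.approx(p_ref, abs=1e-12)

    def test_antisymmetry_under_contrast_swap(self, balanced_peptides):
        table = normalize_channels(balanced_peptides)
        fwd = quantify_proteins(table, [PAIN])
        rev = quantify_proteins(table, [PAIN.swapped()])
        merged = fwd.merge(rev, on="entity_id", suffixes=("_f", "_r"))
        assert np.allclose(merged["log2_fc_f"], -merged["log2_fc_r"], atol=1e-12)


def table_deltas(table, protein_id, contrast):
    from matriq import peptide_deltas

    return peptide_deltas(table, protein_id, contrast)


# ---------------------------------------------------------------------------
# phospho fold change and CV propagation
# ---------------------------------------------------------------------------

class TestPhosphoQuant:
    def test_identical_runs_zero_fc_zero_cv(self):
        table = phospho_table({"I1": {g: [100.0, 100.0] for g in GROUPS}})
        frag = phospho_fold_change(table, "I1", PAIN)
        assert frag["log2_fc"] == 0.0
        assert frag["cv_num"] == 0.0
        assert frag["cv_fc"] == 0.0

    def test_mean_of_run_log_ratios(self):
        table = phospho_table(
            {
                "I1": {
                    "NoSNI": [100.0, 100.0],
                    "NoSCS": [120.0, 130.0],
                    "DTMP": [100.0, 100.0],
                    "LRSCS": [100.0, 100.0],
                }
            }
        )
        frag = phospho_fold_change(table, "I1", PAIN)
        # mean(log2 1.2, log2 1.3) = 0.3207730; 2**fc = sqrt(1.56) = 1.2489996
        assert frag["log2_fc"] == pytest.approx(0.3207730, abs=1e-6)
        assert frag["linear_ratio"] == pytest.approx(1.2489996, abs=1e-6)

    def test_duplicate_cv_uses_n_minus_1_sd(self):
        table = phospho_table({"I1": {g: [100.0, 120.0] for g in GROUPS}})
        frag = phospho_fold_change(table, "I1", PAIN)
        assert frag["cv_num"] == pytest.approx(0.1285649, abs=1e-6)

    def test_missing_run_gives_no_quant(self):
        table = phospho_table({"I1": {g: [100.0, 120.0] for g in GROUPS}})
        table = table[~((table["group"] == "NoSCS") & (table["run_id"] == "run2"))]
        assert phospho_fold_change(table, "I1", PAIN) is None
        q = quantify_phospho(table)
        assert "pain" not in set(q[q["entity_id"] == "I1"]["contrast"])

    def test_table_quant_matches_per_isoform_path(self):
        rng = np.random.default_rng(5)
        vals = {
            f"I{i}": {g: list(rng.lognormal(10, 1, size=2)) for g in GROUPS}
            for i in range(5)
        }
        table = phospho_table(vals)
        q = quantify_phospho(table)
        for _, row in q.iterrows():
            contrast = next(c for c in CONTRASTS if c.name == row["contrast"])
            frag = phospho_fold_change(table, row["entity_id"], contrast)
            assert row["log2_fc"] == pytest.approx(frag["log2_fc"], abs=1e-12)
            assert row["cv_fc"] == pytest.approx(frag["cv_fc"], abs=1e-12)


class TestCvPropagation:
    @pytest.mark.parametrize(
        "cv_num,cv_den,expected",
        [(0.03, 0.04, 0.05), (0.0, 0.07, 0.07), (0.10, 0.10, math.sqrt(0.02))],
    )
    def test_closed_form(self, cv_num, cv_den, expected):
        assert propagate_cv(cv_num, cv_den) == pytest.approx(expected, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            propagate_cv(-0.1, 0.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0, 1))
    def test_symmetric_monotone_dominating(self, a, b, eps):
        assert propagate_cv(a, b) == propagate_cv(b, a)
        assert propagate_cv(a, b) >= max(a, b)
        assert propagate_cv(a + eps, b) >= propagate_cv(a, b)


class TestPercentChange:
    @pytest.mark.parametrize(
        "fc,expected", [(0.0, 0.0), (1.0, 100.0), (-0.152003093, -10.0)]
    )
    def test_closed_form(self, fc, expected):
        assert percent_change(fc) == pytest.approx(expected, abs=1e-6)
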