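import numpy as np
import pandas as pd
import pytest

from genefamscan.expression import delta_delta_ct, parse_sample_label, scale_matrix
from genefamscan.synthetic_data import generate_expression_profiles


def _ct_rows(gene, tissue, condition, timepoint, ct, reps=3):
    return [
        {
            "gene": gene, "tissue": tissue, "condition": condition,
            "timepoint": timepoint, "replicate": r, "ct": ct,
        }
        for r in range(1, reps + 1)
    ]


def _simple_ct_table():
    rows = []
    rows += _ct_rows("target", "leaf", "salt", 0.0, 26.0)
    rows += _ct_rows("target", "leaf", "salt", 3.0, 24.0)
    rows += _ct_rows("histone3", "leaf", "salt", 0.0, 20.0)
    rows += _ct_rows("histone3", "leaf", "salt", 3.0, 20.0)
    return pd.DataFrame(rows)


class TestDeltaDeltaCt:
    def test_worked_arithmetic_example(self):
        # ddCt = (24-20) - (26-20) = -2  ->  fold = 4
        rel = delta_delta_ct(_simple_ct_table(), "histone3")
        folds = rel.folds.set_index("timepoint")["fold"]
        assert folds[3.0] == pytest.approx(4.0)

    def test_control_fold_is_exactly_one(self):
        rel = delta_delta_ct(_simple_ct_table(), "histone3")
        folds = rel.folds.set_index("timepoint")["fold"]
        assert folds[0.0] == 1.0

    def test_invariant_to_per_sample_ct_shift(self):
        table = _simple_ct_table()
        shifted = table.copy()
        mask = shifted["timepoint"] == 3.0
        shifted.loc[mask, "ct"] += 1.7  # same shift to target and reference
        r1 = delta_delta_ct(table, "histone3").folds
        r2 = delta_delta_ct(shifted, "histone3").folds
        assert np.allclose(r1["fold"], r2["fold"])

    def test_missing_reference_is_error(self):
        table = _simple_ct_table()
        table = table[table["gene"] != "histone3"]
        table = pd.concat(
            [table, pd.DataFrame(_ct_rows("histone3", "leaf", "salt", 0.0, 20.0))]
        )
        with pytest.raises(ValueError, match="reference"):
            delta_delta_ct(table, "histone3")

    def test_missing_control_is_error(self):
        table = _simple_ct_table()
        table = table[table["timepoint"] != 0.0]
        with pytest.raises(ValueError, match="control"):
            delta_delta_ct(table, "histone3")

    def test_nonpositive_ct_is_error(self):
        table = _simple_ct_table()
        table.loc[0, "ct"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            delta_delta_ct(table, "histone3")

    def test_replicate_sd_propagated(self):
        rows = [
            {"gene": "target", "tissue": "leaf", "condition": "salt",
             "timepoint": 3.0, "replicate": r, "ct": ct}
            for r, ct in enumerate((23.0, 24.0, 25.0), start=1)
        ]
        rows += _ct_rows("target", "leaf", "salt", 0.0, 26.0)
        rows += _ct_rows("histone3", "leaf", "salt", 0.0, 20.0)
        rows += _ct_rows("histone3", "leaf", "salt", 3.0, 20.0)
        rel = delta_delta_ct(pd.DataFrame(rows), "histone3")
        sd = rel.folds.set_index("timepoint")["sd_factor"]
        assert sd[3.0] > 1.0  # variability present
        assert sd[0.0] == pytest.approx(1.0)  # noise-free control


class TestScaleMatrix:
    def _matrix(self):
        return pd.DataFrame(
            {
                "salt_0h": [10.0, 5.0],
                "salt_3h": [40.0, 5.0],
            },
            index=["g1", "g2"],
        )

    def test_log2_of_zero_fpkm(self):
        m = pd.DataFrame({"salt_0h": [0.0]}, index=["g"])
        scaled, _ = scale_matrix(m, "log2")
        assert scaled.iloc[0, 0] == 0.0

    def test_constant_gene_zscore_and_call(self):
        scaled, responsive = scale_matrix(self._matrix(), "zscore")
        assert np.allclose(scaled.loc["g2"], 0.0)
        assert not responsive["g2"]

    def test_fourfold_induction_called_responsive(self):
        _, responsive = scale_matrix(self._matrix(), "log2")
        assert responsive["g1"]

    def test_missing_control_is_error(self):
        m = pd.DataFrame({"salt_3h": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="control"):
            scale_matrix(m)

    def test_bad_label_is_error(self):
        with pytest.raises(ValueError):
            parse_sample_label("salt-3h")


class TestGeneratorClosure:
    def test_noise_free_folds_recovered(self, small_family):
        fpkm, ct, planted = generate_expression_profiles(
            small_family.truth,
            conditions=("salt",),
            seed=3,
            noise_sd=0.0,
            ct_noise_sd=0.0,
        )
        rel = delta_delta_ct(ct, "histone3")
        for _, row in rel.folds.iterrows():
            expected = planted[row.gene] if row.timepoint in (3.0, 6.0) else 1.0
            assert row.fold == pytest.approx(expected)

    def test_nonresponsive_gene_fold_one(self, small_family):
        _, ct, planted = generate_expression_profiles(
            small_family.truth, conditions=("cold",), seed=5,
            noise_sd=0.0, ct_noise_sd=0.0,
        )
        quiet = [g for g, f in planted.items() if f == 1.0]
        rel = delta_delta_ct(ct, "histone3").folds
        sub = rel[rel.gene.isin(quiet)]
        assert np.allclose(sub["fold"], 1.0)

    def test_seeds_differ(self, small_family):
        m1, _, _ = generate_expression_profiles(small_family.truth, seed=1)
        m2, _, _ = generate_expression_profiles(small_family.truth, seed=2)
        assert not m1.equals(m2)

    def test_responsive_genes_called_from_fpkm(self, small_family):
        fpkm, _, planted = generate_expression_profiles(
            small_family.truth, conditions=("salt",), seed=3, noise_sd=0.0
        )
        _, responsive = scale_matrix(fpkm, "log2")
        for gene, fold in planted.items():
            assert responsive[gene] == (fold >= 2.0)

    def test_invalid_condition_rejected(self, small_family):
        with pytest.raises(ValueError, match="unknown conditions"):
            generate_expression_profiles(small_family.truth, conditions=("frost",))

    def test_missing_control_timepoint_rejected(self, small_family):
        with pytest.raises(ValueError, match="include 0"):
            generate_expression_profiles(
                small_family.truth, timepoints=(1, 3), seed=1
            )
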