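"""Seed-family aggregation, ddCt displacement and ATP-linked OCR."""

import math

import numpy as np
import pandas as pd
import pytest

from cystometer import (
    PlantedExpressionModel,
    assign_seed_family,
    atp_linked_ocr,
    cross_model_correlation,
    family_cumulative_fold_change,
    family_pool_contribution,
    generate_expression_table,
    generate_mipsa_table,
    generate_ocr_trace,
    mipsa_displacement,
    summarize_families,
)


def _table(rows):
    """rows: (mirna_id, control_mean, disease_mean, significant, family_id)."""
    return pd.DataFrame(
        [
            {
                "mirna_id": mid,
                "mature_sequence": "N" * 22,
                "family_id": fam,
                "control_1": c,
                "control_2": c,
                "disease_1": d,
                "disease_2": d,
                "log2_fc": math.log2(d / c) if c > 0 and d > 0 else math.nan,
                "significant": sig,
            }
            for mid, c, d, sig, fam in rows
        ]
    )


class TestSeedFamily:
    def test_shared_seed_groups_together(self):
        df = pd.DataFrame(
            {
                "mirna_id": ["miR-17", "miR-106a"],
                "mature_sequence": [
                    "UAAAGUGCUUACAGUGCAGGUAG",
                    "CAAAGUGCUUAUAGUGCAGGUAG",
                ],
            }
        )
        out = assign_seed_family(df)
        assert out["seed_7mer"].tolist() == ["AAAGUGC", "AAAGUGC"]
        assert out["family_id"].nunique() == 1

    def test_position_one_is_ignored(self):
        df = pd.DataFrame(
            {
                "mirna_id": ["a", "b"],
                "mature_sequence": ["AGGCCUUAAACCUU", "UGGCCUUAAACCUU"],
            }
        )
        out = assign_seed_family(df)
        assert out["family_id"].iloc[0] == out["family_id"].iloc[1]

    def test_short_sequence_unassigned(self):
        out = assign_seed_family(
            pd.DataFrame({"mirna_id": ["x"], "mature_sequence": ["ACGUAC"]})
        )
        assert out["family_id"].isna().all()

    def test_name_map_renames_families(self):
        df = pd.DataFrame(
            {"mirna_id": ["miR-17"], "mature_sequence": ["UAAAGUGCUUACAGUGCAGGUAG"]}
        )
        out = assign_seed_family(df, name_map={"AAAGUGC": "miR-17-family"})
        assert out["family_id"].iloc[0] == "miR-17-family"

    def test_dna_input_accepted(self):
        df = pd.DataFrame({"mirna_id": ["a"], "mature_sequence": ["TAAAGTGCTTACAGTGCAGG"]})
        assert assign_seed_family(df)["seed_7mer"].iloc[0] == "AAAGUGC"


class TestCumulativeFoldChange:
    def test_single_member_equal_means_is_zero(self):
        t = _table([("m1", 100.0, 100.0, True, "f")])
        assert family_cumulative_fold_change(t, "f") == 0.0

    def test_pooled_counts_definition(self):
        t = _table([("m1", 100.0, 300.0, True, "f"), ("m2", 100.0, 100.0, True, "f")])
        assert family_cumulative_fold_change(t, "f") == 1.0  # log2(400/200)

    def test_significant_only_vs_all_expressed(self):
        t = _table([("m1", 100.0, 400.0, True, "f"), ("m2", 100.0, 100.0, False, "f")])
        assert family_cumulative_fold_change(t, "f", "significant_only") == 2.0
        assert family_cumulative_fold_change(t, "f", "all_expressed") == pytest.approx(
            math.log2(500.0 / 200.0)
        )

    def test_single_member_matches_row_fold_change(self):
        t = _table([("m1", 50.0, 175.0, True, "f")])
        assert family_cumulative_fold_change(t, "f") == pytest.approx(
            t["log2_fc"].iloc[0]
        )

    def test_sum_log2fc_mode(self):
        t = _table([("m1", 100.0, 200.0, True, "f"), ("m2", 100.0, 200.0, True, "f")])
        assert family_cumulative_fold_change(t, "f", method="sum_log2fc") == 2.0

    def test_zero_control_total_raises(self):
        t = _table([("m1", 0.0, 100.0, True, "f")])
        with pytest.raises(ValueError):
            family_cumulative_fold_change(t, "f")

    def test_no_eligible_members_raises(self):
        t = _table([("m1", 100.0, 100.0, False, "f")])
        with pytest.raises(ValueError):
            family_cumulative_fold_change(t, "f", "significant_only")


class TestPoolContribution:
    def test_equal_partition(self):
        rows = [(f"m{i}", 50.0, 50.0, False, f"f{i % 4}") for i in range(8)]
        t = _table(rows)
        for fam in ("f0", "f1", "f2", "f3"):
            assert family_pool_contribution(t, fam, "disease") == pytest.approx(25.0)

    def test_fraction_arithmetic(self):
        t = _table([("m1", 27.0, 27.0, False, "f"), ("m2", 973.0, 973.0, False, "g")])
        assert family_pool_contribution(t, "f", "control") == pytest.approx(2.7)

    def test_absent_family_is_zero(self):
        t = _table([("m1", 10.0, 10.0, False, "f")])
        assert family_pool_contribution(t, "missing", "control") == 0.0

    def test_partition_sums_to_100(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"m{i}", float(rng.integers(1, 1000)), float(rng.integers(1, 1000)), False, f"f{i % 7}")
            for i in range(40)
        ]
        t = _table(rows)
        total = sum(family_pool_contribution(t, f"f{k}", "disease") for k in range(7))
        assert total == pytest.approx(100.0, abs=1e-9)


class TestCrossModelCorrelation:
    def test_identical_vectors(self):
        v = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert cross_model_correlation(v, v) == pytest.approx(1.0)

    def test_perfect_linear_relation(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert cross_model_correlation(a, 2 * a) == pytest.approx(1.0)

    def test_closed_form_quarter(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        b = pd.Series([1.0, 3.0, 2.0], index=["a", "b", "c"])
        assert cross_model_correlation(a, b) == 0.25  # Pearson r is exactly 0.5

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        idx = [f"m{i}" for i in range(20)]
        a = pd.Series(rng.normal(size=20), index=idx)
        b = pd.Series(rng.normal(size=20), index=idx)
        r2 = cross_model_correlation(a, b)
        assert cross_model_correlation(b, a) == pytest.approx(r2)
        assert cross_model_correlation(3.0 * a - 2.0, -0.5 * b + 7.0) == pytest.approx(r2)

    def test_intersection_of_ids(self):
        a = pd.Series([1.0, 2.0, 3.0, 9.0], index=["a", "b", "c", "only_a"])
        b = pd.Series([2.0, 4.0, 6.0, -9.0], index=["a", "b", "c", "only_b"])
        assert cross_model_correlation(a, b) == pytest.approx(1.0)

    def test_too_few_shared_raises(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            cross_model_correlation(a, a)

    def test_zero_variance_flagged(self):
        a = pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"])
        b = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            assert math.isnan(cross_model_correlation(a, b))


def _ct_table(rows):
    return pd.DataFrame(
        [
            {"gene": g, "role": role, "condition": cond, "replicate": 1, "ct": ct}
            for g, role, cond, ct in rows
        ]
    )


class TestMipsaDisplacement:
    def test_all_equal_is_zero(self):
        t = _ct_table(
            [
                ("miR-17", "target", "treated", 20.0),
                ("miR-17", "target", "control", 20.0),
                ("let-7d", "reference", "treated", 18.0),
                ("let-7d", "reference", "control", 18.0),
            ]
        )
        assert mipsa_displacement(t) == 0.0

    def test_worked_example(self):
        t = _ct_table(
            [
                ("miR-17", "target", "treated", 21.0),
                ("miR-17", "target", "control", 20.0),
                ("let-7d", "reference", "treated", 18.0),
                ("let-7d", "reference", "control", 18.0),
            ]
        )
        assert mipsa_displacement(t) == 1.0  # (21-18) - (20-18)

    def test_reference_shift_cancels(self):
        base = generate_mipsa_table(1.0, 0.0, 0.0, seed=0)
        shifted = generate_mipsa_table(1.0, 3.0, 0.0, seed=0)
        assert mipsa_displacement(base) == pytest.approx(mipsa_displacement(shifted))

    def test_missing_cell_raises(self):
        t = _ct_table([("miR-17", "target", "treated", 21.0)])
        with pytest.raises(ValueError):
            mipsa_displacement(t)

    def test_noisy_recovery_within_propagated_error(self):
        # displacement is a sum/difference of 4 replicate means: its sd is
        # noise_sd * sqrt(4 / n_reps)
        noise_sd, n_reps = 0.2, 4
        est = [
            mipsa_displacement(generate_mipsa_table(1.5, 0.0, noise_sd, seed=s, n_replicates=n_reps))
            for s in range(30)
        ]
        sd = noise_sd * math.sqrt(4 / n_reps)
        assert abs(np.mean(est) - 1.5) < 3 * sd / math.sqrt(len(est))


class TestAtpLinkedOcr:
    def test_printed_formula(self):
        t = generate_ocr_trace(atp_linked=60.0, basal_level=100.0, seed=0)
        assert atp_linked_ocr(t) == 60.0

    def test_equal_phases_give_zero(self):
        t = generate_ocr_trace(atp_linked=0.0, seed=0)
        assert atp_linked_ocr(t) == 0.0

    def test_negative_value_warned_not_raised(self):
        t = generate_ocr_trace(atp_linked=-10.0, seed=0)
        with pytest.warns(UserWarning):
            assert atp_linked_ocr(t) == pytest.approx(-10.0)

    def test_missing_phase_raises(self):
        t = generate_ocr_trace(seed=0)
        with pytest.raises(ValueError):
            atp_linked_ocr(t[t["phase"] != "oligomycin"])


class TestPlantedRecovery:
    def test_zero_dispersion_recovers_family_fold_changes_exactly(self):
        model = PlantedExpressionModel(
            families=(
                ("f17", "AAAGUGC", ("m1", "m2", "m3"), 1.0),
                ("f21", "AGCUUAU", ("m4", "m5"), -0.5),
                ("fnull", "GAGGUAG", ("m6", "m7"), 0.0),
            ),
            dispersion=0.0,
            seed=3,
        )
        t = generate_expression_table(model)
        assert family_cumulative_fold_change(t, "f17", "all_expressed") == 1.0
        assert family_cumulative_fold_change(t, "f21", "all_expressed") == pytest.approx(
            -0.5, abs=1e-12
        )
        assert family_cumulative_fold_change(t, "fnull", "all_expressed") == 0.0

    def test_error_shrinks_with_baseline_counts(self):
        def mae(baseline):
            errs = []
            for seed in range(8):
                model = PlantedExpressionModel(
                    families=(("f", "AAAGUGC", ("m1", "m2", "m3", "m4"), 1.0),),
                    dispersion=0.002,
                    baseline_counts=baseline,
                    n_control=6,
                    n_disease=6,
                    seed=seed,
                )
                t = generate_expression_table(model)
                errs.append(abs(family_cumulative_fold_change(t, "f", "all_expressed") - 1.0))
            return np.mean(errs)

        assert mae(20000.0) < mae(50.0)

    def test_summarize_families_table(self):
        model = PlantedExpressionModel(
            families=(
                ("f17", "AAAGUGC", ("m1", "m2"), 1.0),
                ("fnull", "GAGGUAG", ("m3", "m4"), 0.0),
            ),
            seed=0,
        )
        fam = summarize_families(generate_expression_table(model))
        assert set(fam["family_id"]) == {"f17", "fnull"}
        row = fam.set_index("family_id").loc["f17"]
        assert row["n_members_total"] == 2
        assert row["cumulative_log2_fc_all"] == 1.0
        assert fam["pool_pct_disease"].sum() == pytest.approx(100.0)
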