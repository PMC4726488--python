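"""Per-metabolite association scans, Bonferroni thresholds and set logic."""

import numpy as np
import pandas as pd
import pytest

from dopametab import (
    Contrast,
    Group,
    MetaboliteMatrix,
    Scale,
    Sex,
    bonferroni_threshold,
    classify,
    default_contrasts,
    fit_metabolite_model,
    run_scan,
)

from conftest import toy_matrix


class TestBonferroniThreshold:
    def test_metabolome_wide_threshold(self):
        # 0.05/456 = 1.0965e-4, quoted as 1.09e-4 (truncated 3 digits)
        thr = bonferroni_threshold(0.05, 456)
        assert thr == pytest.approx(1.09e-4, abs=1e-6)

    def test_single_test_recovers_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_metabogenomic_threshold(self):
        thr = bonferroni_threshold(0.05, 32 * 456)
        assert thr == pytest.approx(3.43e-6, rel=5e-3)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _two_group_annotation(n_per_group, seed=0, case=Group.PD):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_group):
        grp = case if i < n_per_group else Group.CONTROL
        rows.append(
            {
                "sample_id": f"s{i}",
                "group": grp.value,
                "age": float(rng.normal(65, 8)),
                "sex": float(rng.integers(0, 2)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _matrix_from_array(vals, annotation):
    frame = pd.DataFrame(
        np.asarray(vals, dtype=float),
        index=annotation.index,
        columns=[f"m{j}" for j in range(np.asarray(vals).shape[1])],
    )
    return MetaboliteMatrix(
        data=frame,
        run_day=pd.Series("d0", index=annotation.index),
        scale=Scale.LOG,
    )


class TestFitMetaboliteModel:
    def test_matches_vectorized_scan(self):
        rng = np.random.default_rng(1)
        ann = _two_group_annotation(100, seed=1)
        vals = rng.normal(size=(200, 5))
        matrix = _matrix_from_array(vals, ann)
        contrast = Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL)
        table = run_scan(matrix, ann, [contrast])
        for met in matrix.metabolite_ids:
            rec = fit_metabolite_model(matrix.data[met], ann, contrast)
            row = table[table["metabolite_id"] == met].iloc[0]
            assert rec.beta == pytest.approx(row["beta"], rel=1e-10)
            assert rec.se == pytest.approx(row["se"], rel=1e-10)
            assert rec.p_value == pytest.approx(row["p_value"], rel=1e-8)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(2)
        ann = _two_group_annotation(100, seed=2)
        vals = rng.normal(size=(200, 1000))
        matrix = _matrix_from_array(vals, ann)
        table = run_scan(matrix, ann,
                         [Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL)])
        frac = float((table["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_injected_shift_recovered(self):
        rng = np.random.default_rng(3)
        ann = _two_group_annotation(500, seed=3)
        y = rng.normal(size=(1000, 1))
        y[(ann["group"] == "PD").to_numpy(), 0] += 1.0
        matrix = _matrix_from_array(y, ann)
        rec = fit_metabolite_model(
            matrix.data["m0"], ann,
            Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL),
        )
        assert 0.8 <= rec.beta <= 1.2
        assert rec.p_value < 1e-10

    def test_age_only_effect_leaves_case_null(self):
        rng = np.random.default_rng(4)
        ann = _two_group_annotation(300, seed=4)
        y = 0.05 * ann["age"].to_numpy()[:, None] + rng.normal(size=(600, 1))
        matrix = _matrix_from_array(y, ann)
        rec = fit_metabolite_model(
            matrix.data["m0"], ann,
            Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL),
        )
        assert abs(rec.beta) < 3 * rec.se

    def test_swapping_groups_negates_beta_and_preserves_p(self):
        rng = np.random.default_rng(5)
        ann = _two_group_annotation(50, seed=5)
        y = rng.normal(size=(100, 1))
        matrix = _matrix_from_array(y, ann)
        fwd = fit_metabolite_model(
            matrix.data["m0"], ann,
            Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL),
        )
        rev = fit_metabolite_model(
            matrix.data["m0"], ann,
            Contrast("CONTROL_vs_PD", Group.CONTROL, Group.PD),
        )
        assert rev.beta == pytest.approx(-fwd.beta, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)

    def test_constant_offset_changes_only_intercept(self):
        rng = np.random.default_rng(6)
        ann = _two_group_annotation(50, seed=6)
        y = rng.normal(size=(100, 1))
        matrix = _matrix_from_array(y, ann)
        shifted = _matrix_from_array(y + 7.5, ann)
        contrast = Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL)
        a = fit_metabolite_model(matrix.data["m0"], ann, contrast)
        b = fit_metabolite_model(shifted.data["m0"], ann, contrast)
        assert b.beta == pytest.approx(a.beta, abs=1e-10)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)

    def test_rank_deficient_design_raises(self):
        ann = _two_group_annotation(20, seed=7)
        ann["sex"] = ann["age"]  # force collinearity
        y = pd.Series(np.random.default_rng(7).normal(size=40),
                      index=ann.index, name="m0")
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_metabolite_model(
                y, ann, Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL)
            )


class TestRunScan:
    def test_single_metabolite_threshold_equals_alpha(self):
        rng = np.random.default_rng(8)
        ann = _two_group_annotation(200, seed=8)
        y = rng.normal(size=(400, 1))
        y[(ann["group"] == "PD").to_numpy(), 0] += 0.3  # p ~ 0.003
        matrix = _matrix_from_array(y, ann)
        table = run_scan(matrix, ann,
                         [Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL)])
        row = table.iloc[0]
        assert bool(row["significant"]) == bool(row["p_value"] < 0.05)

    def test_listwise_deletion_with_missing_y(self):
        rng = np.random.default_rng(9)
        ann = _two_group_annotation(100, seed=9)
        vals = rng.normal(size=(200, 2))
        vals[:5, 0] = np.nan
        matrix = _matrix_from_array(vals, ann)
        table = run_scan(matrix, ann,
                         [Contrast("PD_vs_CONTROL", Group.PD, Group.CONTROL)])
        n_used = table.set_index("metabolite_id")["n_used"]
        assert n_used["m0"] == 195
        assert n_used["m1"] == 200

    def test_empty_contrast_group_is_an_error(self):
        ann = _two_group_annotation(30, seed=10)
        matrix = _matrix_from_array(
            np.random.default_rng(10).normal(size=(60, 2)), ann
        )
        with pytest.raises(ValueError, match="empty group"):
            run_scan(matrix, ann,
                     [Contrast("RLS_vs_CONTROL", Group.RLS, Group.CONTROL)])

    def test_injected_effects_recovered_without_censoring(self, uncensored_cohort):
        # Without intensity-dependent truncation the full pipeline
        # (day normalization, imputation of random dropout, OLS scan)
        # recovers every injected shift within +-3 SE.
        truth = uncensored_cohort["truth"]
        table = run_scan(
            uncensored_cohort["log"], uncensored_cohort["annotation"],
            default_contrasts(), n_tests=456,
        )
        for contrast_label, contrast_name in (
            ("PD", "PD_vs_CONTROL"), ("RLS", "RLS_vs_CONTROL")
        ):
            sub = table[table["contrast"] == contrast_name].set_index(
                "metabolite_id"
            )
            for met, shift in truth.group_effects[contrast_label].items():
                if met not in sub.index:
                    continue  # dropped by QC
                row = sub.loc[met]
                assert abs(row["beta"] - shift) < 3 * row["se"]

    def test_strong_shifts_detected_despite_censoring(self, default_cohort):
        # Left-censoring attenuates effect estimates toward zero (the
        # truncated tail is imputed near the conditional mean), but
        # detection and sign of strong shifts survive.
        truth = default_cohort["truth"]
        table = run_scan(
            default_cohort["log"], default_cohort["annotation"],
            default_contrasts(), n_tests=456,
        )
        threshold = bonferroni_threshold(0.05, 456)
        for contrast_label, contrast_name in (
            ("PD", "PD_vs_CONTROL"), ("RLS", "RLS_vs_CONTROL")
        ):
            sub = table[table["contrast"] == contrast_name].set_index(
                "metabolite_id"
            )
            n_strong = n_detected = 0
            for met, shift in truth.group_effects[contrast_label].items():
                if met not in sub.index or abs(shift) < 0.8:
                    continue
                row = sub.loc[met]
                n_strong += 1
                n_detected += int(row["p_value"] < threshold)
                assert np.sign(row["beta"]) == np.sign(shift)
                # attenuation is toward zero, never past the true value
                assert abs(row["beta"]) < abs(shift) + 3 * row["se"]
                # beyond the truncation bias (~0.27 log-units) plus 3 SE
                # of sampling noise, detection is certain
                if abs(shift) >= 1.05:
                    assert row["p_value"] < threshold
            # at |shift| >= 0.8 per-metabolite power is ~0.85 after the
            # censoring attenuation; the majority must still be detected
            if n_strong >= 3:
                assert n_detected / n_strong >= 0.5


class TestClassify:
    def _toy_table(self, rows):
        frame = pd.DataFrame(
            rows,
            columns=["metabolite_id", "contrast", "beta", "direction",
                     "p_value", "significant"],
        )
        return frame

    def test_shared_and_unique_sets(self):
        rows = [
            ("A", "PD_vs_CONTROL", -1.0, "DOWN", 1e-9, True),
            ("A", "RLS_vs_CONTROL", -0.8, "DOWN", 1e-7, True),
            ("A", "PD_vs_RLS", -0.1, "DOWN", 0.4, False),
            ("B", "PD_vs_CONTROL", 0.5, "UP", 1e-6, True),
            ("B", "RLS_vs_CONTROL", 0.1, "UP", 0.2, False),
            ("B", "PD_vs_RLS", 0.4, "UP", 0.01, False),
            ("C", "PD_vs_CONTROL", 0.1, "UP", 0.3, False),
            ("C", "RLS_vs_CONTROL", 0.9, "UP", 1e-8, True),
            ("C", "PD_vs_RLS", -0.8, "DOWN", 1e-5, True),
        ]
        cls = classify(self._toy_table(rows))
        assert cls.shared_unidirectional == {"A"}
        assert cls.pd_unique == {"B"}
        assert cls.rls_unique == {"C"}
        assert cls.pd_vs_rls == {"C"}
        assert cls.discordant == set()

    def test_discordant_metabolite_in_no_main_set(self):
        rows = [
            ("A", "PD_vs_CONTROL", 1.0, "UP", 1e-9, True),
            ("A", "RLS_vs_CONTROL", -1.0, "DOWN", 1e-9, True),
            ("A", "PD_vs_RLS", 0.0, "UP", 1.0, False),
        ]
        cls = classify(self._toy_table(rows))
        assert cls.discordant == {"A"}
        assert not cls.shared_unidirectional
        assert not cls.pd_unique and not cls.rls_unique

    def test_sets_are_disjoint_on_default_cohort(self, default_cohort):
        table = run_scan(
            default_cohort["log"], default_cohort["annotation"],
            default_contrasts(), n_tests=456,
        )
        cls = classify(table)
        assert not (cls.pd_unique & cls.rls_unique)
        assert not (cls.shared_unidirectional & cls.pd_unique)
        assert not (cls.shared_unidirectional & cls.rls_unique)

    def test_disjoint_injected_effects_recovered_uniquely(self, default_cohort):
        truth = default_cohort["truth"]
        table = run_scan(
            default_cohort["log"], default_cohort["annotation"],
            default_contrasts(), n_tests=456,
        )
        cls = classify(table)
        # |shift| >= 1.05 clears the censoring attenuation plus 3 SE, so
        # detection (and hence unique classification) is guaranteed
        strong_pd = {m for m, s in truth.group_effects["PD"].items()
                     if abs(s) >= 1.05}
        strong_rls = {m for m, s in truth.group_effects["RLS"].items()
                      if abs(s) >= 1.05}
        # injected sets are disjoint, so strong effects classify uniquely
        assert strong_pd <= cls.pd_unique | cls.shared_unidirectional
        assert strong_pd & cls.pd_unique == strong_pd - cls.shared_unidirectional
        assert strong_rls <= cls.rls_unique | cls.shared_unidirectional
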