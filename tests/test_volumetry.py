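"""eTIV normalization, three-group ANOVA and clinical correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thalnet as tn
from thalnet.labels import NUCLEUS_COLUMNS
from thalnet.volumetry import UndefinedCorrelationError

from oracles import anova_oracle


def _cohort_from_volumes(pct_by_group: dict[str, np.ndarray],
                         etiv: float = 1000.0) -> tn.CohortTable:
    """Build a cohort whose percent volumes are given per group (one region
    of interest; all other regions filled with constants plus jitter)."""
    rng = np.random.default_rng(0)
    rows = []
    for g, vals in pct_by_group.items():
        for i, v in enumerate(vals):
            row = {"subject_id": f"{g}{i}", "group": g, "age": 30.0,
                   "sex": i % 2, "lesion_volume": 0.0 if g == "HC" else 5.0,
                   "eTIV": etiv, "disease_duration": np.nan}
            for c in NUCLEUS_COLUMNS:
                row[c] = etiv * (0.01 + 0.001 * rng.random()) / 100.0
            row["Left-AV"] = v * etiv / 100.0
            rows.append(row)
    return tn.CohortTable(pd.DataFrame(rows))


class TestNormalization:
    def test_direct_substitution(self, small_cohort):
        norm = tn.normalize_volumes(small_cohort)
        expected = (small_cohort.volumes()
                    / small_cohort.data["eTIV"].to_numpy()[:, None] * 100.0)
        np.testing.assert_array_equal(norm.volumes(), expected)

    def test_five_ml_of_a_litre_is_half_percent(self):
        cohort = _cohort_from_volumes({"HC": np.full(4, 0.5),
                                       "F-MS": np.full(4, 0.5),
                                       "NF-MS": np.full(4, 0.5)})
        norm = tn.normalize_volumes(cohort)
        # 5 mL at eTIV = 1000 mL was encoded as percent 0.5 above
        assert np.allclose(norm.data["Left-AV"], 0.5)
        assert np.allclose(cohort.data["Left-AV"], 5.0)

    def test_scale_invariance_of_ratio(self, small_cohort):
        doubled = small_cohort.data.copy()
        doubled["eTIV"] *= 2.0
        for c in NUCLEUS_COLUMNS:
            doubled[c] *= 2.0
        norm_a = tn.normalize_volumes(small_cohort)
        norm_b = tn.normalize_volumes(tn.CohortTable(doubled))
        np.testing.assert_allclose(norm_a.volumes(), norm_b.volumes())

    def test_covariates_untouched(self, small_cohort):
        norm = tn.normalize_volumes(small_cohort)
        for col in ("age", "sex", "lesion_volume", "eTIV"):
            np.testing.assert_array_equal(norm.data[col], small_cohort.data[col])

    def test_double_normalization_rejected(self, small_cohort):
        norm = tn.normalize_volumes(small_cohort)
        with pytest.raises(ValueError):
            tn.normalize_volumes(norm)


class TestAnova:
    def test_f_matches_sums_of_squares_oracle_and_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            samples = {g: 0.5 + 0.05 * rng.standard_normal(n)
                       for g, n in (("F-MS", 7), ("NF-MS", 9), ("HC", 12))}
            cohort = _cohort_from_volumes(samples)
            res = tn.anova_posthoc(tn.normalize_volumes(cohort), "Left-AV")
            f_oracle = anova_oracle(list(samples.values()))
            f_scipy = stats.f_oneway(*samples.values()).statistic
            assert res.f_statistic == pytest.approx(f_oracle, abs=1e-10)
            assert res.f_statistic == pytest.approx(f_scipy, rel=1e-10)

    def test_no_between_group_variance_gives_p_one(self):
        cohort = _cohort_from_volumes({
            "F-MS": np.full(5, 0.7), "NF-MS": np.full(5, 0.7),
            "HC": np.full(5, 0.7)})
        res = tn.anova_posthoc(tn.normalize_volumes(cohort), "Left-AV")
        assert res.f_statistic == 0.0
        assert res.anova_p == 1.0
        assert all(p == 1.0 for p in res.pairwise_p.values())

    def test_flags_follow_alpha(self):
        rng = np.random.default_rng(2)
        samples = {"F-MS": 0.4 + 0.02 * rng.standard_normal(10),
                   "NF-MS": 0.5 + 0.02 * rng.standard_normal(10),
                   "HC": 0.6 + 0.02 * rng.standard_normal(10)}
        res = tn.anova_posthoc(tn.normalize_volumes(
            _cohort_from_volumes(samples)), "Left-AV", alpha=0.001)
        for pair, p in res.pairwise_p.items():
            assert 0.0 <= p <= 1.0
            assert res.significant[pair] == (p < 0.001)

    def test_missing_group_rejected(self):
        cohort = _cohort_from_volumes({"F-MS": np.full(5, 0.5),
                                       "NF-MS": np.full(5, 0.6)})
        with pytest.raises(ValueError, match="three groups"):
            tn.anova_posthoc(tn.normalize_volumes(cohort), "Left-AV")

    def test_table_covers_all_regions(self, small_cohort):
        table = tn.volumetry_table(tn.normalize_volumes(small_cohort))
        assert len(table) == 50
        assert set(table["region"]) == set(NUCLEUS_COLUMNS)


class TestClinicalCorrelation:
    def _patients(self, x, y, region="Left-AV"):
        n = len(x)
        rows = []
        for i in range(n):
            row = {"subject_id": f"s{i}", "group": "F-MS" if i % 2 else "NF-MS",
                   "age": 30.0 + i, "sex": i % 2, "lesion_volume": float(y[i]),
                   "eTIV": 1000.0, "disease_duration": 2.0}
            for c in NUCLEUS_COLUMNS:
                row[c] = 10.0
            row[region] = float(x[i]) * 10.0
            rows.append(row)
        return tn.CohortTable(pd.DataFrame(rows))

    def test_perfect_monotone_gives_rho_one(self):
        x = np.arange(1.0, 11.0)
        cohort = self._patients(x, x ** 3)  # monotone, nonlinear
        res = tn.correlate_clinical(tn.normalize_volumes(cohort), "Left-AV",
                                    "lesion_volume", method="spearman")
        assert res.rho == pytest.approx(1.0)
        res_neg = tn.correlate_clinical(
            tn.normalize_volumes(self._patients(x, 12.0 - x)), "Left-AV",
            "lesion_volume")
        assert res_neg.rho == pytest.approx(-1.0)

    def test_spearman_equals_rank_product_moment_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        cohort = self._patients(np.abs(x) + 1.0, np.abs(y))
        res = tn.correlate_clinical(tn.normalize_volumes(cohort), "Left-AV",
                                    "lesion_volume", method="spearman")
        rx = stats.rankdata(np.abs(x) + 1.0)
        ry = stats.rankdata(np.abs(y))
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        cohort = self._patients(np.ones(10), np.arange(10.0))
        with pytest.raises(UndefinedCorrelationError):
            tn.correlate_clinical(tn.normalize_volumes(cohort), "Left-AV",
                                  "lesion_volume")

    def test_patient_only_variables_subset(self, default_cohort):
        norm = tn.normalize_volumes(default_cohort)
        res = tn.correlate_clinical(norm, "Right-LGN", "lesion_volume")
        n_patients = sum(len(default_cohort.group_indices(g))
                        for g in ("F-MS", "NF-MS"))
        assert res.n == n_patients
        res_age = tn.correlate_clinical(norm, "Right-LGN", "age")
        assert res_age.n == len(default_cohort)
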