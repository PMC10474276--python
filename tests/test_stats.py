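"""Cohort statistics: gated correlations, ANOVA, reference database."""

import numpy as np
import pandas as pd
import pytest

import rcmorph as rm
from rcmorph.curves import build_volume_curves
from rcmorph.schema import MUSCLES, ScanRecord
from rcmorph.stats import StatsError

from conftest import make_prism_volume


class TestCorrelationGated:
    def test_affine_gaussian_pair_uses_pearson(self):
        x = np.random.default_rng(0).standard_normal(33)
        res = rm.correlation_gated(x, 2 * x + 1)
        assert res.method == "pearson"
        assert res.r == pytest.approx(1.0)

    def test_monotone_heavy_tailed_pair_uses_spearman(self):
        x = np.random.default_rng(1).standard_t(df=1, size=50)
        res = rm.correlation_gated(x, x**3)
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            rm.correlation_gated(np.ones(10), np.arange(10.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError, match="at least 4"):
            rm.correlation_gated([1, 2, np.nan], [1, 2, 3])

    def test_missing_pairs_deleted(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.1, 6.0, 8.2, np.nan, 12.0])
        res = rm.correlation_gated(x, y)
        assert res.n == 4

    def test_bivariate_gaussian_recovers_generating_rho(self):
        """Monte-Carlo at the study's n = 33: mean r within 0.05 of 0.8."""
        rho = 0.8
        rs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(33)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(33)
            rs.append(rm.correlation_gated(x, y).r)
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)


def proportional_curve_sets(schema, n_scans=8, base=3):
    """Complete-coverage uniform-prism scans with per-scan proportions.

    Uniform prisms make every metric at partial coverage an exact linear
    function of its full-coverage value across scans, so all gated
    correlations are 1; muscle/scapula proportions vary per scan so no
    metric is constant.
    """
    sets = []
    for i in range(n_scans):
        vol = make_prism_volume(
            schema,
            scapula_area_vox=(base + i, 10),
            muscle_areas_vox={m: (3 + (i + j) % 5, 6 + 2 * j)
                              for j, m in enumerate(MUSCLES)},
        )
        sets.append(build_volume_curves(vol))
    return sets


class TestPartialVsFull:
    def test_proportional_cohort_gives_unit_correlation(self, schema):
        table = rm.partial_vs_full_analysis(proportional_curve_sets(schema))
        raw = table[table.metric == "raw_volume"]
        assert np.allclose(raw["r"], 1.0, atol=1e-9)
        assert set(raw["coverage_pct"]) == {10, 20, 30, 40}
        assert set(table["roi"]) == {"scapula", *MUSCLES}

    def test_single_scan_cohort_rejected(self, schema):
        sets = proportional_curve_sets(schema, n_scans=1)
        with pytest.raises(StatsError, match="at least 4"):
            rm.partial_vs_full_analysis(sets)

    def test_partial_coverage_scan_rejected(self, schema):
        vol = make_prism_volume(schema)
        partial = build_volume_curves(vol, predicted_length_mm=100.0)
        with pytest.raises(StatsError, match="complete-coverage"):
            rm.partial_vs_full_analysis([partial] * 5)


class TestCorrelationSweep:
    def make_records(self, n, sex="male", age=25.0):
        return [ScanRecord(f"s{i}", age, sex, "right") for i in range(n)]

    def test_exact_proportionality_gives_unit_correlation(self, schema):
        # muscle areas share the scapula's per-scan scale factor, so muscle
        # volume is an exact multiple of scapula volume at every location
        sets = [
            build_volume_curves(make_prism_volume(
                schema,
                scapula_area_vox=(3 + i, 10),
                muscle_areas_vox={m: (3 + i, k) for m, k in zip(MUSCLES, (4, 6, 8, 10))},
            ))
            for i in range(8)
        ]
        records = [ScanRecord(f"s{i}", 25.0, "male" if i % 2 else "female", "right")
                   for i in range(len(sets))]
        table = rm.scapula_muscle_correlation_sweep(sets, records)
        assert np.allclose(table["r"], 1.0, atol=1e-9)
        assert set(table["p"]) == set(range(30, 41))

    def test_age_filter_applied(self, schema):
        sets = proportional_curve_sets(schema)
        records = [ScanRecord(f"s{i}", 25.0 if i < 6 else 55.0,
                              "male" if i % 2 else "female", "right")
                   for i in range(len(sets))]
        table = rm.scapula_muscle_correlation_sweep(sets, records, strata=("all",))
        assert table["n"].unique().tolist() == [6]

    def test_empty_stratum_rejected(self, schema):
        sets = proportional_curve_sets(schema)
        records = self.make_records(len(sets), sex="male")
        with pytest.raises(StatsError, match="female"):
            rm.scapula_muscle_correlation_sweep(sets, records)

    def test_independent_muscle_volume_has_small_correlation(self, schema):
        """Null check: muscle volumes independent of scapula volume give
        |r| < 0.5 in ≥ 95% of seeds at n = 25."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            scap = rng.uniform(50, 150, size=25)
            mus = rng.uniform(50, 150, size=25)
            if abs(rm.correlation_gated(scap, mus).r) < 0.5:
                hits += 1
        assert hits >= 0.95 * n_seeds


def balanced_anova_oracle(df):
    """Closed-form balanced two-way decomposition (equal cell n)."""
    grand = df["value"].mean()
    n_cell = df.groupby(["sex", "age_bin"], observed=True).size().iloc[0]
    a_means = df.groupby("sex", observed=True)["value"].mean()
    b_means = df.groupby("age_bin", observed=True)["value"].mean()
    cell_means = df.groupby(["sex", "age_bin"], observed=True)["value"].mean()
    a, b = len(a_means), len(b_means)
    ss_a = n_cell * b * ((a_means - grand) ** 2).sum()
    ss_b = n_cell * a * ((b_means - grand) ** 2).sum()
    ss_ab = n_cell * sum(
        (cell_means[s, g] - a_means[s] - b_means[g] + grand) ** 2
        for s, g in cell_means.index
    )
    ss_err = sum(
        ((grp["value"] - cell_means[key]) ** 2).sum()
        for key, grp in df.groupby(["sex", "age_bin"], observed=True)
    )
    df_err = len(df) - a * b
    return {
        "sex": (ss_a, a - 1),
        "age_bin": (ss_b, b - 1),
        "sex:age_bin": (ss_ab, (a - 1) * (b - 1)),
        "err": (ss_err, df_err),
    }


class TestTwoWayAnova:
    def make_balanced(self, seed=0, n_cell=8, age_effect=0.0, sex_effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for sex_i, sex in enumerate(("male", "female")):
            for b, label in enumerate(("15-29", "30-39", "40-49", "50-59", "60-69", "70-89")):
                mu = 1.0 + age_effect * b + sex_effect * sex_i
                for _ in range(n_cell):
                    rows.append((rng.normal(mu, 0.15), sex, label))
        return pd.DataFrame(rows, columns=["value", "sex", "age_bin"])

    def test_identical_group_means_give_near_zero_f(self):
        df = self.make_balanced(seed=1)
        df["value"] = 1.0 + 0.01 * np.tile([-1, 1], len(df) // 2)  # pure noise, no structure
        res = rm.two_way_anova(df["value"], df["sex"], df["age_bin"])
        assert res.effects.loc["sex", "partial_eta_sq"] < 0.02
        assert res.effects.loc["age_bin", "partial_eta_sq"] < 0.05

    def test_balanced_design_matches_closed_form(self):
        """Type III reduces to the classical balanced decomposition."""
        df = self.make_balanced(seed=2, age_effect=0.05, sex_effect=0.1)
        res = rm.two_way_anova(df["value"], df["sex"], df["age_bin"])
        oracle = balanced_anova_oracle(df)
        ss_err, df_err = oracle["err"]
        for effect, (ss, dof) in oracle.items():
            if effect == "err":
                continue
            f_expected = (ss / dof) / (ss_err / df_err)
            assert res.effects.loc[effect, "F"] == pytest.approx(f_expected, abs=1e-8)
            assert res.effects.loc[effect, "df1"] == dof
            eta_expected = ss / (ss + ss_err)
            assert res.effects.loc[effect, "partial_eta_sq"] == pytest.approx(eta_expected, abs=1e-8)

    def test_posthoc_only_for_significant_main_effects(self):
        df = self.make_balanced(seed=3, age_effect=0.2)
        res = rm.two_way_anova(df["value"], df["sex"], df["age_bin"])
        assert set(res.posthoc["effect"]) <= {"age_bin", "sex"}
        age_rows = res.posthoc[res.posthoc["effect"] == "age_bin"]
        assert len(age_rows) == 15  # all pairwise comparisons of 6 bins
        assert (age_rows["p_bonferroni"] <= 1.0).all()

    def test_empty_cell_warns_or_raises(self):
        df = self.make_balanced(seed=4)
        df = df[~((df.sex == "female") & (df.age_bin == "70-89"))]
        with pytest.raises(StatsError, match="empty"):
            rm.two_way_anova(df["value"], df["sex"], df["age_bin"], on_empty_cell="raise")
        with pytest.warns(UserWarning, match="empty"):
            rm.two_way_anova(df["value"], df["sex"], df["age_bin"], on_empty_cell="warn")

    def test_single_factor_level_rejected(self):
        with pytest.raises(StatsError, match="levels"):
            rm.two_way_anova([1.0, 2.0], ["male", "male"], ["15-29", "30-39"])

    def test_injected_age_effect_detected(self):
        """Power: a 30% supraspinatus size decline across bins is detected
        at the cohort's cell size in the vast majority of seeds."""
        spec = rm.CohortSpec(n_per_cell=14, age_slope_size={"supraspinatus": -0.06})
        detected = 0
        n_seeds = 50
        for seed in range(n_seeds):
            df = rm.sample_cohort_metrics(spec, seed=seed)
            sel = df[(df.muscle == "supraspinatus") & (df.metric == "normalized_size")]
            res = rm.two_way_anova(sel["value"], sel["sex"], sel["age_bin"])
            if res.effects.loc["age_bin", "p"] < 0.05:
                detected += 1
        assert detected >= 0.8 * n_seeds


class TestReferenceDatabase:
    def tidy_cohort(self, seed=0, n_per_cell=6, identical=False):
        spec = rm.CohortSpec(n_per_cell=n_per_cell, age_slope_size={}, fat_age_slope={},
                             fat_sex_offset={}, seed=seed)
        df = rm.sample_cohort_metrics(spec, metric_cv=0.0 if identical else 0.15)
        return df.rename(columns={})

    def test_identical_scans_give_zero_sd(self):
        df = self.tidy_cohort(identical=True)
        sel = df[df.metric == "normalized_size"]
        db = rm.build_reference_database(sel)
        assert (db.cells_["sd"] == 0).all()
        assert not db.cells_["usable"].any()

    def test_single_scan_cell_flagged_unusable(self):
        df = self.tidy_cohort(n_per_cell=1)
        db = rm.build_reference_database(df[df.metric == "normalized_size"])
        assert not db.cells_["usable"].any()
        with pytest.raises(StatsError, match="unusable"):
            db.z_score(1.0, "male", 25.0, "supraspinatus", "normalized_size")

    def test_cell_means_within_three_se_of_generating_means(self):
        spec = rm.CohortSpec(n_per_cell=40, age_slope_size={}, sex_offset_size={},
                             fat_age_slope={}, fat_sex_offset={}, seed=7)
        df = rm.sample_cohort_metrics(spec, metric_cv=0.10)
        sel = df[(df.metric == "normalized_size") & (df.muscle == "supraspinatus")]
        db = rm.build_reference_database(sel)
        gen_mean = 0.9  # baseline supraspinatus normalized size
        for _, cell in db.cells_.iterrows():
            se = gen_mean * 0.10 / np.sqrt(cell["n"])
            assert abs(cell["mean"] - gen_mean) <= 3 * se

    def test_z_score_of_cell_mean_is_zero(self):
        df = self.tidy_cohort(seed=2)
        db = rm.build_reference_database(df)
        cell = db.cells_[db.cells_["usable"]].iloc[0]
        z = db.z_score(cell["mean"], cell["sex"], 20.0 if cell["age_bin"] == "15-29" else 35.0,
                       cell["muscle"], cell["metric"])
        if cell["age_bin"] in ("15-29", "30-39"):
            assert z == pytest.approx(0.0, abs=1e-12)

    def test_z_score_one_sd_above_mean_is_one(self):
        df = self.tidy_cohort(seed=3)
        db = rm.build_reference_database(df)
        sel = db.cells_[(db.cells_["sex"] == "male") & (db.cells_["age_bin"] == "15-29")
                        & (db.cells_["muscle"] == "supraspinatus")
                        & (db.cells_["metric"] == "normalized_size")].iloc[0]
        z = db.z_score(sel["mean"] + sel["sd"], "male", 22.0, "supraspinatus", "normalized_size")
        assert z == pytest.approx(1.0, abs=1e-12)

    def test_age_outside_bins_rejected(self):
        db = rm.build_reference_database(self.tidy_cohort(seed=4))
        with pytest.raises(ValueError, match="outside"):
            db.z_score(1.0, "male", 95.0, "supraspinatus", "normalized_size")

    def test_z_invariant_to_common_affine_rescaling(self):
        df = self.tidy_cohort(seed=5)
        sel = df[df.metric == "normalized_size"].copy()
        db = rm.build_reference_database(sel)
        z1 = db.z_score(1.1, "male", 25.0, "supraspinatus", "normalized_size")
        sel2 = sel.copy()
        sel2["value"] = 7.0 * sel2["value"] + 3.0
        db2 = rm.build_reference_database(sel2)
        z2 = db2.z_score(7.0 * 1.1 + 3.0, "male", 25.0, "supraspinatus", "normalized_size")
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_transform_appends_z_column(self):
        df = self.tidy_cohort(seed=6)
        db = rm.build_reference_database(df)
        out = db.transform(df.head(10))
        assert "z" in out.columns
        assert out["z"].notna().all()

    def test_leave_one_out_z_scores_calibrated(self):
        """LOO z-scores on a Gaussian cohort: mean ≈ 0, SD ≈ 1."""
        spec = rm.CohortSpec(n_per_cell=42, age_slope_size={}, sex_offset_size={},
                             fat_age_slope={}, fat_sex_offset={}, seed=8)
        df = rm.sample_cohort_metrics(spec, metric_cv=0.12)
        sel = df[(df.metric == "normalized_size") & (df.muscle == "supraspinatus")]
        zs = []
        for scan_id in sel["scan_id"]:
            rest = sel[sel["scan_id"] != scan_id]
            row = sel[sel["scan_id"] == scan_id].iloc[0]
            db = rm.build_reference_database(rest)
            zs.append(db.z_score(row["value"], row["sex"], row["age_years"],
                                 row["muscle"], row["metric"]))
        assert abs(np.mean(zs)) < 0.1
        assert np.std(zs) == pytest.approx(1.0, abs=0.15)
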