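"""Core ratios, exclusion/averaging rules, stratification and statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from stromaquant import cohort as cs
from stromaquant.simulate import CohortSimParams, generate_survival_cohort


def core_row(**kw):
    base = dict(
        core_id="c1", sample_id="s1", patient_id="p1", group="primary",
        fibroblasts=50, cancer_cells=600, immunocytes=20, others=10,
        asma_pos=40, inhba_pos=10, cd3cd4=30, cd3cd4foxp3=6,
    )
    base.update(kw)
    return base


class TestCoreRatios:
    def test_fibroblast_ratio_from_printed_formula(self):
        df = pd.DataFrame([core_row(fibroblasts=50, cancer_cells=30,
                                    immunocytes=20)])
        out = cs.compute_core_ratios(df)
        assert out.loc[0, "fibroblast_ratio"] == pytest.approx(0.5)

    def test_zero_fibroblasts_make_stromal_ratios_missing(self):
        df = pd.DataFrame([core_row(fibroblasts=0, asma_pos=0, inhba_pos=0)])
        out = cs.compute_core_ratios(df)
        assert np.isnan(out.loc[0, "asma_ratio"])
        assert np.isnan(out.loc[0, "inhba_ratio"])
        assert not np.isnan(out.loc[0, "fibroblast_ratio"])

    def test_random_tables_match_spreadsheet_recomputation(self, rng):
        rows = [
            core_row(
                core_id=f"c{i}",
                fibroblasts=int(rng.integers(1, 500)),
                cancer_cells=int(rng.integers(0, 3000)),
                immunocytes=int(rng.integers(0, 500)),
                asma_pos=int(rng.integers(0, 200)),
                inhba_pos=int(rng.integers(0, 200)),
                cd3cd4=int(rng.integers(1, 100)),
                cd3cd4foxp3=int(rng.integers(0, 50)),
            )
            for i in range(200)
        ]
        out = cs.compute_core_ratios(pd.DataFrame(rows))
        for _, r in out.iterrows():
            f, c, i = r.fibroblasts, r.cancer_cells, r.immunocytes
            assert r.fibroblast_ratio == pytest.approx(f / (f + c + i))
            assert r.asma_ratio == pytest.approx(r.asma_pos / f)
            assert r.inhba_ratio == pytest.approx(r.inhba_pos / f)
            assert r.treg_ratio == pytest.approx(r.cd3cd4foxp3 / r.cd3cd4)

    def test_defined_ratios_stay_in_unit_interval(self, rng):
        p = CohortSimParams(seed=int(rng.integers(1000)))
        from stromaquant.simulate import generate_cell_count_tables

        out = cs.compute_core_ratios(generate_cell_count_tables(p))
        for col in cs.RATIO_COLUMNS:
            vals = out[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([core_row(fibroblasts=-1)])
        with pytest.raises(ValueError, match="non-negative"):
            cs.compute_core_ratios(df)


class TestCoreExclusion:
    def test_boundary_at_exactly_500_cancer_cells(self):
        df = pd.DataFrame(
            [core_row(core_id="a", cancer_cells=499),
             core_row(core_id="b", cancer_cells=500)]
        )
        kept = cs.apply_core_exclusion(df)
        assert kept["core_id"].tolist() == ["b"]

    def test_empty_input_stays_empty(self):
        df = pd.DataFrame(columns=list(core_row()))
        assert cs.apply_core_exclusion(df).empty

    def test_mixed_table_matches_bruteforce_filter(self, rng):
        df = pd.DataFrame(
            [core_row(core_id=f"c{i}",
                      cancer_cells=int(rng.integers(0, 1500)))
             for i in range(100)]
        )
        kept = cs.apply_core_exclusion(df)
        brute = [r["core_id"] for _, r in df.iterrows()
                 if r["cancer_cells"] >= 500]
        assert kept["core_id"].tolist() == brute


class TestAveraging:
    def test_single_core_sample_keeps_its_ratio(self):
        df = cs.compute_core_ratios(pd.DataFrame([core_row()]))
        out = cs.average_per_sample(df)
        assert out.loc[0, "inhba_ratio"] == pytest.approx(10 / 50)
        assert out.loc[0, "n_cores"] == 1

    def test_two_core_mean(self):
        df = cs.compute_core_ratios(pd.DataFrame([
            core_row(core_id="a", inhba_pos=10, fibroblasts=50),   # 0.2
            core_row(core_id="b", inhba_pos=20, fibroblasts=50),   # 0.4
        ]))
        out = cs.average_per_sample(df)
        assert out.loc[0, "inhba_ratio"] == pytest.approx(0.3)

    def test_matches_groupby_mean_oracle(self, rng):
        rows = []
        for s in range(30):
            for k in range(int(rng.integers(1, 4))):
                rows.append(core_row(
                    core_id=f"s{s}-c{k}", sample_id=f"s{s:02d}",
                    inhba_pos=int(rng.integers(0, 50)),
                ))
        df = cs.compute_core_ratios(pd.DataFrame(rows))
        out = cs.average_per_sample(df).set_index("sample_id")
        for sid, grp in df.groupby("sample_id"):
            assert out.loc[sid, "inhba_ratio"] == pytest.approx(
                grp["inhba_ratio"].mean()
            )

    def test_samples_losing_all_cores_flagged_missing(self):
        df = cs.compute_core_ratios(pd.DataFrame([
            core_row(sample_id="kept", cancer_cells=700),
            core_row(sample_id="lost", cancer_cells=100),
        ]))
        kept = cs.apply_core_exclusion(df)
        out = cs.average_per_sample(
            kept, all_samples=["kept", "lost"]
        ).set_index("sample_id")
        assert out.loc["lost", "n_cores"] == 0
        assert np.isnan(out.loc["lost", "inhba_ratio"])


class TestSplitLowHigh:
    def test_mean_split_of_four_values(self):
        df = pd.DataFrame({"inhba_ratio": [0.1, 0.2, 0.3, 0.4]})
        stratum, thr = cs.split_low_high(df, "inhba_ratio")
        assert thr == pytest.approx(0.25)
        assert stratum.tolist() == ["low", "low", "high", "high"]

    def test_matches_bruteforce_split_on_simulated_cohort(self):
        surv = generate_survival_cohort(CohortSimParams(seed=17), n_samples=41)
        stratum, thr = cs.split_low_high(surv, "inhba_ratio")
        brute = ["high" if v > surv["inhba_ratio"].mean() else "low"
                 for v in surv["inhba_ratio"]]
        assert stratum.tolist() == brute
        assert (stratum == "low").sum() + (stratum == "high").sum() == 41

    def test_single_distinct_high_value(self):
        df = pd.DataFrame({"r": [0.2, 0.2, 0.2, 0.5]})
        stratum, _ = cs.split_low_high(df, "r")
        assert stratum.tolist() == ["low", "low", "low", "high"]

    def test_all_identical_values_warn_and_go_low(self):
        df = pd.DataFrame({"r": [0.3, 0.3, 0.3]})
        with pytest.warns(UserWarning, match="stratum empty"):
            stratum, _ = cs.split_low_high(df, "r")
        assert (stratum == "low").all()

    def test_ties_at_the_mean_go_low(self):
        df = pd.DataFrame({"r": [0.2, 0.4, 0.3]})  # mean exactly 0.3
        stratum, _ = cs.split_low_high(df, "r")
        assert stratum.tolist() == ["low", "high", "low"]


class TestSurvivalCompare:
    def test_identical_strata_give_zero_statistic(self):
        half = pd.DataFrame({
            "os_months": [5.0, 10.0, 15.0, 20.0],
            "os_event": [True, True, False, True],
        })
        df = pd.concat(
            [half.assign(stratum="low"), half.assign(stratum="high")],
            ignore_index=True,
        )
        comp = cs.survival_compare(df)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_planted_hazard_ratio_detected(self):
        p = CohortSimParams(seed=29, hazard_ratio_high_vs_low=3.0)
        surv = generate_survival_cohort(p, n_samples=200)
        comp = cs.survival_compare(surv)
        assert comp.p_value < 1e-4
        assert comp.medians["high"] < comp.medians["low"]

    def test_stratum_without_events_is_an_error(self):
        df = pd.DataFrame({
            "os_months": [5.0, 8.0, 7.0, 9.0],
            "os_event": [True, True, False, False],
            "stratum": ["low", "low", "high", "high"],
        })
        with pytest.raises(ValueError, match="no events"):
            cs.survival_compare(df)

    def test_survival_table_has_both_strata(self):
        surv = generate_survival_cohort(CohortSimParams(seed=1), n_samples=40)
        comp = cs.survival_compare(surv)
        tbl = comp.survival_table()
        assert set(tbl["stratum"]) == {"low", "high"}
        assert ((tbl["survival"] >= 0) & (tbl["survival"] <= 1)).all()


class TestGroupTests:
    def _matched_samples(self, delta, n=20, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(0.2, 0.04, n).clip(0.01)
        rows = []
        for i in range(n):
            for g, v in [("primary", base[i]),
                         ("metastatic", base[i] + delta),
                         ("recurrent", base[i] + delta)]:
                rows.append({"sample_id": f"{g}-{i}", "patient_id": f"p{i}",
                             "group": g, "inhba_ratio": v})
        return pd.DataFrame(rows)

    def test_paired_t_on_identical_vectors_is_null(self):
        df = self._matched_samples(delta=0.0)
        t, p = cs.paired_t_by_patient(df, "inhba_ratio", "primary",
                                      "metastatic")
        assert (t, p) == (0.0, 1.0)

    def test_paired_shift_detected_at_study_sample_size(self):
        # planted paired shift of 0.1 at n=40 pairs: power is essentially 1
        detected = 0
        for seed in range(20):
            df = self._matched_samples(delta=0.1, n=40, seed=seed)
            _, p = cs.paired_t_by_patient(df, "inhba_ratio", "primary",
                                          "metastatic")
            detected += p < 0.05
        assert detected == 20

    def test_unmatched_patients_named_in_error(self):
        df = self._matched_samples(delta=0.1, n=4)
        df = df[~((df.patient_id == "p2") & (df.group == "metastatic"))]
        with pytest.raises(ValueError, match="p2"):
            cs.paired_t_by_patient(df, "inhba_ratio", "primary", "metastatic")

    def test_pearson_self_correlation_is_one(self):
        x = np.linspace(0, 1, 30)
        r, _ = cs.pearson_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_anova_needs_two_groups(self):
        df = pd.DataFrame({"group": ["primary"] * 3,
                           "inhba_ratio": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="2 groups"):
            cs.anova_across_groups(df, "inhba_ratio")

    def test_mann_whitney_separates_shifted_strata(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "stratum": ["low"] * 21 + ["high"] * 20,
            "treg_ratio": np.concatenate(
                [rng.normal(0.1, 0.03, 21), rng.normal(0.3, 0.03, 20)]
            ),
        })
        _, p = cs.mann_whitney_low_high(df, "treg_ratio")
        assert p < 1e-6

    def test_group_compare_wires_all_tests(self):
        df = self._matched_samples(delta=0.1, n=15, seed=2)
        res = cs.group_compare(df)
        assert set(res) == {"anova", "paired_t_primary_vs_metastatic",
                            "paired_t_primary_vs_recurrent"}
        assert res["paired_t_primary_vs_metastatic"][1] < 0.05
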