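"""Peptide-array kinetics, QC, fold changes, KRSA z-scores, quartiles."""

import math

import numpy as np
import pandas as pd
import pytest

from otoscreen import synthetic
from otoscreen.kinome import (
    average_activities,
    average_zscores,
    family_aggregate,
    fit_peptide_slopes,
    krsa_zscores,
    peptide_fold_changes,
    qc_filter,
    quartile_harmonize,
)
from otoscreen.types import KinomeChipRun


def _run(data, exposures=(5.0, 25.0, 100.0), condition="case"):
    df = pd.DataFrame(data, columns=list(exposures))
    df.index = [f"P{i}" for i in range(len(df))]
    return KinomeChipRun(well_id="w1", condition=condition, intensities=df)


class TestFitPeptideSlopes:
    def test_exact_on_noiseless_linear_data(self):
        run = _run([[2.0 * e for e in (5, 25, 100)],
                    [0.5 * e + 3 for e in (5, 25, 100)]])
        acts = fit_peptide_slopes(run)
        np.testing.assert_allclose(acts["slope"], [2.0, 0.5], rtol=1e-14)
        np.testing.assert_allclose(acts["r2"], [1.0, 1.0], rtol=1e-12)

    def test_constant_intensity_has_zero_slope_and_r2(self):
        acts = fit_peptide_slopes(_run([[7.0, 7.0, 7.0]]))
        assert acts["slope"].iloc[0] == 0.0
        assert acts["r2"].iloc[0] == 0.0

    def test_slope_matches_closed_form_sums(self, rng):
        x = np.array([5.0, 10.0, 25.0, 50.0, 100.0])
        y = rng.normal(50, 10, size=5)
        run = _run([y], exposures=x)
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x ** 2).sum()
                                                           - x.sum() ** 2)
        assert fit_peptide_slopes(run)["slope"].iloc[0] == pytest.approx(
            slope, rel=1e-12)

    def test_rejects_too_few_exposures(self):
        with pytest.raises(ValueError, match=">=3 exposure"):
            _run([[1.0, 2.0]], exposures=(5.0, 25.0))


class TestQcFilter:
    def test_boundary_rules(self):
        acts = pd.DataFrame({
            "peptide_id": ["at_floor", "dim_ok", "nonlinear", "good"],
            "slope": [1.0] * 4,
            "r2": [0.99, 0.95, 0.89, 0.99],
            "max_signal": [5.0, 5.1, 100.0, 100.0],
        })
        kept = qc_filter(acts, min_signal=5.0, min_r2=0.90)
        # raw signal <= 5 removed; R^2 < 0.90 removed; 0.90 itself kept
        assert set(kept["peptide_id"]) == {"dim_ok", "good"}

    def test_retained_equals_enumeration(self, rng):
        acts = pd.DataFrame({
            "peptide_id": [f"P{i}" for i in range(50)],
            "slope": rng.normal(size=50),
            "r2": rng.uniform(0.8, 1.0, size=50),
            "max_signal": rng.uniform(0, 20, size=50),
        })
        kept = set(qc_filter(acts)["peptide_id"])
        for row in acts.itertuples(index=False):
            assert (row.peptide_id in kept) == (
                row.max_signal > 5.0 and row.r2 >= 0.90)


class TestPeptideFoldChanges:
    def _acts(self, slopes):
        return pd.DataFrame({"peptide_id": [f"P{i}" for i in range(len(slopes))],
                             "slope": slopes, "r2": 1.0,
                             "max_signal": 100.0})

    def test_exact_fc_threshold_not_called(self):
        fcs = peptide_fold_changes(self._acts([1.15, 1.0, 0.85]),
                                   self._acts([1.0, 1.0, 1.0]))
        assert list(fcs["differential"]) == [False, False, False]
        assert fcs["log2fc"].iloc[1] == 0.0

    def test_planted_multiplier_recovered_noiselessly(self):
        pep_map = {"K1": {f"P{i}" for i in range(5)}}
        case = synthetic.gen_kinome_run(pep_map, activity={"K1": 1.5},
                                        noise_sd=0.0, n_wells=1, seed=0)[0]
        ctrl = synthetic.gen_kinome_run(pep_map, activity={}, noise_sd=0.0,
                                        n_wells=1, seed=0,
                                        condition="control")[0]
        fcs = peptide_fold_changes(fit_peptide_slopes(case),
                                   fit_peptide_slopes(ctrl))
        np.testing.assert_allclose(fcs["fc"], 1.5, rtol=1e-12)
        assert fcs["differential"].all()

    def test_nonpositive_control_slope_skipped(self):
        fcs = peptide_fold_changes(self._acts([2.0, 2.0]),
                                   self._acts([0.0, 1.0]))
        assert list(fcs["peptide_id"]) == ["P1"]

    def test_invariant_to_common_intensity_rescaling(self):
        pep_map = {"K1": {f"P{i}" for i in range(6)}}
        case = synthetic.gen_kinome_run(pep_map, activity={"K1": 1.3},
                                        noise_sd=0.0, n_wells=1, seed=1)[0]
        ctrl = synthetic.gen_kinome_run(pep_map, noise_sd=0.0, n_wells=1,
                                        seed=1, condition="control")[0]
        scaled = lambda run, f: KinomeChipRun(run.well_id, run.condition,
                                              run.intensities * f)
        f1 = peptide_fold_changes(fit_peptide_slopes(case),
                                  fit_peptide_slopes(ctrl))
        f2 = peptide_fold_changes(fit_peptide_slopes(scaled(case, 7.5)),
                                  fit_peptide_slopes(scaled(ctrl, 7.5)))
        np.testing.assert_allclose(f1["fc"], f2["fc"], rtol=1e-12)


class TestKrsaZscores:
    def test_whole_chip_kinase_degenerate_z_zero(self):
        chip = {f"P{i}" for i in range(6)}
        scores = krsa_zscores({"P0", "P1"}, chip, {"ALL": chip}, n_iter=500,
                              seed=3)
        assert scores.loc[scores["kinase_id"] == "ALL", "z"].iloc[0] == 0.0

    def test_against_exact_hypergeometric_null(self):
        """Sampled null mean/sd match the closed-form hypergeometric moments
        within 3 Monte-Carlo standard errors (10-peptide chip, 3 differential,
        4 mapped)."""
        chip = [f"P{i}" for i in range(10)]
        diff = set(chip[:3])
        mapped = set(chip[2:6])
        n_iter = 100_000
        scores = krsa_zscores(diff, chip, {"K": mapped}, n_iter=n_iter, seed=5)
        N, K, d = 10, 4, 3
        mu = d * K / N
        sd = math.sqrt(d * (K / N) * (1 - K / N) * (N - d) / (N - 1))
        row = scores.iloc[0]
        assert abs(row["null_mean"] - mu) < 3 * sd / math.sqrt(n_iter)
        assert abs(row["null_sd"] - sd) < 3 * sd / math.sqrt(2 * n_iter)
        assert row["observed"] == len(diff & mapped)

    def test_no_differential_peptides_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            krsa_zscores(set(), {"P0", "P1", "P2"}, {"K": {"P0"}}, seed=0)

    def test_unmapped_kinase_skipped(self):
        scores = krsa_zscores({"P0"}, {"P0", "P1"}, {"K_off": {"X1"}},
                              n_iter=200, seed=0)
        assert len(scores) == 0

    def test_deterministic_under_seed(self):
        chip = {f"P{i}" for i in range(20)}
        kmap = {"K1": {f"P{i}" for i in range(8)}}
        s1 = krsa_zscores({"P0", "P1", "P5"}, chip, kmap, n_iter=1000, seed=9)
        s2 = krsa_zscores({"P0", "P1", "P5"}, chip, kmap, n_iter=1000, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_planted_kinase_attains_top_mean_z(self):
        pep_map = {f"K{i}": {f"P{10 * i + j}" for j in range(10)}
                   for i in range(5)}
        frames = []
        for chip_seed in range(3):
            case = synthetic.gen_kinome_run(pep_map, activity={"K0": 1.3},
                                            noise_sd=0.5, n_wells=1,
                                            seed=100 + chip_seed)[0]
            ctrl = synthetic.gen_kinome_run(pep_map, noise_sd=0.5, n_wells=1,
                                            seed=200 + chip_seed,
                                            condition="control")[0]
            fcs = peptide_fold_changes(
                qc_filter(fit_peptide_slopes(case)),
                qc_filter(fit_peptide_slopes(ctrl)))
            diff = set(fcs.loc[fcs["differential"], "peptide_id"])
            frames.append(krsa_zscores(diff, set(fcs["peptide_id"]), pep_map,
                                       n_iter=2000, seed=chip_seed))
        final = average_zscores(frames)
        assert final["kinase_id"].iloc[0] == "K0"
        assert final["z_mean"].iloc[0] > 2.0

    def test_null_mean_z_near_zero(self):
        """With no planted kinase the mean z over kinases is ~0."""
        pep_map = {f"K{i}": {f"P{10 * i + j}" for j in range(10)}
                   for i in range(5)}
        case = synthetic.gen_kinome_run(pep_map, noise_sd=8.0, n_wells=1,
                                        seed=31)[0]
        ctrl = synthetic.gen_kinome_run(pep_map, noise_sd=8.0, n_wells=1,
                                        seed=32, condition="control")[0]
        fcs = peptide_fold_changes(qc_filter(fit_peptide_slopes(case)),
                                   qc_filter(fit_peptide_slopes(ctrl)))
        diff = set(fcs.loc[fcs["differential"], "peptide_id"])
        scores = krsa_zscores(diff, set(fcs["peptide_id"]), pep_map,
                              n_iter=2000, seed=33)
        assert abs(scores["z"].mean()) < 0.35


class TestAggregation:
    def test_average_activities_requires_common_peptides(self):
        a = pd.DataFrame({"peptide_id": ["P0", "P1"], "slope": [1.0, 2.0],
                          "r2": [1.0, 1.0], "max_signal": [10.0, 10.0]})
        b = pd.DataFrame({"peptide_id": ["P1", "P2"], "slope": [4.0, 8.0],
                          "r2": [0.9, 1.0], "max_signal": [20.0, 10.0]})
        avg = average_activities([a, b])
        assert list(avg["peptide_id"]) == ["P1"]
        assert avg["slope"].iloc[0] == pytest.approx(3.0)
        assert avg["max_signal"].iloc[0] == pytest.approx(20.0)

    def test_family_aggregate_single_and_multi(self):
        log2fcs = pd.DataFrame({"noise_vs_control": [0.5, 1.5, -1.0],
                                "drug_vs_control": [0.1, 0.3, 0.5]},
                               index=["P0", "P1", "P2"])
        table = family_aggregate(log2fcs, {"AKT": ["P0", "P1"], "ERK": ["P2"]})
        akt = table[(table["family"] == "AKT")
                    & (table["comparison"] == "noise_vs_control")].iloc[0]
        assert akt["mean_log2fc"] == pytest.approx(1.0)
        assert akt["sd_log2fc"] == pytest.approx(np.std([0.5, 1.5], ddof=1))
        erk = table[(table["family"] == "ERK")
                    & (table["comparison"] == "drug_vs_control")].iloc[0]
        assert erk["mean_log2fc"] == pytest.approx(0.5)
        assert erk["sd_log2fc"] == 0.0


class TestQuartileHarmonize:
    def test_four_kinases_span_quartiles(self):
        table = quartile_harmonize({"m1": ["a", "b", "c", "d"],
                                    "m2": ["d", "c", "b", "a"]})
        assert list(table["m1"].loc[["a", "b", "c", "d"]]) == [1, 2, 3, 4]
        assert list(table["m2"].loc[["a", "b", "c", "d"]]) == [4, 3, 2, 1]

    def test_ceiling_rule_eight_kinases(self):
        ranking = [f"k{i}" for i in range(8)]
        table = quartile_harmonize({"m1": ranking, "m2": ranking})
        assert list(table["m1"].loc[ranking]) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_absent_kinase_left_blank_and_hand_enumeration(self):
        table = quartile_harmonize({"m1": ["a", "b", "c"], "m2": ["b", "d"]})
        assert math.isnan(table.loc["a", "m2"])
        # ceil(4r/n): n=2 -> quartiles 2 and 4; n=3 -> 2, 3, 4
        assert table.loc["b", "m2"] == 2 and table.loc["d", "m2"] == 4
        assert table.loc["a", "m1"] == 2 and table.loc["c", "m1"] == 4

    def test_requires_two_methods(self):
        with pytest.raises(ValueError, match=">=2 methods"):
            quartile_harmonize({"m1": ["a"]})
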