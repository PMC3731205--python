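"""Specificity profiles, ratio-of-ratios, derived-vs-direct, dependency calls."""

import math

import numpy as np
import pandas as pd
import pytest

import sumoquant as sq
from conftest import protein_frame

CORE = sq.CORE_GENOTYPES


def _mutant_table(genotype, rows):
    df = protein_frame(rows)
    df["experiment_id"] = f"{genotype}_vs_WT"
    df["numerator_strain"] = genotype
    return df


def _targets(ids):
    return pd.DataFrame({"protein_id": list(ids), "called": True})


class TestBuildProfiles:
    def test_missing_genotype_is_na(self):
        profiles = sq.build_profiles(
            _targets(["P1"]),
            {"siz1Δ": _mutant_table("siz1Δ", [("P1", 0.25, 5)])},
        )
        assert profiles.loc["P1", "siz1Δ"] == pytest.approx(-2.0)
        assert math.isnan(profiles.loc["P1", "mms21-11"])

    def test_only_called_targets_are_profiled(self):
        targets = pd.DataFrame({"protein_id": ["P1", "P2"], "called": [True, False]})
        profiles = sq.build_profiles(
            targets, {"siz1Δ": _mutant_table("siz1Δ", [("P1", 2.0, 5), ("P2", 2.0, 5)])}
        )
        assert list(profiles.index) == ["P1"]

    def test_unknown_genotype_label_rejected(self):
        with pytest.raises(sq.DesignError):
            sq.build_profiles(_targets(["P1"]), {"ulp1Δ": _mutant_table("siz1Δ", [("P1", 1.0, 5)])})

    def test_floor_imputed_loss_is_large_negative_but_finite(self, quantify):
        """A fully Siz1-dependent target in siz1Δ: floor-imputed ratio, big loss."""
        import dataclasses

        cfg = sq.GeneratorConfig(
            seed=2, n_proteins=1, peptide_noise_sigma=0.0, missing_channel_prob=0.0
        )
        gt = dataclasses.replace(
            sq.generate_ground_truth(cfg)[0],
            is_sumo_target=True,
            is_contaminant=False,
            dep_weights={"siz1_only": 1.0, "siz2_only": 0.0, "siz_redundant": 0.0, "mms21": 0.0},
        )
        design = sq.mutant_design("siz1Δ")
        pep = sq.simulate_silac_experiment([gt], design, cfg)
        table = quantify(pep, [design])
        # oracle: oriented ratio = floor / WT-channel intensity, per peptide
        expected = sq.ratio_median(
            sorted(1e3 / pep["light_intensity"])
        )
        got = float(table["median_ratio"].iloc[0])
        assert got == pytest.approx(expected, rel=1e-12)
        assert math.isfinite(math.log2(got)) and math.log2(got) < -2.0
        assert table["imputed_fraction"].iloc[0] == 1.0


class TestRatioOfRatios:
    def test_derived_is_difference_of_log2_changes(self):
        profiles = pd.DataFrame(
            {"mms21-11": [-3.0], "siz1Δ siz2Δ": [-1.0]},
            index=pd.Index(["P1"], name="protein_id"),
        ).reindex(columns=list(sq.PROFILE_GENOTYPES))
        profiles.loc["P1", "mms21-11"] = -3.0
        profiles.loc["P1", "siz1Δ siz2Δ"] = -1.0
        out = sq.ratio_of_ratios(profiles, "mms21-11", "siz1Δ siz2Δ")
        assert out.loc["P1", "derived_log2"] == pytest.approx(-2.0)

    def test_na_operand_propagates(self):
        profiles = pd.DataFrame(
            {g: [np.nan] for g in sq.PROFILE_GENOTYPES},
            index=pd.Index(["P1"], name="protein_id"),
        )
        profiles.loc["P1", "mms21-11"] = -3.0
        out = sq.ratio_of_ratios(profiles, "mms21-11", "siz1Δ siz2Δ")
        assert math.isnan(out.loc["P1", "derived_log2"])

    def test_undeclared_genotype_rejected(self):
        profiles = pd.DataFrame({g: [0.0] for g in sq.PROFILE_GENOTYPES}, index=["P1"])
        with pytest.raises(sq.DesignError):
            sq.ratio_of_ratios(profiles, "mms21-11", "ulp2Δ")


def _simulate_specificity(seed, n, sigma, quantify, genotypes=("mms21-11", "siz1Δ siz2Δ")):
    cfg = sq.GeneratorConfig(
        seed=seed,
        n_proteins=n,
        target_fraction=1.0,
        contaminant_fraction=0.0,
        peptide_noise_sigma=sigma,
        missing_channel_prob=0.0 if sigma == 0.0 else 0.05,
    )
    truth = sq.generate_ground_truth(cfg)
    rep1, rep2 = sq.enrichment_replicates()
    t1 = quantify(sq.simulate_silac_experiment(truth, rep1, cfg), [rep1])
    t2 = quantify(sq.simulate_silac_experiment(truth, rep2, cfg), [rep2])
    params = sq.AnalysisParams()
    targets = sq.call_targets(t1, t2, params)
    mutant_tables = {}
    for g in genotypes:
        d = sq.mutant_design(g)
        mutant_tables[g] = quantify(sq.simulate_silac_experiment(truth, d, cfg), [d])
    direct = sq.direct_design("mms21-11", "siz1Δ siz2Δ")
    direct_table = quantify(sq.simulate_silac_experiment(truth, direct, cfg), [direct])
    profiles = sq.build_profiles(targets, mutant_tables)
    derived = sq.ratio_of_ratios(profiles, "mms21-11", "siz1Δ siz2Δ")
    return derived, direct_table


class TestDerivedVsDirect:
    def test_identity_on_noiseless_data(self, quantify):
        derived, direct = _simulate_specificity(3, 60, 0.0, quantify)
        report = sq.validate_derived_vs_direct(derived, direct)
        assert report.table["abs_diff"].max() <= 1e-9  # exact up to IEEE rounding
        assert report.concordant_fraction == 1.0

    def test_concordance_under_noise(self, quantify):
        derived, direct = _simulate_specificity(5, 150, 0.2, quantify)
        report = sq.validate_derived_vs_direct(derived, direct, tolerance_log2=1.0)
        assert report.concordant_fraction >= 0.9

    def test_single_discordant_protein(self):
        derived = pd.DataFrame(
            {"derived_log2": [-2.0]}, index=pd.Index(["P1"], name="protein_id")
        )
        direct = _mutant_table("siz1Δ", [("P1", 2.0 ** -3.5, 5)])
        report = sq.validate_derived_vs_direct(derived, direct, tolerance_log2=1.0)
        assert report.concordant_fraction == 0.0
        assert report.table["abs_diff"].iloc[0] == pytest.approx(1.5)

    def test_empty_intersection_rejected(self):
        derived = pd.DataFrame(
            {"derived_log2": [-2.0]}, index=pd.Index(["P1"], name="protein_id")
        )
        direct = _mutant_table("siz1Δ", [("P9", 1.0, 5)])
        with pytest.raises(sq.ParameterError):
            sq.validate_derived_vs_direct(derived, direct)


class TestClassifier:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ({"siz1Δ": -4, "siz2Δ": 0, "siz1Δ siz2Δ": -4, "mms21-11": 0}, "siz1_specific"),
            (
                {"siz1Δ": -0.2, "siz2Δ": 0.4, "siz1Δ siz2Δ": -3, "mms21-11": -0.4},
                "siz1_siz2_redundant",
            ),
            ({"siz1Δ": 0, "siz2Δ": 0.5, "siz1Δ siz2Δ": -0.3, "mms21-11": -3}, "mms21_preferred"),
            ({"siz1Δ": 0.1, "siz2Δ": 1.4, "siz1Δ siz2Δ": 0.2, "mms21-11": 0.3}, "up_in_mutant"),
            ({"siz1Δ": 0.1, "siz2Δ": -0.2, "siz1Δ siz2Δ": 0.2, "mms21-11": 0.3}, "unaffected"),
            ({"siz1Δ": -1.5, "siz2Δ": 0, "siz1Δ siz2Δ": -1.2, "mms21-11": 0}, "mixed"),
            ({"siz1Δ": float("nan"), "siz2Δ": float("nan"), "siz1Δ siz2Δ": -3, "mms21-11": 0},
             "insufficient_data"),
        ],
    )
    def test_decision_rule(self, values, expected):
        assert sq.classify_dependency(values) == expected

    def test_call_is_total_and_order_independent(self):
        values = {"siz1Δ": -4.0, "siz2Δ": 0.0, "siz1Δ siz2Δ": -4.0, "mms21-11": 0.0}
        reordered = dict(reversed(list(values.items())))
        assert sq.classify_dependency(values) == sq.classify_dependency(reordered)
        for cat in (sq.classify_dependency(values),):
            assert cat in sq.profiles.DEPENDENCY_CATEGORIES

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(sq.ParameterError):
            sq.ClassifierThresholds(strong_loss=-0.1)

    def test_recovers_generating_classes(self, quantify):
        """Pure-dependency targets classify back to their generating class."""
        import dataclasses

        cfg = sq.GeneratorConfig(
            seed=41, n_proteins=300, target_fraction=1.0, contaminant_fraction=0.0,
            peptide_noise_sigma=0.2,
        )
        classes = ("siz1_only", "siz_redundant", "mms21")
        expected = {
            "siz1_only": "siz1_specific",
            "siz_redundant": "siz1_siz2_redundant",
            "mms21": "mms21_preferred",
        }
        truth, assigned = [], {}
        for i, g in enumerate(sq.generate_ground_truth(cfg)):
            cls = classes[i % 3]
            assigned[g.protein_id] = cls
            weights = {k: (1.0 if k == cls else 0.0) for k in sq.simulate.DEP_KEYS}
            truth.append(dataclasses.replace(g, dep_weights=weights))
        rep1, rep2 = sq.enrichment_replicates()
        params = sq.AnalysisParams()
        t1 = quantify(sq.simulate_silac_experiment(truth, rep1, cfg), [rep1])
        t2 = quantify(sq.simulate_silac_experiment(truth, rep2, cfg), [rep2])
        targets = sq.call_targets(t1, t2, params)
        mutant_tables = {}
        for g in CORE:
            d = sq.mutant_design(g)
            mutant_tables[g] = quantify(sq.simulate_silac_experiment(truth, d, cfg), [d])
        profiles = sq.build_profiles(targets, mutant_tables)
        calls = sq.classify_profiles(profiles)
        hit = np.mean([calls[p] == expected[assigned[p]] for p in calls.index])
        assert hit >= 0.95
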