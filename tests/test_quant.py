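"""Peptide-ratio computation, protein rollup, orientation, log2 transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sumoquant as sq
from conftest import with_peptide_count

RATIOS = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False)


def _measurement(light, heavy):
    return sq.PeptideMeasurement("P1", "PEPTIDEK", "exp", light, heavy)


def _ratio_list(values, protein="P1", experiment="exp"):
    return [
        sq.PeptideRatio(protein, f"PEP{i}K", experiment, v, False, "none")
        for i, v in enumerate(values)
    ]


class TestPeptideRatio:
    @pytest.mark.parametrize(
        "light,heavy,ratio,imputed,channel",
        [
            (2000.0, 2000.0, 1.0, False, "none"),
            (0.0, 5e5, 500.0, True, "light"),
            (5e5, 0.0, 1 / 500.0, True, "heavy"),
        ],
    )
    def test_ratio_and_noise_floor_imputation(self, params, light, heavy, ratio, imputed, channel):
        r = sq.compute_peptide_ratio(_measurement(light, heavy), params)
        assert r.raw_ratio == pytest.approx(ratio)
        assert r.imputed is imputed
        assert r.imputed_channel == channel

    def test_both_channels_empty_is_unquantifiable(self, params):
        with pytest.raises(sq.UnquantifiablePeptideError):
            sq.compute_peptide_ratio(_measurement(0.0, 0.0), params)

    def test_table_drops_dead_peptides_with_warning(self, params, caplog):
        df = pd.DataFrame(
            [
                ("P1", "AK", "exp", 10.0, 20.0),
                ("P1", "CK", "exp", 0.0, 0.0),
            ],
            columns=list(sq.simulate.PEPTIDE_COLUMNS),
        )
        with caplog.at_level("WARNING"):
            out = sq.peptide_ratio_table(df, params)
        assert len(out) == 1
        assert "no signal" in caplog.text


class TestProteinRollup:
    def test_median_and_mean_over_three_peptides(self, params):
        p = sq.aggregate_protein(_ratio_list([2.0, 4.0, 8.0]), params)
        assert p.median_ratio == pytest.approx(4.0)
        assert p.mean_ratio == pytest.approx(14.0 / 3.0)
        assert p.n_peptides == 3
        assert not p.under_quantified

    def test_median_is_robust_to_an_outlier(self, params):
        p = sq.aggregate_protein(_ratio_list([1.0, 1.0, 1.0, 100.0]), params)
        assert p.median_ratio == pytest.approx(1.0)

    def test_two_peptides_is_under_quantified(self, params):
        p = sq.aggregate_protein(_ratio_list([2.0, 4.0]), params)
        assert p.under_quantified

    def test_even_count_median_is_geometric_midpoint(self):
        # ratios live on a log scale: median({2, 8}) = 4, not 5
        assert sq.ratio_median([2.0, 8.0]) == pytest.approx(4.0)

    def test_duplicate_sequences_collapse_before_counting(self, params):
        ratios = _ratio_list([2.0, 4.0, 8.0]) + [
            sq.PeptideRatio("P1", "PEP0K", "exp", 2.0, False, "none")
        ]
        p = sq.aggregate_protein(ratios, params)
        assert p.n_peptides == 3

    def test_empty_input_rejected(self, params):
        with pytest.raises(sq.ParameterError):
            sq.aggregate_protein([], params)

    @given(st.lists(RATIOS, min_size=1, max_size=12), st.randoms(use_true_random=False))
    def test_median_invariant_under_peptide_permutation(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert sq.ratio_median(shuffled) == sq.ratio_median(values)

    def test_imputed_fraction_within_unit_interval(self, params, quantify):
        cfg = sq.GeneratorConfig(seed=19, n_proteins=80, missing_channel_prob=0.3)
        truth = sq.generate_ground_truth(cfg)
        design = sq.enrichment_replicates()[0]
        table = quantify(sq.simulate_silac_experiment(truth, design, cfg), [design])
        assert table["imputed_fraction"].between(0.0, 1.0).all()


def _oriented_value(raw, swap):
    design = sq.enrichment_replicates()[1 if swap else 0]  # rep2 has reference light
    df = pd.DataFrame(
        {
            "protein_id": ["P1"],
            "experiment_id": [design.experiment_id],
            "n_peptides": [3],
            "median_ratio": [raw],
            "mean_ratio": [raw],
            "imputed_fraction": [0.0],
            "under_quantified": [False],
            "oriented": [False],
            "numerator_strain": [""],
        }
    )
    return float(sq.orient_to_reference(df, [design])["median_ratio"].iloc[0])


class TestOrientation:
    @pytest.mark.parametrize(
        "raw,reference_heavy,expected",
        [(0.1, True, 10.0), (10.0, False, 10.0), (1.0, True, 1.0), (1.0, False, 1.0)],
    )
    def test_reference_strain_goes_to_denominator(self, raw, reference_heavy, expected):
        # rep1 carries the mock (reference) heavy, rep2 carries it light
        assert _oriented_value(raw, swap=not reference_heavy) == pytest.approx(expected)

    @given(RATIOS)
    def test_reciprocal_consistency(self, raw):
        inverted = _oriented_value(raw, swap=False)  # reference heavy: reciprocal
        kept = _oriented_value(raw, swap=True)  # reference light: identity
        assert inverted == 1.0 / raw
        assert kept == raw
        assert inverted * raw == pytest.approx(1.0, rel=1e-12)

    def test_unknown_experiment_raises(self):
        df = pd.DataFrame({"experiment_id": ["nope"], "median_ratio": [1.0], "mean_ratio": [1.0]})
        with pytest.raises(sq.DesignError):
            sq.orient_to_reference(df, [sq.enrichment_replicates()[0]])


class TestLog2Transform:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (4.0, 2.0), (0.25, -2.0)])
    def test_log2_values(self, ratio, expected):
        assert float(np.log2(ratio)) == pytest.approx(expected)
        values = sq.log2_transform(
            pd.DataFrame(
                {
                    "protein_id": ["P1"],
                    "experiment_id": ["exp"],
                    "median_ratio": [ratio],
                    "under_quantified": [False],
                    "oriented": [True],
                }
            )
        )
        assert values["P1"] == pytest.approx(expected)

    def test_unoriented_table_rejected(self):
        df = pd.DataFrame(
            {
                "protein_id": ["P1"],
                "experiment_id": ["exp"],
                "median_ratio": [2.0],
                "under_quantified": [False],
                "oriented": [False],
            }
        )
        with pytest.raises(sq.DesignError):
            sq.log2_transform(df)

    def test_under_quantified_proteins_become_unavailable(self):
        df = pd.DataFrame(
            {
                "protein_id": ["P1", "P2"],
                "experiment_id": ["exp", "exp"],
                "median_ratio": [2.0, 3.0],
                "under_quantified": [False, True],
                "oriented": [True, True],
            }
        )
        values = sq.log2_transform(df)
        assert "P2" not in values.index


class TestParameterRecovery:
    def test_noiseless_estimates_equal_truth(self, quantify):
        cfg = sq.GeneratorConfig(
            seed=2, n_proteins=40, peptide_noise_sigma=0.0, missing_channel_prob=0.0
        )
        truth = sq.generate_ground_truth(cfg)
        design = sq.enrichment_replicates()[0]
        table = quantify(sq.simulate_silac_experiment(truth, design, cfg), [design])
        enr = {g.protein_id: g.enrichment for g in truth}
        for row in table.itertuples():
            assert row.median_ratio == pytest.approx(enr[row.protein_id], rel=1e-12)

    def test_recovery_under_realistic_noise(self, quantify):
        # median of 5 lognormal ratios at sigma=0.2 (nat) has log2 SD ~0.155,
        # so ±0.35 log2 covers ~2.3 SD (expected ~98% of proteins)
        cfg = sq.GeneratorConfig(
            seed=21, n_proteins=500, peptide_noise_sigma=0.2, missing_channel_prob=0.0
        )
        truth = with_peptide_count(sq.generate_ground_truth(cfg), 5)
        design = sq.enrichment_replicates()[0]
        table = quantify(sq.simulate_silac_experiment(truth, design, cfg), [design])
        enr = {g.protein_id: g.enrichment for g in truth}
        err = np.abs(
            np.log2(table["median_ratio"].to_numpy())
            - np.log2([enr[p] for p in table["protein_id"]])
        )
        assert (err <= 0.35).mean() >= 0.95
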