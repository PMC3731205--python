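import hypothesis
import pandas as pd
import pytest

import sumoquant as sq

hypothesis.settings.register_profile("suite", derandomize=True, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> sq.AnalysisParams:
    return sq.AnalysisParams()


@pytest.fixture(scope="session")
def quantify(params):
    """Peptide table + designs -> oriented protein-ratio table."""

    def _quantify(peptides: pd.DataFrame, designs) -> pd.DataFrame:
        ratios = sq.peptide_ratio_table(peptides, params)
        return sq.orient_to_reference(sq.protein_table(ratios, params), designs)

    return _quantify


def with_peptide_count(truth, n_peptides: int):
    """Clone a ground-truth collection with a fixed peptide count per protein."""
    return [
        sq.GroundTruth(
            protein_id=g.protein_id,
            is_sumo_target=g.is_sumo_target,
            is_contaminant=g.is_contaminant,
            baseline_abundance=g.baseline_abundance,
            enrichment=g.enrichment,
            dep_weights=g.dep_weights,
            esc2_coupling=g.esc2_coupling,
            slx5_gain=g.slx5_gain,
            n_peptides=n_peptides,
        )
        for g in truth
    ]


def protein_frame(rows):
    """Build a minimal oriented protein-ratio table for calling tests.

    ``rows``: iterables of (protein_id, median_ratio, n_peptides).
    """
    df = pd.DataFrame(rows, columns=["protein_id", "median_ratio", "n_peptides"])
    df["experiment_id"] = "exp"
    df["mean_ratio"] = df["median_ratio"]
    df["imputed_fraction"] = 0.0
    df["under_quantified"] = df["n_peptides"] < 3
    df["oriented"] = True
    df["numerator_strain"] = "HF-SUMO"
    return df
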