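"""SUMO-target calling from dual label-swap replicate enrichment experiments.

A protein is called a SUMO target when it is quantified in both tagged-vs-mock
replicates and shows at least a 10-fold (default) tagged/mock abundance ratio
in each.  Contaminants co-purify equally from both arms and sit near ratio 1,
so the dual-replicate cutoff removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError
from .quant import AnalysisParams

TARGET_COLUMNS = (
    "protein_id",
    "ratio_rep1",
    "ratio_rep2",
    "n_peptides_rep1",
    "n_peptides_rep2",
    "eligible",
    "called",
)


@dataclass(frozen=True)
class ConcordanceReport:
    """Replicate overlap counts and paired log2 scatter data."""

    n_rep1: int
    n_rep2: int
    n_both: int
    pairs: pd.DataFrame  # protein_id, log2_rep1, log2_rep2
    only_rep1: tuple[str, ...]
    only_rep2: tuple[str, ...]

    def __post_init__(self):
        if self.n_both > min(self.n_rep1, self.n_rep2):
            raise ParameterError("replicate overlap exceeds a replicate size")


def _check_oriented(table: pd.DataFrame, name: str) -> None:
    if table.empty:
        raise ParameterError(f"{name}: empty protein table")
    if not bool(table["oriented"].all()):
        raise DesignError(f"{name}: table must be oriented (tagged strain in numerator)")


def call_targets(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    params: AnalysisParams,
    peptide_rule: str = "per_replicate",
) -> pd.DataFrame:
    """Apply the dual-replicate fold cutoff; returns all shared proteins.

    ``peptide_rule`` decides how the minimum-unique-peptides rule interacts
    with the two replicates: ``"per_replicate"`` (default) requires the
    minimum in each replicate, ``"combined"`` requires it summed over both.
    ``called`` is True iff the protein is eligible and its oriented median
    ratio is at least ``params.fold_cutoff`` in both replicates (inclusive).
    """
    _check_oriented(rep1, "rep1")
    _check_oriented(rep2, "rep2")
    if peptide_rule not in ("per_replicate", "combined"):
        raise ParameterError(f"unknown peptide_rule {peptide_rule!r}")
    cols = ["protein_id", "median_ratio", "n_peptides", "under_quantified"]
    merged = rep1[cols].merge(rep2[cols], on="protein_id", suffixes=("_rep1", "_rep2"))
    if peptide_rule == "per_replicate":
        eligible = ~(merged["under_quantified_rep1"] | merged["under_quantified_rep2"])
    else:
        eligible = (
            merged["n_peptides_rep1"] + merged["n_peptides_rep2"]
        ) >= params.min_unique_peptides
    called = (
        eligible
        & (merged["median_ratio_rep1"] >= params.fold_cutoff)
        & (merged["median_ratio_rep2"] >= params.fold_cutoff)
    )
    out = pd.DataFrame(
        {
            "protein_id": merged["protein_id"],
            "ratio_rep1": merged["median_ratio_rep1"],
            "ratio_rep2": merged["median_ratio_rep2"],
            "n_peptides_rep1": merged["n_peptides_rep1"],
            "n_peptides_rep2": merged["n_peptides_rep2"],
            "eligible": eligible,
            "called": called,
        }
    )
    return out.sort_values("protein_id").reset_index(drop=True)


def replicate_concordance(rep1: pd.DataFrame, rep2: pd.DataFrame) -> ConcordanceReport:
    """Overlap counts and paired log2 ratios of the two replicates."""
    _check_oriented(rep1, "rep1")
    _check_oriented(rep2, "rep2")
    ids1 = set(rep1["protein_id"])
    ids2 = set(rep2["protein_id"])
    both = sorted(ids1 & ids2)
    r1 = rep1.set_index("protein_id")["median_ratio"]
    r2 = rep2.set_index("protein_id")["median_ratio"]
    pairs = pd.DataFrame(
        {
            "protein_id": both,
            "log2_rep1": np.log2(r1.loc[both].to_numpy(dtype=float)),
            "log2_rep2": np.log2(r2.loc[both].to_numpy(dtype=float)),
        }
    )
    return ConcordanceReport(
        n_rep1=len(ids1),
        n_rep2=len(ids2),
        n_both=len(both),
        pairs=pairs,
        only_rep1=tuple(sorted(ids1 - ids2)),
        only_rep2=tuple(sorted(ids2 - ids1)),
    )
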