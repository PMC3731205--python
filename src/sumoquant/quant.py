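"""Peptide-level SILAC ratios and their protein-level rollup.

The quantification rules: a peptide's raw ratio is heavy/light ion intensity;
a channel that went undetected is imputed at the noise floor (minimal ion
intensity 1e3) so a finite ratio can still be formed; a protein is quantified
from at least three unique peptides, its abundance ratio being the median (and
mean) of the peptide ratios; ratios are then oriented so the non-reference
strain is in the numerator and reported on the log2 scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError, UnquantifiablePeptideError
from .simulate import ExperimentDesign

logger = logging.getLogger(__name__)


def ratio_median(values) -> float:
    """Median of ratios; even counts use the geometric midpoint.

    Abundance ratios live on a log scale, and the geometric midpoint of the
    central pair is the ordinary median of the log ratios.  It also makes the
    median commute with taking reciprocals, so label-swapped and direct
    mutant-vs-mutant comparisons aggregate consistently — the arithmetic
    midpoint does not (mean of reciprocals != reciprocal of the mean).
    Odd counts return the middle ratio unchanged.
    """
    arr = np.sort(np.asarray(list(values), dtype=float))
    n = arr.size
    if n == 0:
        raise ParameterError("median of empty ratio set")
    mid = n // 2
    if n % 2:
        return float(arr[mid])
    return float(math.sqrt(arr[mid - 1] * arr[mid]))

#: columns of the protein-ratio TSV
PROTEIN_COLUMNS = (
    "protein_id",
    "experiment_id",
    "n_peptides",
    "median_ratio",
    "mean_ratio",
    "imputed_fraction",
    "under_quantified",
    "oriented",
    "numerator_strain",
)


@dataclass(frozen=True)
class AnalysisParams:
    """Quantification constants.

    ``noise_floor``: minimal ion intensity substituted for an undetected
    channel.  ``min_unique_peptides``: unique peptides required to quantify a
    protein.  ``fold_cutoff``: enrichment required (in both replicates) to call
    a SUMO target.  Ratios are reported in log base 2.
    """

    noise_floor: float = 1e3
    min_unique_peptides: int = 3
    fold_cutoff: float = 10.0

    LOG_BASE = 2

    def __post_init__(self):
        if self.noise_floor <= 0:
            raise ParameterError("noise_floor must be positive")
        if self.min_unique_peptides < 1:
            raise ParameterError("min_unique_peptides must be >= 1")
        if self.fold_cutoff <= 1:
            raise ParameterError("fold_cutoff must exceed 1")


@dataclass(frozen=True)
class PeptideMeasurement:
    """One peptide's light/heavy ion intensities in one experiment."""

    protein_id: str
    peptide: str
    experiment_id: str
    light_intensity: float
    heavy_intensity: float


@dataclass(frozen=True)
class PeptideRatio:
    """Heavy/light ratio of one peptide, before orientation."""

    protein_id: str
    peptide: str
    experiment_id: str
    raw_ratio: float
    imputed: bool
    imputed_channel: str  # "light", "heavy" or "none"


@dataclass(frozen=True)
class ProteinRatio:
    """Protein-level abundance ratio over unique peptides."""

    protein_id: str
    experiment_id: str
    n_peptides: int
    median_ratio: float
    mean_ratio: float
    imputed_fraction: float
    under_quantified: bool
    oriented: bool = False
    numerator_strain: str = ""


def compute_peptide_ratio(m: PeptideMeasurement, params: AnalysisParams) -> PeptideRatio:
    """Heavy/light ratio with noise-floor imputation of an undetected channel."""
    light, heavy = m.light_intensity, m.heavy_intensity
    if light <= 0.0 and heavy <= 0.0:
        raise UnquantifiablePeptideError(
            f"{m.protein_id}/{m.peptide} in {m.experiment_id}: both channels empty"
        )
    channel = "none"
    if light <= 0.0:
        light, channel = params.noise_floor, "light"
    elif heavy <= 0.0:
        heavy, channel = params.noise_floor, "heavy"
    return PeptideRatio(
        protein_id=m.protein_id,
        peptide=m.peptide,
        experiment_id=m.experiment_id,
        raw_ratio=heavy / light,
        imputed=channel != "none",
        imputed_channel=channel,
    )


def peptide_ratio_table(peptides: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Vectorized :func:`compute_peptide_ratio` over a peptide table.

    Peptides empty in both channels carry no signal and are dropped with a
    logged warning.
    """
    light = peptides["light_intensity"].to_numpy(dtype=float)
    heavy = peptides["heavy_intensity"].to_numpy(dtype=float)
    dead = (light <= 0.0) & (heavy <= 0.0)
    if dead.any():
        logger.warning("dropping %d peptide(s) with no signal in either channel", dead.sum())
    out = peptides.loc[~dead, ["protein_id", "peptide", "experiment_id"]].copy()
    light, heavy = light[~dead], heavy[~dead]
    light_f = np.where(light <= 0.0, params.noise_floor, light)
    heavy_f = np.where(heavy <= 0.0, params.noise_floor, heavy)
    out["raw_ratio"] = heavy_f / light_f
    out["imputed_channel"] = np.where(
        light <= 0.0, "light", np.where(heavy <= 0.0, "heavy", "none")
    )
    out["imputed"] = out["imputed_channel"] != "none"
    return out.reset_index(drop=True)


def protein_table(ratios: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Roll peptide ratios up to proteins, one row per (protein, experiment).

    Duplicate peptide sequences (e.g. charge states) are collapsed to their
    median ratio before counting, so ``n_peptides`` counts unique sequences.
    Proteins with fewer than ``min_unique_peptides`` are flagged
    ``under_quantified`` and are excluded from target calling downstream.
    """
    if ratios.empty:
        raise ParameterError("empty peptide-ratio table")
    per_pep = (
        ratios.groupby(["protein_id", "experiment_id", "peptide"], sort=True)
        .agg(raw_ratio=("raw_ratio", ratio_median), imputed=("imputed", "any"))
        .reset_index()
    )
    agg = (
        per_pep.groupby(["protein_id", "experiment_id"], sort=True)
        .agg(
            n_peptides=("peptide", "size"),
            median_ratio=("raw_ratio", ratio_median),
            mean_ratio=("raw_ratio", "mean"),
            imputed_fraction=("imputed", "mean"),
        )
        .reset_index()
    )
    agg["under_quantified"] = agg["n_peptides"] < params.min_unique_peptides
    agg["oriented"] = False
    agg["numerator_strain"] = ""
    return agg[list(PROTEIN_COLUMNS)]


def aggregate_protein(
    ratios: Sequence[PeptideRatio], params: AnalysisParams
) -> ProteinRatio:
    """Aggregate the peptide ratios of a single protein and experiment."""
    if not ratios:
        raise ParameterError("no peptide ratios to aggregate")
    keys = {(r.protein_id, r.experiment_id) for r in ratios}
    if len(keys) != 1:
        raise ParameterError(f"mixed protein/experiment keys: {sorted(keys)}")
    df = pd.DataFrame([r.__dict__ for r in ratios])
    row = protein_table(df, params).iloc[0]
    return ProteinRatio(
        protein_id=row["protein_id"],
        experiment_id=row["experiment_id"],
        n_peptides=int(row["n_peptides"]),
        median_ratio=float(row["median_ratio"]),
        mean_ratio=float(row["mean_ratio"]),
        imputed_fraction=float(row["imputed_fraction"]),
        under_quantified=bool(row["under_quantified"]),
    )


def _design_map(
    designs: Iterable[ExperimentDesign] | Mapping[str, ExperimentDesign],
) -> Mapping[str, ExperimentDesign]:
    if isinstance(designs, Mapping):
        return designs
    return {d.experiment_id: d for d in designs}


def orient_to_reference(
    table: pd.DataFrame,
    designs: Iterable[ExperimentDesign] | Mapping[str, ExperimentDesign],
) -> pd.DataFrame:
    """Re-express protein ratios with the non-reference strain in the numerator.

    Raw ratios are heavy/light; when the reference strain was grown heavy the
    ratio is inverted, so oriented ratios are always mutant/WT or tagged/mock.
    """
    dmap = _design_map(designs)
    out = table.copy()
    invert = np.empty(len(out), dtype=bool)
    numerator = np.empty(len(out), dtype=object)
    for k, exp_id in enumerate(out["experiment_id"]):
        try:
            design = dmap[exp_id]
        except KeyError:
            raise DesignError(f"experiment {exp_id!r} absent from design table") from None
        invert[k] = not design.reference_is_light
        numerator[k] = design.non_reference_strain
    for col in ("median_ratio", "mean_ratio"):
        vals = out[col].to_numpy(dtype=float)
        out[col] = np.where(invert, 1.0 / vals, vals)
    out["oriented"] = True
    out["numerator_strain"] = numerator
    return out


def log2_transform(table: pd.DataFrame) -> pd.Series:
    """Map protein_id -> log2 oriented median ratio for one experiment.

    Under-quantified proteins are omitted; a protein absent from the returned
    mapping is "not available" for that experiment.
    """
    if not bool(table["oriented"].all()):
        raise DesignError("log2_transform requires oriented ratios")
    if table["experiment_id"].nunique() > 1:
        raise DesignError("log2_transform expects a single experiment")
    quant = table.loc[~table["under_quantified"]]
    values = np.log2(quant["median_ratio"].to_numpy(dtype=float))
    return pd.Series(values, index=pd.Index(quant["protein_id"], name="protein_id"))
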