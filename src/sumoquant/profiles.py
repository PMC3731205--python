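"""E3-ligase specificity profiles, ratio-of-ratios comparisons, dependency calls.

Each called SUMO target gets a per-genotype vector of log2 sumoylation changes
(mutant/WT).  An indirect mutant-vs-mutant comparison is the difference of two
such log2 changes — the ratio of ratios — and can be validated against a
direct mutant-vs-mutant experiment.  A small ordered rule set then classifies
each target's ligase dependency (Siz1-specific, Siz1/Siz2-redundant,
Mms21-preferred, ...).  Missing values propagate as NA; nothing is imputed at
the profile level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError
from .quant import log2_transform
from .simulate import CORE_GENOTYPES, PROFILE_GENOTYPES

DEPENDENCY_CATEGORIES = (
    "siz1_specific",
    "siz1_siz2_redundant",
    "mms21_preferred",
    "mixed",
    "unaffected",
    "up_in_mutant",
    "insufficient_data",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Log2 thresholds for the dependency classifier.

    ``strong_loss``: at or below this the modification is essentially gone;
    ``unaffected_band``: half-width of the "no change" band around 0;
    ``gain``: at or above this the target accumulates in the mutant.
    """

    strong_loss: float = -2.0
    unaffected_band: float = 0.5
    gain: float = 1.0

    def __post_init__(self):
        if not (self.strong_loss < -self.unaffected_band < 0 < self.unaffected_band < self.gain):
            raise ParameterError(
                "need strong_loss < -unaffected_band < 0 < unaffected_band < gain"
            )


@dataclass(frozen=True)
class ValidationReport:
    """Concordance between derived and direct mutant-vs-mutant log2 ratios."""

    table: pd.DataFrame  # protein_id, derived_log2, direct_log2, abs_diff
    tolerance_log2: float
    n_compared: int
    concordant_fraction: float


def build_profiles(
    targets: pd.DataFrame,
    mutant_tables: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-genotype log2 change matrix for called targets.

    ``mutant_tables`` maps genotype labels (from the declared profile set) to
    oriented mutant-vs-WT protein tables.  Genotypes where a target was not
    quantified are NA (NaN).  Rows: called targets only.
    """
    unknown = set(mutant_tables) - set(PROFILE_GENOTYPES)
    if unknown:
        raise DesignError(f"unknown genotype label(s): {sorted(unknown)}")
    called = targets.loc[targets["called"], "protein_id"].tolist()
    profile = pd.DataFrame(index=pd.Index(called, name="protein_id"))
    for genotype in PROFILE_GENOTYPES:
        if genotype in mutant_tables:
            profile[genotype] = log2_transform(mutant_tables[genotype]).reindex(called)
        else:
            profile[genotype] = np.nan
    return profile


def ratio_of_ratios(
    profiles: pd.DataFrame,
    numerator_genotype: str,
    denominator_genotype: str,
) -> pd.DataFrame:
    """Indirect mutant-vs-mutant comparison from two mutant-vs-WT profiles.

    log2(numerator/WT) - log2(denominator/WT) equals the log2 abundance ratio
    between the two mutants; NA in either operand propagates.
    """
    for g in (numerator_genotype, denominator_genotype):
        if g not in profiles.columns:
            raise DesignError(f"genotype {g!r} not in profile set {tuple(profiles.columns)}")
    out = pd.DataFrame(index=profiles.index)
    out["numerator_genotype"] = numerator_genotype
    out["denominator_genotype"] = denominator_genotype
    out["derived_log2"] = profiles[numerator_genotype] - profiles[denominator_genotype]
    return out


def validate_derived_vs_direct(
    derived: pd.DataFrame,
    direct: pd.DataFrame,
    tolerance_log2: float = 1.0,
) -> ValidationReport:
    """Compare ratio-of-ratios values with a direct mutant-vs-mutant run.

    ``direct`` is an oriented protein table whose numerator strain is the
    derived comparison's numerator genotype.  The report carries per-protein
    absolute log2 differences and the fraction within ``tolerance_log2``.
    """
    direct_log2 = log2_transform(direct)
    table = pd.DataFrame(
        {
            "derived_log2": derived["derived_log2"],
            "direct_log2": direct_log2.reindex(derived.index),
        }
    ).dropna()
    if table.empty:
        raise ParameterError("no proteins shared between derived and direct comparisons")
    table["abs_diff"] = (table["derived_log2"] - table["direct_log2"]).abs()
    frac = float((table["abs_diff"] <= tolerance_log2).mean())
    return ValidationReport(
        table=table.reset_index(),
        tolerance_log2=tolerance_log2,
        n_compared=len(table),
        concordant_fraction=frac,
    )


def classify_dependency(
    profile: Mapping[str, float],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> str:
    """Ordered decision rule over the four core genotypes.

    In order: insufficient data (two or more core genotypes NA);
    Siz1-specific (lost in siz1Δ, untouched in mms21-11); Mms21-preferred
    (lost in mms21-11, not in siz1Δ siz2Δ); Siz1/Siz2-redundant (lost only in
    the double deletion, Mms21 intact); up-in-mutant (a gain with no strong
    loss); unaffected (all changes within the band); otherwise mixed.
    Comparisons against NA are False, so a single missing genotype can only
    demote a call towards "mixed", never invent one.
    """
    t = thresholds
    core = [float(profile.get(g, math.nan)) for g in CORE_GENOTYPES]
    if sum(math.isnan(v) for v in core) >= 2:
        return "insufficient_data"
    s1, s2, dd, mm = core

    def le(x: float, bound: float) -> bool:
        return not math.isnan(x) and x <= bound

    def gt(x: float, bound: float) -> bool:
        return not math.isnan(x) and x > bound

    def within(x: float, half_width: float) -> bool:
        return not math.isnan(x) and abs(x) <= half_width

    if le(s1, t.strong_loss) and within(mm, t.unaffected_band):
        return "siz1_specific"
    if le(mm, t.strong_loss) and gt(dd, t.strong_loss):
        return "mms21_preferred"
    if (
        le(dd, t.strong_loss)
        and gt(s1, t.strong_loss)
        and gt(s2, t.strong_loss)
        and gt(mm, t.strong_loss)
    ):
        return "siz1_siz2_redundant"
    finite = [v for v in core if not math.isnan(v)]
    if any(v >= t.gain for v in finite) and not any(v <= t.strong_loss for v in finite):
        return "up_in_mutant"
    if all(abs(v) <= t.unaffected_band for v in finite):
        return "unaffected"
    return "mixed"


def classify_profiles(
    profiles: pd.DataFrame,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.Series:
    """Vectorize :func:`classify_dependency` over a profile matrix."""
    calls = [classify_dependency(dict(row), thresholds) for _, row in profiles.iterrows()]
    return pd.Series(calls, index=profiles.index, name="category")
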