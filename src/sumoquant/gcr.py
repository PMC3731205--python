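"""Fluctuation-assay GCR rates, fold increases, assay ratios, interaction calls.

Gross chromosomal rearrangement (GCR) rates come from Luria–Delbrück
fluctuation assays: parallel cultures are plated on canavanine/5-FOA and the
distribution of resistant-colony counts is converted to a per-cell rate.  The
default estimator is the Lea–Coulson method of the median — solve

    r_median / m - ln(m) = 1.24

for m, the expected mutations per culture, and divide by the culture size —
with a zero-class (p0) fallback, m = -ln(f0), when the median count is zero.

From the rates the module rebuilds the published-style summary table: each
genotype's rate in the single-copy (yel068c::CAN1/URA3) and duplication-
mediated (yel072w::CAN1/URA3) assays, its fold increase over the wild-type
single-copy rate, and the duplication/non-duplication assay ratio.  Fold
triplets for double mutants are classified as synergistic (above kappa times
the additive expectation) or epistatic (within kappa of the stronger single).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import BelowDetectionError, PackagingError, ParameterError
from .simulate import MutantCounts

#: Lea–Coulson median relation constant: median/m - ln(m) = LC_CONSTANT
LC_CONSTANT = 1.24

ASSAYS = ("yel068c", "yel072w")

_FIXTURE = "table1_rates.tsv"


@dataclass(frozen=True)
class GcrResult:
    """A GCR rate estimate (events per cell per generation)."""

    genotype: str
    assay: str
    rate: float
    estimator: str  # "lc_median", "p0" or "supplied"
    fold_vs_reference: float | None = None

    def __post_init__(self):
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.estimator not in ("lc_median", "p0", "supplied"):
            raise ParameterError(f"unknown estimator {self.estimator!r}")


@dataclass(frozen=True)
class InteractionCall:
    """Genetic-interaction category for a double mutant's fold triplet."""

    genotype_pair: tuple[str, str]
    assay: str
    fold_a: float
    fold_b: float
    fold_ab: float
    expected_additive: float
    kappa: float
    category: str  # "synergistic", "epistatic" or "intermediate"


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures, halves away from zero."""
    if sig_figs < 1:
        raise ParameterError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    exponent = d.adjusted()  # floor(log10(|x|))
    quantum = Decimal(1).scaleb(exponent - sig_figs + 1)
    rounded = d.quantize(quantum, rounding=ROUND_HALF_UP)
    if rounded.adjusted() > exponent:  # rounding rolled over a decade, e.g. 9.96 -> 10
        rounded = d.quantize(Decimal(1).scaleb(rounded.adjusted() - sig_figs + 1), ROUND_HALF_UP)
    return float(rounded)


def printed_sig_figs(printed: str) -> int:
    """Significant figures of a printed numeral (trailing zeros count)."""
    s = printed.strip().lstrip("+-")
    if "e" in s.lower():
        s = s.lower().split("e", 1)[0]
    digits = s.replace(".", "").lstrip("0")
    if not digits:
        raise ParameterError(f"no significant digits in {printed!r}")
    return len(digits)


def lc_median_m(median_count: float) -> float:
    """Solve median/m - ln(m) = 1.24 for m (expected mutations per culture)."""
    if median_count <= 0:
        raise ParameterError("Lea–Coulson median solver needs a positive median")

    def f(m: float) -> float:
        return median_count / m - math.log(m) - LC_CONSTANT

    return float(brentq(f, 1e-6, 1e6, xtol=1e-9, rtol=1e-12))


def p0_m(zero_fraction: float) -> float:
    """Zero-class estimator: m = -ln(f0)."""
    if not 0.0 < zero_fraction < 1.0:
        raise ParameterError("zero-class fraction must be in (0, 1)")
    return -math.log(zero_fraction)


def estimate_rate(counts: MutantCounts) -> GcrResult:
    """Estimate the per-cell GCR rate from fluctuation-assay counts.

    Lea–Coulson method of the median when the median count is positive, the
    p0 (zero-class) estimator otherwise.  With no mutants in any culture only
    an upper bound exists, raised as :class:`BelowDetectionError`.
    """
    data = np.asarray(counts.counts, dtype=float)
    if data.size < 5:
        raise ParameterError("need at least 5 cultures to estimate a rate")
    nt = counts.cells_per_culture
    if nt <= 0:
        raise ParameterError("cells_per_culture must be positive")
    median = float(np.median(data))
    if median > 0:
        m = lc_median_m(median)
        estimator = "lc_median"
    else:
        zero_fraction = float((data == 0).mean())
        if zero_fraction >= 1.0:
            n = data.size
            bound = -math.log(1.0 - 1.0 / (n + 1)) / nt
            raise BelowDetectionError(
                f"no mutants in any of {n} cultures; rate < {bound:.3g}", upper_bound=bound
            )
        m = p0_m(zero_fraction)
        estimator = "p0"
    return GcrResult(
        genotype=counts.genotype, assay=counts.assay, rate=m / nt, estimator=estimator
    )


def fold_increase(rate: float, reference_rate: float, sig_figs: int = 3) -> float:
    """Rate over the reference rate, rounded to significant figures."""
    if rate <= 0 or reference_rate <= 0:
        raise ParameterError("rates must be positive")
    return round_sig(rate / reference_rate, sig_figs)


def assay_ratio(rate_dup: float, rate_nondup: float, sig_figs: int = 2) -> float:
    """Duplication-assay rate over single-copy-assay rate, rounded."""
    if rate_dup <= 0 or rate_nondup <= 0:
        raise ParameterError("rates must be positive")
    return round_sig(rate_dup / rate_nondup, sig_figs)


def classify_interaction(
    fold_a: float,
    fold_b: float,
    fold_ab: float,
    kappa: float = 1.5,
    genotype_pair: tuple[str, str] = ("a", "b"),
    assay: str = "yel072w",
) -> InteractionCall:
    """Synergy/epistasis call from single- and double-mutant fold increases.

    Synergistic when the double mutant exceeds kappa times the additive
    expectation fold_a + fold_b - 1; epistatic when it stays within kappa of
    the stronger single mutant; intermediate otherwise.  Both conditions can
    hold when one single mutant dominates, so synergy is tested first only
    when the double mutant exceeds both singles.
    """
    if min(fold_a, fold_b, fold_ab) <= 0:
        raise ParameterError("fold increases must be positive")
    if kappa < 1.0:
        raise ParameterError("kappa must be >= 1")
    expected_additive = fold_a + fold_b - 1.0
    synergistic = fold_ab >= kappa * expected_additive
    epistatic = fold_ab <= kappa * max(fold_a, fold_b)
    if fold_ab > max(fold_a, fold_b):
        category = "synergistic" if synergistic else ("epistatic" if epistatic else "intermediate")
    else:
        category = "epistatic" if epistatic else ("synergistic" if synergistic else "intermediate")
    return InteractionCall(
        genotype_pair=genotype_pair,
        assay=assay,
        fold_a=fold_a,
        fold_b=fold_b,
        fold_ab=fold_ab,
        expected_additive=expected_additive,
        kappa=kappa,
        category=category,
    )


def load_printed_rates() -> pd.DataFrame:
    """The packaged fixture of published GCR rates and printed folds/ratios.

    Columns: genotype, rate_yel068c, printed_fold_yel068c, rate_yel072w,
    printed_fold_yel072w, printed_ratio.  Printed cells are kept as strings to
    preserve the precision each was published with.
    """
    try:
        path = resources.files("sumoquant").joinpath("data", _FIXTURE)
        with path.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    except (FileNotFoundError, OSError) as exc:
        raise PackagingError(f"fixture {_FIXTURE} missing or unreadable: {exc}") from exc
    expected = {
        "genotype",
        "rate_yel068c",
        "printed_fold_yel068c",
        "rate_yel072w",
        "printed_fold_yel072w",
        "printed_ratio",
    }
    if set(df.columns) != expected or df.empty:
        raise PackagingError(f"fixture {_FIXTURE} has unexpected layout")
    return df


def build_rate_table(
    rates: dict[str, dict[str, float]],
    reference_rate: float,
    sig_figs: int = 3,
) -> pd.DataFrame:
    """One summary row per genotype: both assay rates, folds and the ratio.

    ``rates`` maps genotype -> {assay: rate}; ``reference_rate`` is the
    wild-type single-copy (yel068c) rate.  Missing assays yield NA cells.
    """
    if reference_rate <= 0:
        raise ParameterError("reference rate must be positive")
    rows = []
    for genotype, per_assay in rates.items():
        r68 = per_assay.get("yel068c")
        r72 = per_assay.get("yel072w")
        rows.append(
            {
                "genotype": genotype,
                "rate_yel068c": r68,
                "fold_yel068c": fold_increase(r68, reference_rate, sig_figs) if r68 else None,
                "rate_yel072w": r72,
                "fold_yel072w": fold_increase(r72, reference_rate, sig_figs) if r72 else None,
                "ratio": assay_ratio(r72, r68, sig_figs) if (r68 and r72) else None,
            }
        )
    return pd.DataFrame(rows)


def reproduce_table1() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute every printed fold/ratio cell from the packaged rates.

    Returns ``(table, report)``.  ``table`` mirrors the published layout with
    recomputed cells; ``report`` has one row per printed cell with the
    recomputed value (rounded to the cell's own significant figures), the
    printed value and a match flag.  Cells where the published rounding is
    internally inconsistent come out flagged, not forced.
    """
    fixture = load_printed_rates()
    reference = float(fixture.loc[fixture["genotype"] == "Wild type", "rate_yel068c"].iloc[0])
    table_rows, report_rows = [], []
    for _, row in fixture.iterrows():
        r68 = float(row["rate_yel068c"])
        r72 = float(row["rate_yel072w"])
        cells = {
            "fold_yel068c": (row["printed_fold_yel068c"], r68 / reference),
            "fold_yel072w": (row["printed_fold_yel072w"], r72 / reference),
            "ratio": (row["printed_ratio"], r72 / r68),
        }
        computed = {}
        for cell, (printed, quotient) in cells.items():
            sig = printed_sig_figs(printed)
            value = round_sig(quotient, sig)
            computed[cell] = value
            report_rows.append(
                {
                    "genotype": row["genotype"],
                    "cell": cell,
                    "printed": printed,
                    "sig_figs": sig,
                    "computed": value,
                    "quotient": quotient,
                    "match": math.isclose(value, float(printed), rel_tol=1e-9),
                }
            )
        table_rows.append(
            {
                "genotype": row["genotype"],
                "rate_yel068c": r68,
                "fold_yel068c": computed["fold_yel068c"],
                "rate_yel072w": r72,
                "fold_yel072w": computed["fold_yel072w"],
                "ratio": computed["ratio"],
            }
        )
    return pd.DataFrame(table_rows), pd.DataFrame(report_rows)
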