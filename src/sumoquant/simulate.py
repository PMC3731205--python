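"""Synthetic SILAC proteomes and fluctuation-assay counts with known ground truth.

This module is the generative counterpart of a quantitative SUMO-proteomics
study in budding yeast.  Two strains are metabolically labeled with light or
heavy Lys/Arg, mixed in equal amounts, and SUMO conjugates are purified; every
detected peptide therefore carries a light and a heavy ion intensity whose
ratio reflects the relative abundance of the protein between the two strains.
The generator produces

* a ground-truth proteome: bona fide SUMO targets strongly enriched in the
  tagged (HF-SUMO) purification, contaminants near ratio 1, and a weakly
  enriched remainder;
* per-target E3-ligase dependency structure: sumoylation carried by Siz1 only,
  by Siz2 only, redundantly by Siz1/Siz2, or by Mms21 — with the Mms21
  component positively coupled to Esc2 and accumulating when the Slx5-Slx8
  STUbL is absent;
* peptide tables with lognormal ratio noise, peptide-specific ionization
  efficiencies, label-swap support, and missing-in-one-channel dropouts;
* Luria–Delbrück fluctuation-assay mutant counts for GCR-rate estimation.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, ParameterError

#: canonical column order of the peptide-level TSV dialect
PEPTIDE_COLUMNS = (
    "protein_id",
    "peptide",
    "experiment_id",
    "light_intensity",
    "heavy_intensity",
)

#: ligase-dependency weight keys of a SUMO target
DEP_KEYS = ("siz1_only", "siz2_only", "siz_redundant", "mms21")

#: per-strain activity flags consumed by the dependency model
FLAG_KEYS = ("siz1", "siz2", "mms21_ligase", "esc2", "slx5")

#: the four genotypes entering the dependency classification
CORE_GENOTYPES = ("siz1Δ", "siz2Δ", "siz1Δ siz2Δ", "mms21-11")

#: the full declared genotype set for specificity profiles
PROFILE_GENOTYPES = CORE_GENOTYPES + (
    "esc2Δ",
    "slx5Δ",
    "slx5Δ siz1Δ",
    "slx5Δ siz2Δ",
)

TAGGED_STRAIN = "HF-SUMO"
MOCK_STRAIN = "mock"
WT_STRAIN = "WT"

# dependency-class mixture of the synthetic SUMO-target population: a few
# Siz1-only targets (septin-like), a redundant Siz1/Siz2 majority, a small
# Mms21-preferred subset (RNA Pol I / SMC-like) and a mixed remainder.  No
# Siz2-exclusive class: none was observed in vivo.
DEP_CLASS_NAMES = ("siz1_only", "siz_redundant", "mms21", "mixed")
DEP_CLASS_PROBS = (0.10, 0.55, 0.15, 0.20)
_MIXED_ALPHA = (1.0, 0.3, 2.0, 1.0)  # Dirichlet over DEP_KEYS for the mixed class

_AA = "ACDEFGHILMNPQSTVWY"  # tryptic peptide bodies; C-terminal K/R appended


def genotype_flags(label: str) -> dict[str, bool]:
    """Activity flags for the five regulators encoded by a genotype label.

    ``"WT"`` (all active), space-separated deletion tokens (``"siz1Δ siz2Δ"``)
    and the two ligase-dead *mms21* alleles are understood.
    """
    flags = {k: True for k in FLAG_KEYS}
    if label in (WT_STRAIN, "wild type", "Wild type", TAGGED_STRAIN, MOCK_STRAIN):
        return flags
    for token in label.split():
        if token == "siz1Δ":
            flags["siz1"] = False
        elif token == "siz2Δ":
            flags["siz2"] = False
        elif token in ("mms21-11", "mms21-CH"):
            flags["mms21_ligase"] = False
        elif token == "esc2Δ":
            flags["esc2"] = False
        elif token == "slx5Δ":
            flags["slx5"] = False
        else:
            raise DesignError(f"unknown genotype token {token!r} in label {label!r}")
    return flags


@dataclass(frozen=True)
class GroundTruth:
    """True state of one protein in the synthetic proteome."""

    protein_id: str
    is_sumo_target: bool
    is_contaminant: bool
    baseline_abundance: float
    enrichment: float
    dep_weights: Mapping[str, float]
    esc2_coupling: float
    slx5_gain: float
    n_peptides: int

    def __post_init__(self):
        if self.is_sumo_target and self.is_contaminant:
            raise ConfigError(f"{self.protein_id}: target and contaminant are exclusive")
        if self.baseline_abundance <= 0 or self.enrichment <= 0:
            raise ConfigError(f"{self.protein_id}: abundances must be positive")
        if self.n_peptides < 1:
            raise ConfigError(f"{self.protein_id}: need at least one peptide")
        if not 0.0 <= self.esc2_coupling <= 1.0:
            raise ConfigError(f"{self.protein_id}: esc2_coupling outside [0, 1]")
        if self.slx5_gain < 1.0:
            raise ConfigError(f"{self.protein_id}: slx5_gain must be >= 1")
        total = sum(self.dep_weights.get(k, 0.0) for k in DEP_KEYS)
        if self.is_sumo_target and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"{self.protein_id}: dependency weights sum to {total}")
        if self.is_contaminant and not 0.5 <= self.enrichment <= 2.0:
            raise ConfigError(f"{self.protein_id}: contaminant enrichment outside [0.5, 2]")


@dataclass(frozen=True)
class ExperimentDesign:
    """Which strain sits in which SILAC channel for one experiment.

    ``reference_strain`` is the denominator of the oriented ratio: the mock
    purification for target-identification runs, the wild type for mutant
    comparisons (or the denominator mutant for direct mutant-vs-mutant runs).
    """

    experiment_id: str
    light_strain: str
    heavy_strain: str
    reference_strain: str
    genotype_flags: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)

    def __post_init__(self):
        if self.light_strain == self.heavy_strain:
            raise DesignError(f"{self.experiment_id}: identical strains in both channels")
        if self.reference_strain not in (self.light_strain, self.heavy_strain):
            raise DesignError(
                f"{self.experiment_id}: reference {self.reference_strain!r} is in neither channel"
            )

    @property
    def is_enrichment(self) -> bool:
        """True for tagged-vs-mock (target identification) designs."""
        return self.reference_strain == MOCK_STRAIN

    @property
    def non_reference_strain(self) -> str:
        return self.heavy_strain if self.reference_strain == self.light_strain else self.light_strain

    @property
    def reference_is_light(self) -> bool:
        return self.reference_strain == self.light_strain


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    ``peptide_noise_sigma`` is the standard deviation of the lognormal peptide
    ratio noise on the natural-log scale; ``missing_channel_prob`` is the
    probability that the lower-intensity channel of a peptide goes undetected.
    """

    seed: int
    n_proteins: int = 300
    target_fraction: float = 0.50
    contaminant_fraction: float = 0.35
    peptide_noise_sigma: float = 0.2
    missing_channel_prob: float = 0.05
    intensity_log_mean: float = 11.5
    intensity_log_sd: float = 1.0

    def __post_init__(self):
        for name in ("target_fraction", "contaminant_fraction", "missing_channel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.target_fraction + self.contaminant_fraction > 1.0 + 1e-12:
            raise ConfigError("target_fraction + contaminant_fraction exceeds 1")
        if self.peptide_noise_sigma < 0:
            raise ConfigError("peptide_noise_sigma must be non-negative")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.intensity_log_sd < 0:
            raise ConfigError("intensity_log_sd must be non-negative")


@dataclass(frozen=True)
class MutantCounts:
    """Mutant colonies per culture from one fluctuation assay."""

    genotype: str
    assay: str
    counts: tuple[int, ...]
    cells_per_culture: float

    def __post_init__(self):
        if len(self.counts) < 1:
            raise ParameterError("need at least one culture")
        if any(c < 0 for c in self.counts):
            raise ParameterError("mutant counts must be non-negative")
        if self.cells_per_culture < max(self.counts):
            raise ParameterError("cells_per_culture smaller than a mutant count")


def sumoylation_level(truth: GroundTruth, flags: Mapping[str, bool]) -> float:
    """Relative sumoylation of a target under a genotype, wild type = 1.

    The level is linear in the ligase components with a ``max`` term for the
    Siz1/Siz2-redundant share.  The Mms21 component is scaled down by the Esc2
    coupling when Esc2 is absent and scaled up by ``slx5_gain`` when Slx5 is
    absent (STUbL antagonism).  Non-targets sit at 1 in every genotype.
    """
    if not truth.is_sumo_target:
        return 1.0
    w = truth.dep_weights
    a1 = 1.0 if flags["siz1"] else 0.0
    a2 = 1.0 if flags["siz2"] else 0.0
    am = 1.0 if flags["mms21_ligase"] else 0.0
    ae = 1.0 if flags["esc2"] else 0.0
    mms = w.get("mms21", 0.0) * am * (1.0 - truth.esc2_coupling * (1.0 - ae))
    if not flags["slx5"]:
        mms *= truth.slx5_gain
    return (
        w.get("siz1_only", 0.0) * a1
        + w.get("siz2_only", 0.0) * a2
        + w.get("siz_redundant", 0.0) * max(a1, a2)
        + mms
    )


def _pure_weights(key: str) -> dict[str, float]:
    return {k: (1.0 if k == key else 0.0) for k in DEP_KEYS}


def generate_ground_truth(config: GeneratorConfig) -> list[GroundTruth]:
    """Draw a synthetic proteome; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_targets = int(round(n * config.target_fraction))
    n_contam = int(round(n * config.contaminant_fraction))
    n_contam = min(n_contam, n - n_targets)
    width = max(4, len(str(n)))
    records: list[GroundTruth] = []
    for i in range(n):
        pid = f"P{i:0{width}d}"
        baseline = float(np.exp(rng.normal(config.intensity_log_mean, config.intensity_log_sd)))
        n_pep = 2 + int(rng.poisson(4.0))
        if i < n_targets:
            enrichment = float(max(12.0, np.exp(rng.normal(np.log(50.0), 0.6))))
            cls = DEP_CLASS_NAMES[rng.choice(len(DEP_CLASS_NAMES), p=DEP_CLASS_PROBS)]
            if cls == "mixed":
                raw = rng.dirichlet(_MIXED_ALPHA)
                weights = {k: float(v) for k, v in zip(DEP_KEYS, raw)}
            else:
                weights = _pure_weights(cls)
            records.append(
                GroundTruth(
                    protein_id=pid,
                    is_sumo_target=True,
                    is_contaminant=False,
                    baseline_abundance=baseline,
                    enrichment=enrichment,
                    dep_weights=weights,
                    esc2_coupling=float(rng.beta(8.0, 2.0)),
                    slx5_gain=float(max(1.0, np.exp(rng.normal(np.log(2.0), 0.4)))),
                    n_peptides=n_pep,
                )
            )
        elif i < n_targets + n_contam:
            enrichment = float(np.clip(np.exp(rng.normal(0.0, 0.15)), 0.5, 2.0))
            records.append(
                GroundTruth(
                    protein_id=pid,
                    is_sumo_target=False,
                    is_contaminant=True,
                    baseline_abundance=baseline,
                    enrichment=enrichment,
                    dep_weights={k: 0.0 for k in DEP_KEYS},
                    esc2_coupling=0.0,
                    slx5_gain=1.0,
                    n_peptides=n_pep,
                )
            )
        else:
            # weakly enriched bystanders: identified, below the calling cutoff
            records.append(
                GroundTruth(
                    protein_id=pid,
                    is_sumo_target=False,
                    is_contaminant=False,
                    baseline_abundance=baseline,
                    enrichment=float(rng.uniform(2.0, 8.0)),
                    dep_weights={k: 0.0 for k in DEP_KEYS},
                    esc2_coupling=0.0,
                    slx5_gain=1.0,
                    n_peptides=n_pep,
                )
            )
    return records


def _protein_rng(config: GeneratorConfig, index: int) -> np.random.Generator:
    # experiment-independent stream: peptide sequences and ionization factors
    # must be identical across designs so that a label swap is a pure column swap
    return np.random.default_rng([config.seed & 0x7FFFFFFF, 1_000_003, index])


def _experiment_rng(config: GeneratorConfig, experiment_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(experiment_id.encode("utf-8")), 23]
    )


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(7, 15))
        body = "".join(_AA[k] for k in rng.integers(0, len(_AA), size=length))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


def _strain_level(truth: GroundTruth, design: ExperimentDesign, strain: str) -> float:
    if design.is_enrichment:
        return 1.0 if strain == MOCK_STRAIN else truth.enrichment
    try:
        flags = design.genotype_flags[strain]
    except KeyError:
        raise DesignError(
            f"{design.experiment_id}: strain {strain!r} missing from genotype_flags"
        ) from None
    return sumoylation_level(truth, flags)


def simulate_silac_experiment(
    truth: Sequence[GroundTruth],
    design: ExperimentDesign,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Simulate one SILAC purification; returns the peptide table.

    Each peptide's reference-channel intensity is the protein baseline times a
    peptide-specific ionization factor; the other channel carries the true
    between-strain ratio times lognormal noise ``exp(eps)``,
    ``eps ~ N(0, sigma^2)``.  A fully lost modification (level 0) yields an
    undetected channel, and with ``missing_channel_prob`` the lower channel of
    an otherwise detected peptide is dropped — both exercise the noise-floor
    imputation path downstream.
    """
    rng_e = _experiment_rng(config, design.experiment_id)
    light, heavy = design.light_strain, design.heavy_strain
    ref = design.reference_strain
    other = design.non_reference_strain
    if not design.is_enrichment:
        for strain in (light, heavy):
            if strain not in design.genotype_flags:
                raise DesignError(
                    f"{design.experiment_id}: strain {strain!r} missing from genotype_flags"
                )
    rows: list[tuple] = []
    for i, gt in enumerate(truth):
        rng_p = _protein_rng(config, i)
        fly = np.exp(rng_p.normal(0.0, 0.5, size=gt.n_peptides))
        peptides = _peptide_sequences(rng_p, gt.n_peptides)
        # draw per-peptide noise and dropout variates unconditionally so the
        # stream is identical under swapped channel assignment
        eps = rng_e.normal(0.0, config.peptide_noise_sigma, size=gt.n_peptides)
        u_miss = rng_e.random(gt.n_peptides)
        lv_ref = _strain_level(gt, design, ref)
        lv_other = _strain_level(gt, design, other)
        for j in range(gt.n_peptides):
            base = gt.baseline_abundance * fly[j]
            inten = {
                ref: base * lv_ref,
                other: base * lv_other * math.exp(eps[j]),
            }
            li, hi = inten[light], inten[heavy]
            if li > 0.0 and hi > 0.0 and u_miss[j] < config.missing_channel_prob:
                if li < hi:
                    li = 0.0
                elif hi < li:
                    hi = 0.0
            rows.append((gt.protein_id, peptides[j], design.experiment_id, li, hi))
    return pd.DataFrame(rows, columns=list(PEPTIDE_COLUMNS))


def enrichment_replicates() -> tuple[ExperimentDesign, ExperimentDesign]:
    """The two label-swap tagged-vs-mock replicates (tagged light first)."""
    rep1 = ExperimentDesign(
        experiment_id="rep1",
        light_strain=TAGGED_STRAIN,
        heavy_strain=MOCK_STRAIN,
        reference_strain=MOCK_STRAIN,
    )
    rep2 = ExperimentDesign(
        experiment_id="rep2",
        light_strain=MOCK_STRAIN,
        heavy_strain=TAGGED_STRAIN,
        reference_strain=MOCK_STRAIN,
    )
    return rep1, rep2


def mutant_design(
    genotype: str, experiment_id: str | None = None, swap: bool = False
) -> ExperimentDesign:
    """Wild-type-vs-mutant comparison; WT grown light unless ``swap``."""
    light, heavy = (genotype, WT_STRAIN) if swap else (WT_STRAIN, genotype)
    return ExperimentDesign(
        experiment_id=experiment_id or f"{genotype}_vs_WT",
        light_strain=light,
        heavy_strain=heavy,
        reference_strain=WT_STRAIN,
        genotype_flags={
            WT_STRAIN: genotype_flags(WT_STRAIN),
            genotype: genotype_flags(genotype),
        },
    )


def direct_design(
    numerator_genotype: str, denominator_genotype: str, experiment_id: str | None = None
) -> ExperimentDesign:
    """Direct mutant-vs-mutant comparison; denominator grown light."""
    return ExperimentDesign(
        experiment_id=experiment_id or f"{numerator_genotype}_vs_{denominator_genotype}",
        light_strain=denominator_genotype,
        heavy_strain=numerator_genotype,
        reference_strain=denominator_genotype,
        genotype_flags={
            denominator_genotype: genotype_flags(denominator_genotype),
            numerator_genotype: genotype_flags(numerator_genotype),
        },
    )


def default_designs() -> list[ExperimentDesign]:
    """Replicated target identification, all mutant profiles, one direct run."""
    designs = list(enrichment_replicates())
    designs += [mutant_design(g) for g in PROFILE_GENOTYPES]
    designs.append(direct_design("mms21-11", "siz1Δ siz2Δ"))
    return designs


def sample_clone_sizes(
    n: int, rng: np.random.Generator, cap: float | None = None
) -> np.ndarray:
    """Draw mutant-clone sizes from the Lea–Coulson law P(s = k) = 1/(k(k+1)).

    Inversion of the survival function P(s >= k) = 1/k: s = floor(1/U) with
    U ~ Uniform(0, 1].  ``cap`` truncates clones at the culture size.
    """
    u = 1.0 - rng.random(n)  # in (0, 1]
    sizes = np.floor(1.0 / u)
    if cap is not None:
        sizes = np.minimum(sizes, cap)
    return sizes


def simulate_fluctuation_assay(
    rate: float,
    cells_per_culture: float,
    n_cultures: int,
    seed: int,
    genotype: str = "",
    assay: str = "yel068c",
    truncate_at_nt: bool = True,
) -> MutantCounts:
    """Sample a Luria–Delbrück fluctuation assay.

    Per culture the number of mutation events is Poisson(m) with
    m = rate * cells_per_culture, and each event founds a clone whose size
    follows the Lea–Coulson 1/(k(k+1)) law truncated at the culture size.
    """
    if rate < 0:
        raise ParameterError("mutation rate must be non-negative")
    if cells_per_culture <= 0:
        raise ParameterError("cells_per_culture must be positive")
    if n_cultures < 1:
        raise ParameterError("need at least one culture")
    m = rate * cells_per_culture
    if m > 1e4:
        raise ParameterError(f"expected mutations per culture m={m} too large")
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    cap = cells_per_culture if truncate_at_nt else None
    for _ in range(n_cultures):
        n_events = int(rng.poisson(m))
        if n_events == 0:
            counts.append(0)
            continue
        total = float(sample_clone_sizes(n_events, rng, cap=cap).sum())
        if truncate_at_nt:
            total = min(total, cells_per_culture)
        counts.append(int(total))
    return MutantCounts(
        genotype=genotype,
        assay=assay,
        counts=tuple(counts),
        cells_per_culture=float(cells_per_culture),
    )
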