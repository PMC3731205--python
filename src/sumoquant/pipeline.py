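"""End-to-end runs: simulate → quantify → call targets → profile → classify.

Every stage writes its table under the configured output directory and the run
finishes with a manifest echoing the configuration and seed, so re-running the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import SumoQuantError
from .gcr import build_rate_table, estimate_rate, fold_increase, reproduce_table1
from .io import (
    RunConfig,
    config_manifest,
    write_designs,
    write_ground_truth,
    write_mutant_counts,
    write_profile_table,
    write_table,
)
from .profiles import (
    ClassifierThresholds,
    build_profiles,
    classify_profiles,
    ratio_of_ratios,
    validate_derived_vs_direct,
)
from .quant import orient_to_reference, peptide_ratio_table, protein_table
from .simulate import (
    PROFILE_GENOTYPES,
    generate_ground_truth,
    simulate_fluctuation_assay,
    simulate_silac_experiment,
)
from .targets import call_targets, replicate_concordance

logger = logging.getLogger(__name__)

# desk-scale GCR demonstration: wild type and the ligase-dead mms21 allele in
# both assay strains, simulated at the published rates; culture sizes chosen
# per strain so the expected mutations per culture stay in a countable range
_GCR_DEMO = (
    ("Wild type", "yel068c", 2.27e-9, 2e9),
    ("Wild type", "yel072w", 1.97e-8, 2e9),
    ("mms21-11", "yel068c", 1.06e-7, 5e7),
    ("mms21-11", "yel072w", 1.19e-5, 5e7),
)
_GCR_CULTURES = 24


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis described by ``config``.

    Returns a mapping of artifact names to written paths.  Any stage failure
    aborts the run with the stage name in the log record.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        truth = generate_ground_truth(config.generator)
        peptides = pd.concat(
            [simulate_silac_experiment(truth, d, config.generator) for d in config.designs],
            ignore_index=True,
        )
        artifacts["ground_truth"] = write_ground_truth(truth, out / "ground_truth.tsv")
        artifacts["designs"] = write_designs(config.designs, out / "designs.tsv")
        artifacts["peptides"] = write_table(peptides, out / "peptides.tsv")

        stage = "quantify"
        ratios = peptide_ratio_table(peptides, config.params)
        proteins = orient_to_reference(protein_table(ratios, config.params), config.designs)
        artifacts["protein_ratios"] = write_table(proteins, out / "protein_ratios.tsv")

        stage = "call-targets"
        by_exp = {e: g.reset_index(drop=True) for e, g in proteins.groupby("experiment_id")}
        reps = [d for d in config.designs if d.is_enrichment]
        if len(reps) < 2:
            raise SumoQuantError("need two tagged-vs-mock replicate designs")
        rep1, rep2 = by_exp[reps[0].experiment_id], by_exp[reps[1].experiment_id]
        targets = call_targets(rep1, rep2, config.params)
        artifacts["targets"] = write_table(targets, out / "targets.tsv")
        report = replicate_concordance(rep1, rep2)
        scatter = report.pairs.merge(
            targets[["protein_id", "called"]], on="protein_id", how="left"
        ).fillna({"called": False})
        artifacts["scatter"] = write_table(scatter, out / "scatter.tsv")

        stage = "profile"
        mutant_tables = {}
        for design in config.designs:
            if design.is_enrichment or design.reference_strain != "WT":
                continue
            genotype = design.non_reference_strain
            if genotype in PROFILE_GENOTYPES:
                mutant_tables[genotype] = by_exp[design.experiment_id]
        profiles = build_profiles(targets, mutant_tables)
        artifacts["profiles"] = write_profile_table(profiles, out / "profiles.tsv")

        stage = "classify"
        thresholds = ClassifierThresholds()
        calls = classify_profiles(profiles, thresholds).reset_index()
        artifacts["classification"] = write_table(
            calls,
            out / "classification.tsv",
            header_comment=(
                f"thresholds: strong_loss={thresholds.strong_loss} "
                f"unaffected_band=±{thresholds.unaffected_band} gain={thresholds.gain} (log2)"
            ),
        )

        stage = "ratio-of-ratios"
        direct_designs = [
            d
            for d in config.designs
            if not d.is_enrichment
            and d.reference_strain != "WT"
            and d.reference_strain in PROFILE_GENOTYPES
            and d.non_reference_strain in PROFILE_GENOTYPES
        ]
        for design in direct_designs:
            num, den = design.non_reference_strain, design.reference_strain
            derived = ratio_of_ratios(profiles, num, den)
            validation = validate_derived_vs_direct(derived, by_exp[design.experiment_id])
            slug = design.experiment_id.replace(" ", "_")
            artifacts[f"derived_vs_direct_{slug}"] = write_table(
                validation.table,
                out / f"derived_vs_direct_{slug}.tsv",
                header_comment=(
                    f"{num} vs {den}: concordant_fraction="
                    f"{validation.concordant_fraction:.4f} at ±{validation.tolerance_log2} log2"
                ),
            )

        if config.include_gcr:
            stage = "gcr"
            counts = [
                simulate_fluctuation_assay(
                    rate,
                    nt,
                    _GCR_CULTURES,
                    seed=(config.generator.seed * 131 + i) % 2**31,
                    genotype=genotype,
                    assay=assay,
                )
                for i, (genotype, assay, rate, nt) in enumerate(_GCR_DEMO)
            ]
            artifacts["gcr_counts"] = write_mutant_counts(counts, out / "gcr_counts.tsv")
            results = [estimate_rate(mc) for mc in counts]
            reference = next(
                r.rate for r in results if r.genotype == "Wild type" and r.assay == "yel068c"
            )
            estimates = pd.DataFrame(
                {
                    "genotype": [r.genotype for r in results],
                    "assay": [r.assay for r in results],
                    "rate": [r.rate for r in results],
                    "estimator": [r.estimator for r in results],
                    "fold_vs_reference": [fold_increase(r.rate, reference) for r in results],
                }
            )
            artifacts["gcr_estimates"] = write_table(estimates, out / "gcr_estimates.tsv")
            rates = {
                r.genotype: {q.assay: q.rate for q in results if q.genotype == r.genotype}
                for r in results
            }
            artifacts["gcr_table"] = write_table(
                build_rate_table(rates, reference), out / "gcr_table.tsv"
            )

        stage = "table1"
        table, report = reproduce_table1()
        artifacts["table1"] = write_table(table, out / "table1_recomputed.tsv")
        artifacts["table1_check"] = write_table(report, out / "table1_check.tsv")

        stage = "manifest"
        manifest = config_manifest(config, extra={"version": __version__})
        manifest_path = out / "manifest.json"
        manifest_path.write_text(manifest + "\n", encoding="utf-8")
        artifacts["manifest"] = manifest_path
    except SumoQuantError:
        logger.error("pipeline stage %r failed", stage)
        raise
    return artifacts
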