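"""TSV readers/writers and run configuration.

All tables are tab-separated with a header line; "NA" marks missing values.
Readers validate their schema (missing columns are named, bad values are
reported with their line number) so malformed inputs fail early and loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .quant import AnalysisParams, PROTEIN_COLUMNS
from .simulate import (
    DEP_KEYS,
    PEPTIDE_COLUMNS,
    ExperimentDesign,
    GeneratorConfig,
    GroundTruth,
    MutantCounts,
    default_designs,
    genotype_flags,
)

COUNTS_COLUMNS = ("genotype", "assay", "culture_id", "count", "cells_per_culture")

_NA = "NA"


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    params: AnalysisParams
    generator: GeneratorConfig
    designs: list[ExperimentDesign]
    output_dir: Path
    log_level: str = "INFO"
    include_gcr: bool = True

    def __post_init__(self):
        if not self.designs:
            raise ConfigError("run configuration contains no experiment designs")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide TSV, validating schema and intensity values."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"protein_id": str, "peptide": str, "experiment_id": str},
    )
    _require_columns(df, PEPTIDE_COLUMNS, path)
    for col in ("light_intensity", "heavy_intensity"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}:{line}: unparseable {col} {df[col][bad.idxmax()]!r}")
        negative = values < 0
        if negative.any():
            line = int(negative.idxmax()) + 2
            raise ValueError(f"{path}:{line}: negative {col} {values[negative.idxmax()]!r}")
        df[col] = values
    return df[list(PEPTIDE_COLUMNS)]


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> Path:
    """Write a TSV with optional leading ``#`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # %.17g keeps float round trips exact (read(write(x)) == x)
        df.to_csv(fh, sep="\t", index=False, na_rep=_NA, float_format="%.17g")
    return path


def read_protein_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    _require_columns(df, PROTEIN_COLUMNS, path)
    return df


def write_ground_truth(truth: Iterable[GroundTruth], path: str | Path) -> Path:
    rows = []
    for gt in truth:
        row = {
            "protein_id": gt.protein_id,
            "is_sumo_target": gt.is_sumo_target,
            "is_contaminant": gt.is_contaminant,
            "baseline_abundance": gt.baseline_abundance,
            "enrichment": gt.enrichment,
            "esc2_coupling": gt.esc2_coupling,
            "slx5_gain": gt.slx5_gain,
            "n_peptides": gt.n_peptides,
        }
        row.update({f"w_{k}": gt.dep_weights.get(k, 0.0) for k in DEP_KEYS})
        rows.append(row)
    return write_table(pd.DataFrame(rows), path)


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["protein_id", "is_sumo_target", "is_contaminant", "baseline_abundance",
                "enrichment", "esc2_coupling", "slx5_gain", "n_peptides"] + [f"w_{k}" for k in DEP_KEYS]
    _require_columns(df, required, path)
    return [
        GroundTruth(
            protein_id=str(r["protein_id"]),
            is_sumo_target=bool(r["is_sumo_target"]),
            is_contaminant=bool(r["is_contaminant"]),
            baseline_abundance=float(r["baseline_abundance"]),
            enrichment=float(r["enrichment"]),
            dep_weights={k: float(r[f"w_{k}"]) for k in DEP_KEYS},
            esc2_coupling=float(r["esc2_coupling"]),
            slx5_gain=float(r["slx5_gain"]),
            n_peptides=int(r["n_peptides"]),
        )
        for _, r in df.iterrows()
    ]


def write_designs(designs: Iterable[ExperimentDesign], path: str | Path) -> Path:
    rows = [
        {
            "experiment_id": d.experiment_id,
            "light_strain": d.light_strain,
            "heavy_strain": d.heavy_strain,
            "reference_strain": d.reference_strain,
        }
        for d in designs
    ]
    return write_table(pd.DataFrame(rows), path)


def _design_from_row(row: dict) -> ExperimentDesign:
    strains = (str(row["light_strain"]), str(row["heavy_strain"]))
    flags = {}
    if str(row["reference_strain"]) != "mock":
        flags = {s: genotype_flags(s) for s in strains}
    return ExperimentDesign(
        experiment_id=str(row["experiment_id"]),
        light_strain=strains[0],
        heavy_strain=strains[1],
        reference_strain=str(row["reference_strain"]),
        genotype_flags=flags,
    )


def read_designs(path: str | Path) -> list[ExperimentDesign]:
    """Read a design TSV; genotype flags are derived from strain labels."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["experiment_id", "light_strain", "heavy_strain", "reference_strain"], path)
    return [_design_from_row(r) for _, r in df.iterrows()]


def write_mutant_counts(assays: Iterable[MutantCounts], path: str | Path) -> Path:
    rows = []
    for mc in assays:
        for i, c in enumerate(mc.counts):
            rows.append(
                {
                    "genotype": mc.genotype,
                    "assay": mc.assay,
                    "culture_id": i,
                    "count": c,
                    "cells_per_culture": mc.cells_per_culture,
                }
            )
    return write_table(pd.DataFrame(rows, columns=list(COUNTS_COLUMNS)), path)


def read_mutant_counts(path: str | Path) -> list[MutantCounts]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, COUNTS_COLUMNS, path)
    out = []
    for (genotype, assay), grp in df.groupby(["genotype", "assay"], sort=True):
        out.append(
            MutantCounts(
                genotype=str(genotype),
                assay=str(assay),
                counts=tuple(int(c) for c in grp.sort_values("culture_id")["count"]),
                cells_per_culture=float(grp["cells_per_culture"].iloc[0]),
            )
        )
    return out


def write_profile_table(profiles: pd.DataFrame, path: str | Path,
                        header_comment: str | None = None) -> Path:
    return write_table(profiles.reset_index(), path, header_comment=header_comment)


def load_run_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML key-value file.

    ``designs`` may be the string ``"default"`` or a list of design mappings
    (experiment_id, light_strain, heavy_strain, reference_strain).  A seed is
    mandatory in the generator section; ``seed_override`` replaces it.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    gen = dict(raw.get("generator", {}))
    if seed_override is not None:
        gen["seed"] = int(seed_override)
    if "seed" not in gen:
        raise ConfigError(f"{path}: generator.seed is mandatory")
    try:
        generator = GeneratorConfig(**gen)
        params = AnalysisParams(**raw.get("params", {}))
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    designs_raw = raw.get("designs", "default")
    if designs_raw == "default":
        designs = default_designs()
    else:
        designs = [_design_from_row(d) for d in designs_raw]
    return RunConfig(
        params=params,
        generator=generator,
        designs=designs,
        output_dir=Path(raw.get("output_dir", "sumoquant_out")),
        log_level=str(raw.get("log_level", "INFO")),
        include_gcr=bool(raw.get("include_gcr", True)),
    )


def config_manifest(config: RunConfig, extra: dict | None = None) -> str:
    """Deterministic JSON echo of a run configuration."""
    payload = {
        "seed": config.generator.seed,
        "params": asdict(config.params),
        "generator": asdict(config.generator),
        "designs": [
            {
                "experiment_id": d.experiment_id,
                "light_strain": d.light_strain,
                "heavy_strain": d.heavy_strain,
                "reference_strain": d.reference_strain,
            }
            for d in config.designs
        ],
        "output_dir": str(config.output_dir),
        "log_level": config.log_level,
        "include_gcr": config.include_gcr,
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False)
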