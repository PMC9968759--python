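"""Configuration and tabular I/O: vial-count CSV, prediction/trajectory TSV,
estimation JSON, and the structured TOML run configuration."""

from __future__ import annotations

import csv
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

from .cross import CrossSpec, OffspringDistribution
from .genetics import (
    AlleleState,
    DriveArchitecture,
    DriveSystem,
    Genotype,
    RateParams,
    Sex,
    phenotype_markers,
)
from .inference import EstimationResult, VialCounts
from .popsim import TrajectorySummary

CSV_COLUMNS = [
    "cross_id",
    "vial_id",
    "drive_parent_sex",
    "eggs",
    "adults",
    "dsred_adults",
    "egfp_adults",
]

_SEX_CODES = {"female": Sex.FEMALE, "male": Sex.MALE, "none": None, "": None}


def read_vial_csv(path) -> list[VialCounts]:
    """Parse the canonical vial-count CSV.

    Blank marker cells are missing data (excluded from marker
    likelihoods), not zero counts. Malformed rows raise with their line
    number; adults > eggs is a hard error via the VialCounts invariant.
    """
    path = Path(path)
    vials: list[VialCounts] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            line = reader.line_num
            try:
                sex_raw = (row["drive_parent_sex"] or "").strip().lower()
                if sex_raw not in _SEX_CODES:
                    raise ValueError(f"bad drive_parent_sex {sex_raw!r}")
                def _count(col: str, optional: bool = False) -> int | None:
                    raw = (row[col] or "").strip()
                    if raw == "":
                        if optional:
                            return None
                        raise ValueError(f"missing {col}")
                    return int(raw)
                vials.append(
                    VialCounts(
                        cross_id=row["cross_id"].strip(),
                        vial_id=row["vial_id"].strip(),
                        drive_parent_sex=_SEX_CODES[sex_raw],
                        eggs=_count("eggs"),
                        adults=_count("adults"),
                        dsred_adults=_count("dsred_adults", optional=True),
                        egfp_adults=_count("egfp_adults", optional=True),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {line}: {exc}") from exc
    return vials


def write_vial_csv(path, vials: Sequence[VialCounts]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for v in vials:
            writer.writerow(
                [
                    v.cross_id,
                    v.vial_id,
                    v.drive_parent_sex.value if v.drive_parent_sex else "none",
                    v.eggs,
                    v.adults,
                    "" if v.dsred_adults is None else v.dsred_adults,
                    "" if v.egfp_adults is None else v.egfp_adults,
                ]
            )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    architecture: DriveArchitecture
    params: RateParams
    task: dict[str, Any] = field(default_factory=dict)


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")


def architecture_from_dict(d: dict) -> DriveArchitecture:
    allowed = {f.name for f in fields(DriveArchitecture)}
    _check_keys("architecture", d, allowed)
    if "system" not in d:
        raise ValueError("[architecture] requires a 'system' key")
    kw = dict(d)
    kw["system"] = DriveSystem(str(d["system"]).lower())
    return DriveArchitecture(**kw)


def params_from_dict(d: dict) -> RateParams:
    allowed = {f.name for f in fields(RateParams)}
    _check_keys("params", d, allowed)
    return RateParams(**d)


def genotype_from_dict(d: dict) -> Genotype:
    _check_keys("genotype", d, {"drive", "cas9", "target", "sex"})
    target = tuple(AlleleState[str(a).upper()] for a in d.get("target", ["wild_type", "wild_type"]))
    sex = None
    if d.get("sex"):
        sex = Sex(str(d["sex"]).lower())
    return Genotype(int(d.get("drive", 0)), int(d.get("cas9", 0)), target, sex)


def cross_from_dict(d: dict) -> CrossSpec:
    _check_keys("cross", d, {"id", "mother", "father"})
    mother = genotype_from_dict({**d["mother"], "sex": "female"})
    father = genotype_from_dict({**d["father"], "sex": "male"})
    return CrossSpec(mother=mother, father=father)


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Sections: ``[architecture]`` (drive system and rules), ``[params]``
    (rate parameters, probabilities validated on load), ``[task]``
    (subcommand options, passed through). Unknown keys are rejected.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    _check_keys("<root>", raw, {"architecture", "params", "task"})
    if "architecture" not in raw:
        raise ValueError(f"{path}: missing [architecture] section")
    arch = architecture_from_dict(raw["architecture"])
    params = params_from_dict(raw.get("params", {}))
    return RunConfig(architecture=arch, params=params, task=raw.get("task", {}))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _format_genotype(g: Genotype) -> str:
    alleles = "/".join(a.name.lower() for a in g.target)
    return f"drive={g.drive_copies};cas9={g.cas9_copies};target={alleles}"


def write_cross_report_tsv(path, dist: OffspringDistribution) -> None:
    """Tabular cross prediction: genotype, pre/post probabilities, markers."""
    genotypes = sorted(set(dist.pre_selection) | set(dist.post_selection))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genotype\tpre_prob\tpost_prob\tmarkers\n")
        for g in genotypes:
            markers = ",".join(sorted(phenotype_markers(g))) or "-"
            fh.write(
                f"{_format_genotype(g)}\t{dist.pre_selection.get(g, 0.0):.12g}\t"
                f"{dist.post_selection.get(g, 0.0):.12g}\t{markers}\n"
            )


def write_trajectory_tsv(path, traj: TrajectorySummary) -> None:
    cols = [
        "generation",
        "drive_allele_freq",
        "wild_type_allele_freq",
        "disrupted_allele_freq",
        "recoded_allele_freq",
        "genetic_load",
        "fertile_female_fraction",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, gen in enumerate(traj.generations):
            fh.write(
                "\t".join(
                    [
                        str(gen),
                        f"{traj.drive_allele_freq[i]:.10g}",
                        f"{traj.wild_type_allele_freq[i]:.10g}",
                        f"{traj.disrupted_allele_freq[i]:.10g}",
                        f"{traj.recoded_allele_freq[i]:.10g}",
                        f"{traj.genetic_load[i]:.10g}",
                        f"{traj.fertile_female_fraction[i]:.10g}",
                    ]
                )
                + "\n"
            )


def estimation_to_dict(result: EstimationResult) -> dict:
    return {
        "estimates": result.estimates,
        "confidence_intervals": {
            k: list(v) for k, v in result.confidence_intervals.items()
        },
        "log_likelihood": result.log_likelihood,
        "method": result.method,
        "converged": result.converged,
        "boundary_params": list(result.boundary_params),
        "message": result.message,
    }


def write_estimation_json(path, result: EstimationResult) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(estimation_to_dict(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
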