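"""Synthetic vial-structured cross count datasets with known ground truth.

Emulates the statistical structure of fly cross experiments: per-vial egg
counts, binomial egg-to-adult survival with a logit-normal vial (batch)
effect, and binomial fluorescence-marker counts among adults. The
logit-normal batch effect mirrors a binomial GLMM's random intercept; the
beta-binomial option in the inference module is its matched approximate
likelihood.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .cross import CrossSpec, offspring_distribution
from .genetics import DriveArchitecture, Genotype, RateParams, Sex
from .inference import VialCounts


@dataclass(frozen=True)
class EggDistribution:
    """Per-vial egg count law: fixed n, Poisson, or negative binomial."""

    kind: str  # "fixed" | "poisson" | "negative_binomial"
    mean: float = 50.0
    dispersion: float | None = None  # NB size parameter

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "poisson", "negative_binomial"):
            raise ValueError(f"unknown egg distribution kind: {self.kind!r}")
        if self.mean <= 0:
            raise ValueError("egg mean must be > 0")
        if self.kind == "negative_binomial" and (self.dispersion is None or self.dispersion <= 0):
            raise ValueError("negative_binomial requires a positive dispersion")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return int(round(self.mean))
        if self.kind == "poisson":
            return int(rng.poisson(self.mean))
        size = float(self.dispersion)
        p = size / (size + self.mean)
        return int(rng.negative_binomial(size, p))


@dataclass
class GenerationDesign:
    """Design of a synthetic dataset: crosses, vials, egg law, batch effect."""

    cross_specs: dict[str, CrossSpec]
    vials_per_cross: int = 10
    egg_distribution: EggDistribution = field(
        default_factory=lambda: EggDistribution("poisson", 50.0)
    )
    batch_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vials_per_cross < 1:
            raise ValueError("vials_per_cross must be >= 1")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")


def _drive_parent_sex(spec: CrossSpec) -> Sex | None:
    if spec.mother.drive_copies >= 1:
        return Sex.FEMALE
    if spec.father.drive_copies >= 1:
        return Sex.MALE
    return None


def _perturbed(p: float, sd: float, rng: np.random.Generator) -> float:
    """Logit-normal perturbation of a probability; degenerate p passes through."""
    if sd <= 0.0 or p <= 0.0 or p >= 1.0:
        return p
    return float(expit(logit(p) + rng.normal(0.0, sd)))


def generate_dataset(
    design: GenerationDesign,
    params: RateParams,
    arch: DriveArchitecture,
) -> list[VialCounts]:
    """Draw a reproducible vial-count dataset at known parameters."""
    rng = np.random.default_rng(design.seed)
    vials: list[VialCounts] = []
    for cross_id in sorted(design.cross_specs):
        spec = design.cross_specs[cross_id]
        od = offspring_distribution(spec, params, arch)
        sex = _drive_parent_sex(spec)
        for i in range(design.vials_per_cross):
            eggs = design.egg_distribution.sample(rng)
            p = _perturbed(od.absolute_viability, design.batch_sd, rng)
            adults = int(rng.binomial(eggs, p)) if eggs > 0 else 0
            if adults > 0 and od.inheritance_rate is not None:
                dsred = int(rng.binomial(adults, od.inheritance_rate))
                egfp = int(rng.binomial(adults, od.cas9_inheritance_rate))
            else:
                dsred = 0
                egfp = 0
            vials.append(
                VialCounts(
                    cross_id=cross_id,
                    vial_id=f"{cross_id}_v{i + 1}",
                    drive_parent_sex=sex,
                    eggs=eggs,
                    adults=adults,
                    dsred_adults=dsred,
                    egfp_adults=egfp,
                )
            )
    return vials


def _genotype_dict(g: Genotype) -> dict:
    return {
        "drive": g.drive_copies,
        "cas9": g.cas9_copies,
        "target": [a.name.lower() for a in g.target],
        "sex": g.sex.value if g.sex else None,
    }


def ground_truth_sidecar(
    design: GenerationDesign, params: RateParams, arch: DriveArchitecture
) -> dict:
    """JSON-serializable record of the generating design and parameters."""
    return {
        "params": asdict(params),
        "architecture": {
            "system": arch.system.value,
            "required_dosage": arch.required_dosage,
            "rescue_functional": arch.rescue_functional,
            "rescue_is_hdr_template": arch.rescue_is_hdr_template,
            "n_cut_sites": arch.n_cut_sites,
            "drive_disrupts_fertility_gene": arch.drive_disrupts_fertility_gene,
        },
        "design": {
            "vials_per_cross": design.vials_per_cross,
            "egg_distribution": asdict(design.egg_distribution),
            "batch_sd": design.batch_sd,
            "seed": design.seed,
            "crosses": {
                cid: {
                    "mother": _genotype_dict(s.mother),
                    "father": _genotype_dict(s.father),
                }
                for cid, s in sorted(design.cross_specs.items())
            },
        },
    }


def write_ground_truth(
    path, design: GenerationDesign, params: RateParams, arch: DriveArchitecture
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ground_truth_sidecar(design, params, arch), fh, indent=2, sort_keys=True)
        fh.write("\n")
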