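"""Deterministic enumeration of gamete and offspring distributions for one cross.

Composes per-parent germline gamete distributions, unites haplotypes into
diploid offspring, applies maternal-deposition cutting in the embryo, then
somatic and dosage viability selection. Yields expected drive inheritance
(DsRed fraction among survivors) and egg-to-adult viability.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import NamedTuple

from .genetics import (
    AlleleState,
    DriveArchitecture,
    Genotype,
    RateParams,
    Sex,
    germline_cutting_active,
    is_viable,
    maternal_deposition_active,
)

#: Tolerance for probability-mass bookkeeping.
PROB_TOL = 1e-12


class Haplotype(NamedTuple):
    """One transmitted gamete: drive copy, Cas9 copy, target allele."""

    drive: int
    cas9: int
    target: AlleleState


@dataclass(frozen=True)
class CrossSpec:
    """A mother x father pairing."""

    mother: Genotype
    father: Genotype

    def __post_init__(self) -> None:
        if self.mother.sex is not Sex.FEMALE:
            raise ValueError("mother must have sex=FEMALE")
        if self.father.sex is not Sex.MALE:
            raise ValueError("father must have sex=MALE")


@dataclass(frozen=True)
class OffspringDistribution:
    """Offspring genotype probabilities before and after selection.

    ``relative_viability`` is survival relative to an unaffected egg
    (dosage viability and somatic removal only); ``absolute_viability``
    additionally folds in the baseline egg-to-adult survival and the
    per-drive-copy fitness coefficient. ``inheritance_rate`` is the
    DsRed fraction among survivors, ``None`` (undefined, never 0/0)
    when no genotype survives.
    """

    pre_selection: dict[Genotype, float]
    post_selection: dict[Genotype, float]
    relative_viability: float
    absolute_viability: float
    inheritance_rate: float | None
    cas9_inheritance_rate: float | None


def _transmitted_allele_outcomes(
    allele: AlleleState, cutting: bool, params: RateParams, arch: DriveArchitecture
) -> dict[AlleleState, float]:
    """Fate of one transmitted target allele in the parental germline.

    A wild-type allele in an active (drive+Cas9) germline is modified with
    probability ``c_germline``; conditional on modification it is repaired
    to a functional recoded allele off the rescue element (if the
    architecture permits), back to wild type off the homolog, or left
    disrupted. Non-wild-type alleles transmit unchanged.
    """
    if not cutting or allele is not AlleleState.WILD_TYPE:
        return {allele: 1.0}
    c = params.c_germline
    p_r1 = params.p_hdr_functional if arch.rescue_is_hdr_template else 0.0
    p_wt = params.p_hdr_wt
    out: dict[AlleleState, float] = defaultdict(float)
    out[AlleleState.WILD_TYPE] += 1.0 - c + c * p_wt
    if p_r1 > 0.0:
        out[AlleleState.FUNCTIONAL_RECODED] += c * p_r1
    p_r2 = c * (1.0 - p_r1 - p_wt)
    if p_r2 > 0.0:
        out[AlleleState.DISRUPTED] += p_r2
    return {a: p for a, p in out.items() if p > 0.0}


def germline_gametes(
    parent: Genotype, params: RateParams, arch: DriveArchitecture
) -> dict[Haplotype, float]:
    """Gamete haplotype distribution of one parent.

    Drive and Cas9 segregate Mendelianly and independently of the target
    locus (three unlinked loci). Germline cutting applies per transmitted
    allele, which under independence is equivalent to cutting both alleles
    pre-meiotically and then segregating.
    """
    drive_probs = {1: parent.drive_copies / 2.0, 0: 1.0 - parent.drive_copies / 2.0}
    cas9_probs = {1: parent.cas9_copies / 2.0, 0: 1.0 - parent.cas9_copies / 2.0}
    cutting = germline_cutting_active(parent)

    target_probs: dict[AlleleState, float] = defaultdict(float)
    for allele in parent.target:  # each homolog transmitted with prob 1/2
        for state, p in _transmitted_allele_outcomes(allele, cutting, params, arch).items():
            target_probs[state] += 0.5 * p

    gametes: dict[Haplotype, float] = {}
    for d, pd in drive_probs.items():
        if pd == 0.0:
            continue
        for c, pc in cas9_probs.items():
            if pc == 0.0:
                continue
            for t, pt in target_probs.items():
                p = pd * pc * pt
                if p > 0.0:
                    gametes[Haplotype(d, c, t)] = gametes.get(Haplotype(d, c, t), 0.0) + p
    return gametes


def _embryo_cut_genotype(
    genotype: Genotype, c_embryo: float
) -> dict[Genotype, float]:
    """Outcomes of maternal-deposition cutting for one offspring genotype.

    Each wild-type target allele — maternally or paternally inherited —
    is independently disrupted with probability ``c_embryo``.
    """
    per_allele: list[list[tuple[AlleleState, float]]] = []
    for allele in genotype.target:
        if allele is AlleleState.WILD_TYPE and c_embryo > 0.0:
            outcomes = [(AlleleState.WILD_TYPE, 1.0 - c_embryo)]
            if c_embryo > 0.0:
                outcomes.append((AlleleState.DISRUPTED, c_embryo))
            per_allele.append([(s, p) for s, p in outcomes if p > 0.0])
        else:
            per_allele.append([(allele, 1.0)])
    result: dict[Genotype, float] = defaultdict(float)
    for a0, p0 in per_allele[0]:
        for a1, p1 in per_allele[1]:
            g = Genotype(genotype.drive_copies, genotype.cas9_copies, (a0, a1), genotype.sex)
            result[g] += p0 * p1
    return dict(result)


def _apply_embryo_cutting(
    distribution: dict[Genotype, float], c_embryo: float
) -> dict[Genotype, float]:
    if c_embryo <= 0.0:
        return dict(distribution)
    out: dict[Genotype, float] = defaultdict(float)
    for g, p in distribution.items():
        for g2, q in _embryo_cut_genotype(g, c_embryo).items():
            out[g2] += p * q
    return dict(out)


def apply_maternal_deposition(
    offspring_pre_embryo: dict[Genotype, float],
    mother: Genotype,
    params: RateParams,
) -> dict[Genotype, float]:
    """Redistribute genotype mass for embryo cutting by maternal Cas9/gRNA.

    Identity map unless the mother carries both drive and Cas9. Total
    probability mass is preserved (cutting moves mass between genotypes,
    it does not remove it — lethality is applied later by selection).
    """
    if not maternal_deposition_active(mother):
        return dict(offspring_pre_embryo)
    return _apply_embryo_cutting(offspring_pre_embryo, params.c_embryo)


def combine_gametes(
    maternal: dict[Haplotype, float], paternal: dict[Haplotype, float]
) -> dict[Genotype, float]:
    """Random union of gametes into diploid offspring genotypes."""
    offspring: dict[Genotype, float] = defaultdict(float)
    for hm, pm in maternal.items():
        for hf, pf in paternal.items():
            g = Genotype(hm.drive + hf.drive, hm.cas9 + hf.cas9, (hm.target, hf.target))
            offspring[g] += pm * pf
    return dict(offspring)


def somatic_removal_probability(
    genotype: Genotype, params: RateParams, arch: DriveArchitecture
) -> float:
    """Post-embryonic loss from leaky somatic Cas9 cutting of a haplolethal target."""
    if (
        arch.required_dosage == 2
        and genotype.drive_copies >= 1
        and genotype.cas9_copies >= 1
    ):
        return params.somatic_cut_rate
    return 0.0


def offspring_distribution(
    cross: CrossSpec, params: RateParams, arch: DriveArchitecture
) -> OffspringDistribution:
    """Full offspring genotype distribution and viability for a single cross."""
    maternal = germline_gametes(cross.mother, params, arch)
    paternal = germline_gametes(cross.father, params, arch)
    pre = combine_gametes(maternal, paternal)
    pre = apply_maternal_deposition(pre, cross.mother, params)

    relative = 0.0
    weights: dict[Genotype, float] = {}
    for g, p in pre.items():
        if not is_viable(g, arch):
            continue
        survive = 1.0 - somatic_removal_probability(g, params, arch)
        if survive <= 0.0:
            continue
        relative += p * survive
        w = p * survive * params.drive_fitness**g.drive_copies
        if w > 0.0:
            weights[g] = w

    total_w = sum(weights.values())
    absolute = params.baseline_viability * total_w
    if total_w > 0.0:
        post = {g: w / total_w for g, w in weights.items()}
        inheritance = sum(p for g, p in post.items() if g.drive_copies >= 1)
        cas9_inheritance = sum(p for g, p in post.items() if g.cas9_copies >= 1)
    else:
        post = {}
        inheritance = None
        cas9_inheritance = None

    return OffspringDistribution(
        pre_selection=pre,
        post_selection=post,
        relative_viability=relative,
        absolute_viability=absolute,
        inheritance_rate=inheritance,
        cas9_inheritance_rate=cas9_inheritance,
    )


def zero_survivor_bound(n_eggs: int, confidence: float = 0.95) -> float:
    """Lower confidence bound on the per-egg kill probability given 0 survivors.

    Exact (Clopper-Pearson-style) binomial inversion: with 0 survivors
    among ``n_eggs``, the one-sided upper bound on the per-egg survival
    probability p solves (1 - p)**n = 1 - confidence, so the kill-rate
    lower bound is ``(1 - confidence) ** (1 / n_eggs)``.
    """
    if n_eggs < 1:
        raise ValueError("n_eggs must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    return alpha ** (1.0 / n_eggs)
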