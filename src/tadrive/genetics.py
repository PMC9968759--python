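"""Genetic primitives for CRISPR toxin-antidote gene-drive systems.

A split toxin-antidote drive is modeled as three unlinked autosomal loci:

* the drive allele itself (gRNA cassette + recoded rescue element + DsRed
  marker), possibly inserted inside a female-fertility gene;
* a supporting Cas9 allele (EGFP marker);
* the essential target gene, whose alleles are wild-type, disrupted
  (nonfunctional resistance) or functionally recoded (functional
  resistance formed by homology-directed repair off the rescue element).

Viability is a dosage rule: an individual needs ``required_dosage``
functional doses of the target gene product, where a wild-type or
functionally recoded target allele contributes one dose and — if the
rescue element actually works — each drive copy contributes one dose.
Haplolethal targets require two doses (TADE), haplosufficient targets one
(TARE).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class AlleleState(enum.IntEnum):
    """State of one target-gene allele."""

    WILD_TYPE = 0
    DISRUPTED = 1
    FUNCTIONAL_RECODED = 2


#: Target-allele states that provide a functional dose of the gene product.
FUNCTIONAL_STATES = frozenset({AlleleState.WILD_TYPE, AlleleState.FUNCTIONAL_RECODED})


def allele_dosage(state: AlleleState) -> int:
    """Functional-dose contribution of a single target allele (0 or 1)."""
    return 1 if state in FUNCTIONAL_STATES else 0


def is_cleavable(state: AlleleState) -> bool:
    """Only wild-type alleles retain intact gRNA target sites."""
    return state is AlleleState.WILD_TYPE


class DriveSystem(enum.Enum):
    TADE_MODIFICATION = "tade_modification"
    TADE_SUPPRESSION = "tade_suppression"
    TARE = "tare"


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class DriveArchitecture:
    """Which toxin-antidote system is modeled and its viability/fertility rules.

    Parameters
    ----------
    system
        Toxin-antidote system class.
    rescue_functional
        Whether a drive allele contributes a functional target-gene dose.
        Rescue is all-or-nothing; partial rescue is not modeled.
    rescue_is_hdr_template
        Whether a minimally recoded rescue element can serve as template
        for homology-directed repair of a cut target allele, producing a
        functional recoded allele.
    n_cut_sites
        Number of gRNA cut sites in the target gene. Enters only through
        the embryo-resistance estimator; the cross model works with a
        single per-allele disruption probability.
    drive_disrupts_fertility_gene
        True only for TADE suppression, where the drive sits inside a
        haplosufficient female-fertility gene.
    required_dosage
        Functional doses needed for viability. Derived from ``system``
        when omitted: 2 for haplolethal TADE targets, 1 for the
        haplosufficient TARE target.
    """

    system: DriveSystem
    rescue_functional: bool
    rescue_is_hdr_template: bool = False
    n_cut_sites: int = 2
    drive_disrupts_fertility_gene: bool = False
    required_dosage: int | None = None

    def __post_init__(self) -> None:
        expected = 1 if self.system is DriveSystem.TARE else 2
        if self.required_dosage is None:
            object.__setattr__(self, "required_dosage", expected)
        elif self.required_dosage != expected:
            raise ValueError(
                f"required_dosage={self.required_dosage} inconsistent with "
                f"system={self.system.value} (expected {expected})"
            )
        if self.n_cut_sites < 1:
            raise ValueError("n_cut_sites must be >= 1")
        if self.drive_disrupts_fertility_gene and self.system is not DriveSystem.TADE_SUPPRESSION:
            raise ValueError("only a TADE suppression drive disrupts a fertility gene")
        if self.system is DriveSystem.TADE_SUPPRESSION and not self.drive_disrupts_fertility_gene:
            object.__setattr__(self, "drive_disrupts_fertility_gene", True)


@dataclass(frozen=True, order=True)
class Genotype:
    """Diploid genotype over the drive, Cas9 and target loci.

    ``target`` is an unordered pair of :class:`AlleleState`; it is stored
    canonically sorted so genotypes hash and compare by content. ``sex``
    only gates maternal deposition and female fertility; no locus is
    sex-linked, and population-level genotype maps leave it ``None``.
    """

    drive_copies: int
    cas9_copies: int
    target: tuple[AlleleState, AlleleState]
    sex: Sex | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("drive_copies", "cas9_copies"):
            v = getattr(self, name)
            if not 0 <= v <= 2:
                raise ValueError(f"{name} must be in [0, 2], got {v}")
        if len(self.target) != 2:
            raise ValueError("target must hold exactly two alleles (diploid)")
        target = tuple(sorted(AlleleState(a) for a in self.target))
        object.__setattr__(self, "target", target)


@dataclass(frozen=True)
class RateParams:
    """All cutting / repair / viability rate parameters of the model.

    ``c_germline`` is the per-transmitted-allele probability of
    cleavage-derived modification in a drive+Cas9 parent's germline;
    ``c_embryo`` the per-wild-type-allele cleavage probability in the
    embryo from maternal Cas9/gRNA deposition. Germline cuts resolve to
    a functional recoded allele with probability ``p_hdr_functional``
    (only meaningful when the architecture allows the rescue element as
    HDR template), back to wild type with probability ``p_hdr_wt``
    (homolog-templated repair; confounded with a lower ``c_germline``),
    and to a disrupted allele otherwise. ``somatic_cut_rate`` is the
    probability that leaky somatic Cas9 activity removes a carrier of a
    haplolethal target post-embryonically. ``drive_fitness`` is a
    multiplicative viability/fecundity coefficient per drive copy.
    """

    c_germline: float = 0.0
    c_embryo: float = 0.0
    p_hdr_functional: float = 0.0
    p_hdr_wt: float = 0.0
    baseline_viability: float = 1.0
    somatic_cut_rate: float = 0.0
    drive_fitness: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "c_germline",
            "c_embryo",
            "p_hdr_functional",
            "p_hdr_wt",
            "baseline_viability",
            "somatic_cut_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.p_hdr_functional + self.p_hdr_wt > 1.0 + 1e-12:
            raise ValueError("p_hdr_functional + p_hdr_wt must be <= 1")
        if self.drive_fitness < 0.0:
            raise ValueError("drive_fitness must be >= 0")


def germline_cutting_active(parent: Genotype) -> bool:
    """Germline cleavage requires the parent to carry both drive and Cas9."""
    return parent.drive_copies >= 1 and parent.cas9_copies >= 1


def maternal_deposition_active(mother: Genotype) -> bool:
    """Embryo cleavage requires maternal co-deposition of Cas9 and gRNA."""
    return mother.drive_copies >= 1 and mother.cas9_copies >= 1


def functional_dosage(genotype: Genotype, arch: DriveArchitecture) -> int:
    """Total functional target-gene doses carried by a genotype.

    Functional target alleles each contribute one dose; each drive copy
    contributes one dose iff the rescue element is functional. There is
    no upper cap: drive homozygotes with functional rescue contribute two
    doses without an over-expression penalty.
    """
    dose = sum(allele_dosage(a) for a in genotype.target)
    if arch.rescue_functional:
        dose += genotype.drive_copies
    return dose


def is_viable(genotype: Genotype, arch: DriveArchitecture) -> bool:
    """Dosage viability rule: survive iff dosage >= required_dosage."""
    return functional_dosage(genotype, arch) >= arch.required_dosage


def is_fertile_female(genotype: Genotype, arch: DriveArchitecture) -> bool:
    """Fertility of a female genotype.

    For a suppression drive inserted in a haplosufficient female-fertility
    gene, only drive homozygotes are sterile. Raises ``ValueError`` for a
    male genotype.
    """
    if genotype.sex is not Sex.FEMALE:
        raise ValueError("is_fertile_female requires a FEMALE genotype")
    if arch.drive_disrupts_fertility_gene:
        return genotype.drive_copies < 2
    return True


def phenotype_markers(genotype: Genotype) -> frozenset[str]:
    """Dominant fluorescence markers: DsRed tags the drive, EGFP tags Cas9."""
    markers = set()
    if genotype.drive_copies >= 1:
        markers.add("DsRed")
    if genotype.cas9_copies >= 1:
        markers.add("EGFP")
    return frozenset(markers)


def wild_type_genotype(sex: Sex | None = None) -> Genotype:
    """Convenience constructor for an unmodified fly."""
    return Genotype(0, 0, (AlleleState.WILD_TYPE, AlleleState.WILD_TYPE), sex)
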