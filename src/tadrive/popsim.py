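"""Discrete-generation forward simulation of toxin-antidote drive dynamics.

Panmictic population, nonoverlapping generations, 1:1 sex ratio with
genotype frequencies pooled across sexes at birth. Each generation:
sterile females are removed from the mother pool, per-genotype germline
gamete pools are formed, gametes unite at random with maternal-deposition
cutting resolved against the mother's genotype class, then dosage
viability / somatic / fitness selection and renormalization. Stochastic
mode adds multinomial resampling to a fixed population size.

Suppression is summarized as genetic load (1 - mean relative
fecundity x viability); no density dependence is modeled.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cross import Haplotype, combine_gametes, germline_gametes, _apply_embryo_cutting
from .genetics import (
    AlleleState,
    DriveArchitecture,
    Genotype,
    RateParams,
    Sex,
    is_fertile_female,
    is_viable,
    maternal_deposition_active,
    wild_type_genotype,
)
from .cross import somatic_removal_probability

FREQ_TOL = 1e-9


@dataclass
class PopulationState:
    """Genotype-frequency state of the population at one generation."""

    generation: int
    genotype_frequencies: dict[Genotype, float]
    population_size: int | None = None  # None = deterministic / unbounded
    extinct: bool = False

    def normalized(self) -> "PopulationState":
        total = sum(self.genotype_frequencies.values())
        if total <= 0.0:
            raise ValueError("cannot normalize an empty state")
        freqs = {g: f / total for g, f in self.genotype_frequencies.items() if f > 0.0}
        return replace(self, genotype_frequencies=freqs)


@dataclass
class TrajectorySummary:
    """Per-generation series from a forward run."""

    generations: list[int] = field(default_factory=list)
    drive_allele_freq: list[float] = field(default_factory=list)
    disrupted_allele_freq: list[float] = field(default_factory=list)
    recoded_allele_freq: list[float] = field(default_factory=list)
    wild_type_allele_freq: list[float] = field(default_factory=list)
    genetic_load: list[float] = field(default_factory=list)
    fertile_female_fraction: list[float] = field(default_factory=list)
    extinct: bool = False
    extinct_generation: int | None = None


def allele_frequencies(freqs: Mapping[Genotype, float]) -> dict[str, float]:
    """Drive and target-locus allele frequencies of a genotype map."""
    drive = sum(f * g.drive_copies for g, f in freqs.items()) / 2.0
    target = {s: 0.0 for s in AlleleState}
    for g, f in freqs.items():
        for a in g.target:
            target[a] += f / 2.0
    return {
        "drive": drive,
        "wild_type": target[AlleleState.WILD_TYPE],
        "disrupted": target[AlleleState.DISRUPTED],
        "recoded": target[AlleleState.FUNCTIONAL_RECODED],
    }


def _female(g: Genotype) -> Genotype:
    return replace(g, sex=Sex.FEMALE)


def _pooled_gametes(
    weighted: Mapping[Genotype, float], params: RateParams, arch: DriveArchitecture
) -> dict[Haplotype, float]:
    total = sum(weighted.values())
    pool: dict[Haplotype, float] = defaultdict(float)
    for g, w in weighted.items():
        for h, p in germline_gametes(g, params, arch).items():
            pool[h] += (w / total) * p
    return dict(pool)


def _advance(
    state: PopulationState, params: RateParams, arch: DriveArchitecture
) -> tuple[dict[Genotype, float] | None, dict[str, float]]:
    """One generation of the deterministic recursion.

    Returns the next genotype-frequency map (None on extinction) plus
    diagnostics of the current state's reproductive output.
    """
    freqs = state.genotype_frequencies

    mothers: dict[Genotype, float] = {}
    for g, f in freqs.items():
        if is_fertile_female(_female(g), arch):
            mothers[g] = f
    fertile_fraction = sum(mothers.values())
    diag = {"fertile_female_fraction": fertile_fraction, "mean_offspring_viability": 0.0}
    if fertile_fraction <= 0.0:
        diag["genetic_load"] = 1.0
        return None, diag

    # Maternal deposition depends only on whether the mother carries both
    # drive and Cas9, so mothers pool into two classes.
    active = {g: w for g, w in mothers.items() if maternal_deposition_active(g)}
    inactive = {g: w for g, w in mothers.items() if not maternal_deposition_active(g)}
    paternal = _pooled_gametes(freqs, params, arch)

    offspring: dict[Genotype, float] = defaultdict(float)
    for cls, deposits in ((active, True), (inactive, False)):
        mass = sum(cls.values())
        if mass <= 0.0:
            continue
        share = mass / fertile_fraction
        dist = combine_gametes(_pooled_gametes(cls, params, arch), paternal)
        if deposits:
            dist = _apply_embryo_cutting(dist, params.c_embryo)
        for g, p in dist.items():
            offspring[g] += share * p

    survivors: dict[Genotype, float] = {}
    mean_viability = 0.0
    for g, p in offspring.items():
        if not is_viable(g, arch):
            continue
        w = p * (1.0 - somatic_removal_probability(g, params, arch))
        w *= params.drive_fitness**g.drive_copies
        if w > 0.0:
            survivors[g] = w
            mean_viability += w
    diag["mean_offspring_viability"] = mean_viability
    diag["genetic_load"] = min(1.0, max(0.0, 1.0 - fertile_fraction * mean_viability))
    if mean_viability <= 0.0:
        return None, diag
    return {g: w / mean_viability for g, w in survivors.items()}, diag


def step(
    state: PopulationState,
    params: RateParams,
    arch: DriveArchitecture,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Advance one nonoverlapping generation.

    Stochastic mode (``state.population_size`` set) multinomially
    resamples the next generation; pass a seeded ``rng``.
    """
    if state.extinct:
        return state
    next_freqs, _ = _advance(state.normalized(), params, arch)
    if next_freqs is None:
        return replace(state, generation=state.generation + 1, extinct=True)
    if state.population_size is not None:
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        genotypes = sorted(next_freqs)
        probs = np.array([next_freqs[g] for g in genotypes])
        counts = rng.multinomial(state.population_size, probs / probs.sum())
        next_freqs = {
            g: c / state.population_size for g, c in zip(genotypes, counts) if c > 0
        }
        if not next_freqs:
            return replace(state, generation=state.generation + 1, extinct=True)
    return replace(
        state, generation=state.generation + 1, genotype_frequencies=next_freqs
    )


def default_release_genotype() -> Genotype:
    """Release cohort default: drive homozygote carrying homozygous Cas9."""
    return Genotype(2, 2, (AlleleState.WILD_TYPE, AlleleState.WILD_TYPE))


def initial_state(
    initial_release: float,
    release_genotype: Genotype | None = None,
    population_size: int | None = None,
    background_genotype: Genotype | None = None,
) -> PopulationState:
    """Population of ``background_genotype`` (default wild type) with a
    release cohort at the given genotype frequency."""
    if not 0.0 <= initial_release <= 1.0:
        raise ValueError("initial_release must be in [0, 1]")
    release = release_genotype if release_genotype is not None else default_release_genotype()
    background = background_genotype if background_genotype is not None else wild_type_genotype()
    freqs: dict[Genotype, float] = {}
    if initial_release < 1.0:
        freqs[replace(background, sex=None)] = 1.0 - initial_release
    if initial_release > 0.0:
        freqs[replace(release, sex=None)] = (
            freqs.get(replace(release, sex=None), 0.0) + initial_release
        )
    return PopulationState(0, freqs, population_size=population_size)


def run_trajectory(
    initial_release: float,
    generations: int,
    params: RateParams,
    arch: DriveArchitecture,
    mode: str = "deterministic",
    seed: int | None = None,
    population_size: int | None = None,
    release_genotype: Genotype | None = None,
    background_genotype: Genotype | None = None,
) -> TrajectorySummary:
    """Iterate ``step`` and record per-generation allele series and load."""
    if mode not in ("deterministic", "stochastic"):
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    rng = None
    if mode == "stochastic":
        if population_size is None:
            raise ValueError("stochastic mode requires population_size")
        rng = np.random.default_rng(seed)
    else:
        population_size = None

    state = initial_state(
        initial_release, release_genotype, population_size, background_genotype
    )
    summary = TrajectorySummary()
    for _ in range(generations + 1):
        freqs = state.genotype_frequencies
        af = allele_frequencies(freqs)
        _, diag = _advance(state, params, arch)
        summary.generations.append(state.generation)
        summary.drive_allele_freq.append(af["drive"])
        summary.disrupted_allele_freq.append(af["disrupted"])
        summary.recoded_allele_freq.append(af["recoded"])
        summary.wild_type_allele_freq.append(af["wild_type"])
        summary.genetic_load.append(diag["genetic_load"])
        summary.fertile_female_fraction.append(diag["fertile_female_fraction"])
        if state.generation >= generations:
            break
        state = step(state, params, arch, rng)
        if state.extinct:
            summary.extinct = True
            summary.extinct_generation = state.generation
            break
    return summary


def find_introduction_threshold(
    params: RateParams,
    arch: DriveArchitecture,
    generations: int = 100,
    tol: float = 1e-3,
    release_genotype: Genotype | None = None,
    background_genotype: Genotype | None = None,
) -> float | None:
    """Bisect the release frequency separating drive spread from loss.

    Deterministic mode. A release spreads if the drive allele frequency at
    the horizon exceeds its initial value (population extinction by the
    drive also counts as spread). Because a costly drive equilibrates at
    an interior frequency, the upper bracket is found by scanning a
    release grid rather than probing near fixation. Returns ``None`` when
    no positive release spreads, ``0.0`` when every positive release does.
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")

    def spreads(release: float) -> bool:
        traj = run_trajectory(
            release, generations, params, arch,
            mode="deterministic", release_genotype=release_genotype,
            background_genotype=background_genotype,
        )
        if traj.extinct:
            return True
        return traj.drive_allele_freq[-1] > traj.drive_allele_freq[0] + 1e-9

    lo = min(tol, 1e-3)
    if spreads(lo):
        return 0.0
    hi = None
    for candidate in [0.05 * k for k in range(1, 20)]:
        if candidate > lo and spreads(candidate):
            hi = candidate
            break
    if hi is None:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spreads(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
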