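"""Shared helpers and independent oracles for the test suite.

Oracles here deliberately re-derive expectations by brute force
(enumeration, bisection, Monte Carlo) without calling the code paths they
check.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from math import comb

import numpy as np

from tadrive.genetics import (
    AlleleState,
    DriveArchitecture,
    Genotype,
    RateParams,
    Sex,
)

WT = AlleleState.WILD_TYPE
R2 = AlleleState.DISRUPTED
R1 = AlleleState.FUNCTIONAL_RECODED
WT_PAIR = (WT, WT)


def geno(drive=0, cas9=0, target=WT_PAIR, sex=None):
    return Genotype(drive, cas9, tuple(target), sex)


def female(drive=0, cas9=0, target=WT_PAIR):
    return geno(drive, cas9, target, Sex.FEMALE)


def male(drive=0, cas9=0, target=WT_PAIR):
    return geno(drive, cas9, target, Sex.MALE)


# ---------------------------------------------------------------------------
# Exact-test oracles: exhaustive enumeration
# ---------------------------------------------------------------------------

def binomial_two_sided_enum(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by full outcome enumeration."""
    if n == 0:
        return 1.0
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    # minimum-likelihood convention with a small relative tie tolerance
    cut = pmf[k] * (1 + 1e-7)
    return min(1.0, sum(q for q in pmf if q <= cut))


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    def pr(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = pr(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pr(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Monte-Carlo cross oracle (vectorized, independent of tadrive.cross)
# ---------------------------------------------------------------------------

def sample_cross(rng, mother: Genotype, father: Genotype, params: RateParams,
                 arch: DriveArchitecture, n: int):
    """Simulate n offspring of one cross: gamete draws, germline cutting,
    maternal deposition. Returns pre-selection genotype arrays
    (drive, cas9, sorted allele codes) and a viability mask."""

    def gamete(parent: Genotype):
        d = (rng.random(n) < parent.drive_copies / 2).astype(np.int64)
        c = (rng.random(n) < parent.cas9_copies / 2).astype(np.int64)
        pick = rng.integers(0, 2, n)
        al = np.where(pick == 0, int(parent.target[0]), int(parent.target[1]))
        if parent.drive_copies >= 1 and parent.cas9_copies >= 1:
            cut = (al == int(WT)) & (rng.random(n) < params.c_germline)
            u = rng.random(n)
            p_r1 = params.p_hdr_functional if arch.rescue_is_hdr_template else 0.0
            to_r1 = cut & (u < p_r1)
            to_wt = cut & (u >= p_r1) & (u < p_r1 + params.p_hdr_wt)
            to_r2 = cut & ~to_r1 & ~to_wt
            al = np.where(to_r1, int(R1), al)
            al = np.where(to_r2, int(R2), al)
        return d, c, al

    dm, cm, am = gamete(mother)
    df_, cf, af = gamete(father)
    drive = dm + df_
    cas9 = cm + cf
    if mother.drive_copies >= 1 and mother.cas9_copies >= 1:
        am = np.where((am == int(WT)) & (rng.random(n) < params.c_embryo), int(R2), am)
        af = np.where((af == int(WT)) & (rng.random(n) < params.c_embryo), int(R2), af)
    a_lo = np.minimum(am, af)
    a_hi = np.maximum(am, af)

    functional = np.isin(a_lo, [int(WT), int(R1)]).astype(np.int64) + np.isin(
        a_hi, [int(WT), int(R1)]
    ).astype(np.int64)
    dose = functional + (drive if arch.rescue_functional else 0)
    alive = dose >= arch.required_dosage
    if params.somatic_cut_rate > 0 and arch.required_dosage == 2:
        exposed = (drive >= 1) & (cas9 >= 1)
        alive = alive & ~(exposed & (rng.random(n) < params.somatic_cut_rate))
    return drive, cas9, a_lo, a_hi, alive


def empirical_genotype_freqs(drive, cas9, a_lo, a_hi):
    keys = defaultdict(int)
    for row in zip(drive.tolist(), cas9.tolist(), a_lo.tolist(), a_hi.tolist()):
        keys[row] += 1
    n = len(drive)
    return {k: v / n for k, v in keys.items()}


def genotype_key(g: Genotype):
    return (g.drive_copies, g.cas9_copies, int(g.target[0]), int(g.target[1]))


# ---------------------------------------------------------------------------
# Population-step oracle: explicit mother x father pairing
# ---------------------------------------------------------------------------

def brute_population_step(freqs, params, arch):
    """One deterministic generation, pairing every mother genotype with
    every father genotype explicitly before deposition."""
    from tadrive.cross import (
        _apply_embryo_cutting,
        combine_gametes,
        germline_gametes,
        somatic_removal_probability,
    )
    from tadrive.genetics import is_fertile_female, is_viable, maternal_deposition_active

    mothers = {
        g: f
        for g, f in freqs.items()
        if is_fertile_female(replace(g, sex=Sex.FEMALE), arch)
    }
    mm = sum(mothers.values())
    if mm <= 0:
        return None
    off = defaultdict(float)
    for gm, wm in mothers.items():
        gam_m = germline_gametes(gm, params, arch)
        for gf, wf in freqs.items():
            dist = combine_gametes(gam_m, germline_gametes(gf, params, arch))
            if maternal_deposition_active(gm):
                dist = _apply_embryo_cutting(dist, params.c_embryo)
            for g, p in dist.items():
                off[g] += (wm / mm) * wf * p
    surv = {}
    tot = 0.0
    for g, p in off.items():
        if not is_viable(g, arch):
            continue
        w = p * (1 - somatic_removal_probability(g, params, arch))
        w *= params.drive_fitness**g.drive_copies
        if w > 0:
            surv[g] = w
            tot += w
    if tot <= 0:
        return None
    return {g: w / tot for g, w in surv.items()}
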