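"""Estimate cutting/repair rates from observed vial counts.

Closed-form estimators reproduce the back-of-envelope arithmetic on pooled
egg viabilities; ``fit_ml`` maximizes a binomial (or beta-binomial, for
vial-level overdispersion) likelihood with the cross model supplying the
expected viability and inheritance for each cross. Exact Fisher and
binomial tests are provided for the paper-style marker comparisons.

Conventions: all closed-form estimators are exact inverses of the forward
cross model. The beta-binomial dispersion parameter substitutes for a
per-vial random intercept; it approximates — not reproduces — a binomial
GLMM. Two-sided exact tests use the minimum-likelihood method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .cross import CrossSpec, offspring_distribution
from .genetics import DriveArchitecture, RateParams, Sex

#: Parameters that fit_ml may treat as free.
FREE_PARAM_NAMES = ("c_germline", "c_embryo", "p_hdr_functional", "baseline_viability")

_CHI2_95_1DF = 3.841458820694124  # chi2.ppf(0.95, 1)


@dataclass(frozen=True)
class VialCounts:
    """Observable counts for one vial of one cross."""

    cross_id: str
    vial_id: str
    drive_parent_sex: Sex | None
    eggs: int
    adults: int
    dsred_adults: int | None = None
    egfp_adults: int | None = None

    def __post_init__(self) -> None:
        if self.eggs < 0 or self.adults < 0:
            raise ValueError("counts must be nonnegative")
        if self.adults > self.eggs:
            raise ValueError(
                f"vial {self.vial_id!r} of cross {self.cross_id!r}: "
                f"adults ({self.adults}) exceed eggs ({self.eggs})"
            )
        for name in ("dsred_adults", "egfp_adults"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= self.adults:
                raise ValueError(
                    f"vial {self.vial_id!r}: {name}={v} outside [0, adults={self.adults}]"
                )


@dataclass(frozen=True)
class EstimationResult:
    """Point estimates, profile 95% intervals and achieved log-likelihood."""

    estimates: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]
    log_likelihood: float
    method: str  # CLOSED_FORM | ML_BINOMIAL | ML_BETABINOMIAL
    converged: bool = True
    boundary_params: tuple[str, ...] = ()
    message: str = ""


# ---------------------------------------------------------------------------
# Closed-form estimators on pooled viabilities
# ---------------------------------------------------------------------------

def estimate_germline_rate(v_drive_male: float, v_control: float) -> float:
    """Per-allele germline cut rate from male drive-cross vs control viability.

    Male drive parents deposit no Cas9 into the embryo, so under the
    any-cut-lethal haplolethal model the only excess lethality is germline
    disruption of the single transmitted target allele:
    ``c_g = 1 - v_male / v_control``.
    """
    if v_control <= 0.0:
        raise ValueError("control viability must be positive")
    if not 0.0 <= v_drive_male <= 1.0 or v_control > 1.0:
        raise ValueError("viabilities must be proportions in [0, 1]")
    if v_drive_male > v_control:
        warnings.warn(
            "male drive-cross viability exceeds control; clamping estimate to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - v_drive_male / v_control


def estimate_embryo_rate(
    v_drive_female: float, v_control: float, c_germline: float
) -> float:
    """Per-allele embryo cut rate from female drive-cross viability.

    Both wild-type target alleles of an embryo are exposed to maternally
    deposited Cas9/gRNA, so survival of the non-germline-cut fraction is
    ``(1 - c_e)**2``:  ``c_e = 1 - sqrt(v_female / (v_control * (1 - c_g)))``.
    """
    for name, v in (("v_drive_female", v_drive_female), ("v_control", v_control),
                    ("c_germline", c_germline)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = v_control * (1.0 - c_germline)
    if denom <= 0.0:
        raise ValueError("v_control * (1 - c_germline) must be positive")
    ratio = v_drive_female / denom
    if ratio > 1.0:
        warnings.warn(
            "female drive-cross viability above expectation; clamping estimate to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - math.sqrt(ratio)


def estimate_embryo_resistance_rate(
    v_drive_female: float, v_control: float, n_cut_sites: int = 1
) -> float:
    """Per-site embryo resistance-allele formation rate.

    Under the rule that a single resistance allele renders the egg
    non-viable, the lethal fraction is ``1 - (1 - r)**n_cut_sites``;
    solving against the observed viability deficit gives
    ``r = 1 - (v_female / v_control) ** (1 / n_cut_sites)``.
    """
    if n_cut_sites < 1:
        raise ValueError("n_cut_sites must be >= 1")
    if v_control <= 0.0:
        raise ValueError("control viability must be positive")
    ratio = v_drive_female / v_control
    if ratio > 1.0:
        warnings.warn(
            "female drive-cross viability above control; clamping estimate to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - ratio ** (1.0 / n_cut_sites)


# ---------------------------------------------------------------------------
# Maximum likelihood on vial counts
# ---------------------------------------------------------------------------

def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    p = min(max(p, 1e-300), 1.0 - 1e-16)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


def _betabinom_logpmf(k: np.ndarray, n: np.ndarray, p: float, rho: float) -> np.ndarray:
    # mean p, intra-vial correlation rho
    nu = 1.0 / rho - 1.0
    a = max(p * nu, 1e-12)
    b = max((1.0 - p) * nu, 1e-12)
    return stats.betabinom.logpmf(k, n, a, b)


class _Likelihood:
    """Binomial/beta-binomial log-likelihood of vial counts given rate params."""

    def __init__(
        self,
        dataset: Sequence[VialCounts],
        cross_specs: Mapping[str, CrossSpec],
        arch: DriveArchitecture,
        names: Sequence[str],
        base: RateParams,
        overdispersion: bool,
    ):
        self.names = list(names)
        self.base = base
        self.arch = arch
        self.overdispersion = overdispersion
        self.cross_specs = dict(cross_specs)
        missing = {v.cross_id for v in dataset} - set(cross_specs)
        if missing:
            raise ValueError(f"dataset references crosses without a spec: {sorted(missing)}")
        self.groups: dict[str, dict[str, np.ndarray]] = {}
        for cid in sorted({v.cross_id for v in dataset}):
            vials = [v for v in dataset if v.cross_id == cid]
            marked = [v for v in vials if v.dsred_adults is not None]
            self.groups[cid] = {
                "eggs": np.array([v.eggs for v in vials], dtype=float),
                "adults": np.array([v.adults for v in vials], dtype=float),
                "marker_n": np.array([v.adults for v in marked], dtype=float),
                "marker_k": np.array([v.dsred_adults for v in marked], dtype=float),
            }

    def params_at(self, theta: Sequence[float]) -> RateParams:
        kw = {n: float(v) for n, v in zip(self.names, theta) if n != "rho"}
        return replace(self.base, **kw)

    def __call__(self, theta: Sequence[float]) -> float:
        rho = float(theta[self.names.index("rho")]) if self.overdispersion else 0.0
        try:
            params = self.params_at(theta)
        except ValueError:
            return -np.inf
        ll = 0.0
        for cid, d in self.groups.items():
            od = offspring_distribution(self.cross_specs[cid], params, self.arch)
            v = od.absolute_viability
            if self.overdispersion and rho > 1e-9:
                ll += float(_betabinom_logpmf(d["adults"], d["eggs"], v, rho).sum())
            else:
                ll += float(_binom_logpmf(d["adults"], d["eggs"], v).sum())
            if od.inheritance_rate is not None and d["marker_n"].size:
                ll += float(
                    _binom_logpmf(d["marker_k"], d["marker_n"], od.inheritance_rate).sum()
                )
        if not np.isfinite(ll):
            return -np.inf
        return ll


def fit_ml(
    dataset: Sequence[VialCounts],
    cross_specs: Mapping[str, CrossSpec],
    arch: DriveArchitecture,
    free_params: Iterable[str],
    base_params: RateParams | None = None,
    overdispersion: bool = False,
    compute_ci: bool = True,
    ci_level: float = 0.95,
) -> EstimationResult:
    """Maximum-likelihood fit of rate parameters to vial counts.

    Adult counts contribute ``Binomial(adults | eggs, absolute_viability)``
    (beta-binomial with dispersion ``rho`` when ``overdispersion=True``);
    DsRed counts contribute ``Binomial(dsred_adults | adults,
    inheritance_rate)``. Both expectations are recomputed per cross from
    the forward cross model at each parameter vector. Confidence
    intervals are profile-likelihood (chi-square, 1 df).
    """
    base = base_params if base_params is not None else RateParams()
    requested = list(free_params)
    unknown = set(requested) - set(FREE_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    names = [n for n in FREE_PARAM_NAMES if n in requested]
    if not names:
        raise ValueError("at least one free parameter is required")
    if overdispersion:
        names.append("rho")

    lik = _Likelihood(dataset, cross_specs, arch, names, base, overdispersion)

    lo, hi = 1e-9, 1.0 - 1e-9
    bounds = []
    x0 = []
    for n in names:
        if n == "rho":
            bounds.append((lo, 0.99))
            x0.append(0.02)
        else:
            bounds.append((lo, hi))
            start = getattr(base, n)
            if start <= lo or start >= hi:
                start = 0.1 if n != "baseline_viability" else 0.8
            x0.append(start)

    neg = lambda th: -lik(th)
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
    )
    # Nelder-Mead polish for tight oracle equivalence near the optimum.
    polish = optimize.minimize(
        neg, res.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    best = polish if polish.fun <= res.fun else res
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    ll_max = lik(theta)
    converged = bool((res.success or polish.success) and np.isfinite(ll_max))

    estimates = {n: float(v) for n, v in zip(names, theta)}
    boundary = tuple(
        n for n, v, (blo, bhi) in zip(names, theta, bounds)
        if v <= blo * 10 or v >= 1.0 - (1.0 - bhi) * 10 - 1e-7
    )

    cis: dict[str, tuple[float, float]] = {}
    if compute_ci:
        crit = 0.5 * stats.chi2.ppf(ci_level, 1)
        target = ll_max - crit
        for i, n in enumerate(names):
            cis[n] = _profile_interval(lik, theta, bounds, i, target)

    return EstimationResult(
        estimates=estimates,
        confidence_intervals=cis,
        log_likelihood=float(ll_max),
        method="ML_BETABINOMIAL" if overdispersion else "ML_BINOMIAL",
        converged=converged,
        boundary_params=boundary,
        message=str(best.message),
    )


def _profile_interval(
    lik: _Likelihood,
    theta: np.ndarray,
    bounds: list[tuple[float, float]],
    index: int,
    target_ll: float,
) -> tuple[float, float]:
    """Profile-likelihood interval for one parameter by bisection."""
    others = [j for j in range(len(theta)) if j != index]

    def profile(x: float) -> float:
        if not others:
            full = np.array(theta)
            full[index] = x
            return lik(full)
        if len(others) == 1:
            j = others[0]

            def neg1(y: float) -> float:
                full = np.array(theta)
                full[index] = x
                full[j] = y
                return -lik(full)

            r = optimize.minimize_scalar(
                neg1, bounds=bounds[j], method="bounded",
                options={"xatol": 1e-7},
            )
            return -r.fun

        def negk(ys: np.ndarray) -> float:
            full = np.array(theta)
            full[index] = x
            full[others] = ys
            return -lik(full)

        r = optimize.minimize(
            negk, theta[others], method="L-BFGS-B",
            bounds=[bounds[j] for j in others],
            options={"ftol": 1e-12},
        )
        return -r.fun

    blo, bhi = bounds[index]
    est = float(theta[index])

    def edge(a: float, b: float, fa: float, fb: float) -> float:
        # root of profile(x) - target_ll between a (below) and b (above)
        return float(optimize.brentq(
            lambda x: profile(x) - target_ll, a, b, xtol=1e-6, rtol=1e-8, maxiter=80
        ))

    if profile(blo) >= target_ll:
        low = 0.0
    else:
        low = edge(blo, est, 0, 0)
    if profile(bhi) >= target_ll:
        high = 1.0
    else:
        high = edge(est, bhi, 0, 0)
    return (low, high)


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def binomial_exact_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method).

    Sums ``Binomial(n, p0)`` probabilities of all outcomes whose point
    probability does not exceed that of the observed ``k``.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if n == 0:
        return 1.0
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def fisher_exact_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value on the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
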