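"""Closed-form finite-sample SFS theory for rare deleterious variants.

The model: carriers of a deleterious allele arise by mutation (rate
``rho * mu`` per unit area per generation), diffuse with RMS dispersal
``sigma`` per generation, reproduce at rate ``1 - s`` and die at rate 1
on an ``L x L`` torus.  A sample of ``n`` haploid genomes is drawn with
spatial weighting given by a Gaussian kernel of per-axis width ``w`` (or
uniformly).  At stationarity the kernel-weighted population frequency of
an allele is approximately Gamma distributed with shape ``theta_E`` (the
effective mutation supply) and rate ``gamma_E`` (the effective selection
intensity); mixing with Poisson sampling makes the sample allele count
``K`` Negative Binomial:

    K ~ NegBin(r = theta_E, p = gamma_E / (gamma_E + n)).

For concentrated (``w << L``) Gaussian sampling,

    theta_E = mu * rho * ell_c**2 * lambda(x),
    gamma_E = s  * rho * ell_c**2 * lambda(x),
    lambda(x) = 4 * pi / (exp(x) * E1(x)),   x = (w / ell_c)**2,

with characteristic length ``ell_c = sigma / (2 * sqrt(s))`` — the
spatial scale over which the carriers of one allele spread before the
allele's extinction.  ``rho * ell_c**2 * lambda`` plays the role of the
population size effectively being sampled; for broad kernels it grows as
``4 * pi * rho * w**2`` and under uniform sampling the effective
parameters reduce to the panmictic values ``N * mu`` and ``N * s``.

The constant in ``ell_c`` follows from matching the exact second moment
of the kernel-weighted frequency under this package's dispersal
convention (per-axis Brownian variance ``sigma**2 / 2`` per generation)
and is validated against the branching-process simulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import exp1, gammaln

from .params import PopulationParams, SamplingKernel

__all__ = [
    "EffectiveParams",
    "SummaryStatExpectations",
    "characteristic_length",
    "exp_scaled_e1",
    "sampling_effect_scalar",
    "effective_params",
    "sfs_pmf",
    "sfs_small_theta",
    "expected_summary_stats",
    "population_afd_density",
    "afd_distribution",
]


@dataclass(frozen=True)
class EffectiveParams:
    """Effective parameters of the finite-sample SFS for one design."""

    ell_c: float
    lam: float
    theta_E: float
    gamma_E: float

    def __post_init__(self) -> None:
        for name in ("ell_c", "lam", "theta_E", "gamma_E"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SummaryStatExpectations:
    """Expected SFS summary statistics for a sample of size n over M sites.

    ``het`` and ``cmaf`` use the rare-allele approximations
    ``2 * E[x]`` and ``M * E[x]``; ``het_exact`` evaluates
    ``E[2 (K/n) (1 - K/n)]`` under the Negative Binomial directly.
    """

    p_variant: float
    p_singleton: float
    mean_freq_variant: float
    mean_freq_all: float
    het: float
    het_exact: float
    cmaf: float


def characteristic_length(sigma: float, s: float) -> float:
    """Characteristic spatial scale ``ell_c = sigma / (2 * sqrt(s))``.

    Carrier lineages diffuse for ~1/s generations before the allele goes
    extinct, so the carriers of one allele spread over a distance of
    order ``sigma / sqrt(s)``; the factor 1/2 makes the second-moment
    formulas of :func:`effective_params` exact under the package's
    dispersal convention.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not 0 < s < 1:
        raise ValueError(f"s must lie in (0, 1), got {s}")
    return sigma / (2.0 * math.sqrt(s))


def exp_scaled_e1(x):
    """Numerically stable ``exp(x) * E1(x)`` for x > 0.

    Direct evaluation below x = 100; the asymptotic expansion
    ``(1/x) * sum_k k! * (-1/x)**k`` above, where the direct product
    loses relative precision (and eventually underflows) long before
    the expansion error reaches 1e-14.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    out = np.empty_like(x)
    small = x < 100.0
    if np.any(small):
        xs = x[small]
        out[small] = np.exp(xs) * exp1(xs)
    if np.any(~small):
        xl = x[~small]
        acc = np.zeros_like(xl)
        term = np.ones_like(xl)
        for k in range(1, 21):
            acc += term
            term *= -k / xl
        out[~small] = acc / xl
    return out if out.ndim else float(out)


def sampling_effect_scalar(w: float, ell_c: float):
    """Sampling effect scalar ``lambda = 4*pi / (exp(x) * E1(x))``, x=(w/ell_c)^2.

    Strictly increasing in ``w`` at fixed ``ell_c``; behaves as
    ``4*pi / log(1/x)`` for narrow kernels and as ``4*pi*x`` (so the
    effective population approaches ``4*pi*rho*w**2``) for broad ones.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("w must be positive")
    if not ell_c > 0:
        raise ValueError("ell_c must be positive")
    x = (w / ell_c) ** 2
    lam = 4.0 * math.pi / exp_scaled_e1(x)
    return lam if np.ndim(lam) else float(lam)


def effective_params(pop: PopulationParams, kernel: SamplingKernel) -> EffectiveParams:
    """Effective mutation supply and selection intensity for a design.

    Gaussian kernels use the concentrated-sampling formulas
    ``theta_E = mu * rho * ell_c**2 * lambda`` and
    ``gamma_E = s * rho * ell_c**2 * lambda``; the uniform kernel uses
    the panmictic values ``N * mu`` and ``N * s``.  A warning (not an
    error) is emitted when the Gaussian-regime effective population
    ``rho * ell_c**2 * lambda`` exceeds ``N``: there the ``w << L``
    derivation has left its validity domain and uniform sampling is the
    appropriate model.
    """
    if not pop.mu > 0:
        raise ValueError("effective parameters require mu > 0")
    ell_c = characteristic_length(pop.sigma, pop.s)
    if kernel.kind == "uniform":
        # lam chosen so N == rho * ell_c**2 * lam, keeping one algebraic form.
        lam = pop.L**2 / ell_c**2
        return EffectiveParams(
            ell_c=ell_c, lam=lam, theta_E=pop.N * pop.mu, gamma_E=pop.N * pop.s
        )
    lam = sampling_effect_scalar(kernel.width, ell_c)
    n_eff = pop.rho * ell_c**2 * lam
    if n_eff > pop.N:
        warnings.warn(
            f"effective population sampled ({n_eff:.3g}) exceeds N ({pop.N:.3g}); "
            "kernel width is not << L and the concentrated-sampling formulas are "
            "outside their validity domain (consider kind='uniform')",
            RuntimeWarning,
            stacklevel=2,
        )
    return EffectiveParams(
        ell_c=ell_c, lam=lam, theta_E=pop.mu * n_eff, gamma_E=pop.s * n_eff
    )


def _check_n_k(n, k) -> tuple[int, np.ndarray]:
    if not (float(n).is_integer() and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n}")
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        if not np.all(np.asarray(k, dtype=float) == np.floor(k)):
            raise ValueError("k must be integer")
        k = np.asarray(k, dtype=int)
    return int(n), k


def sfs_pmf(eff: EffectiveParams, n: int, k):
    """``Pr(K = k)`` for the sample allele count, vectorized over ``k``.

    ``K ~ NegBin(r=theta_E, p=gamma_E/(gamma_E+n))``, equivalently the
    Gamma(theta_E, gamma_E)-mixed Poisson(n*x).  Evaluated in log space
    for stability at large ``theta_E`` or ``k``.  Support is all k >= 0;
    for rare alleles the mass above k = n is negligible and no
    truncation is applied.
    """
    n, k = _check_n_k(n, k)
    if np.any(k < 0):
        raise ValueError("k must be nonnegative")
    r, g = eff.theta_E, eff.gamma_E
    # log1p forms avoid cancellation; the naive log difference loses
    # ~E[K]*1e-15 of total mass over the support
    logp = math.log1p(-n / (g + n))
    log1mp = math.log1p(-g / (g + n))
    logpmf = gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * logp + k * log1mp
    out = np.exp(logpmf)
    return out if out.ndim else float(out)


def sfs_small_theta(eff: EffectiveParams, n: int, k):
    """Small-``theta_E`` limit of the normalized SFS, k >= 1.

    ``xi_k(n) = (theta_E / k) * (n / (gamma_E + n))**k``; relative error
    versus :func:`sfs_pmf` is O(theta_E).
    """
    n, k = _check_n_k(n, k)
    if np.any(k < 1):
        raise ValueError("small-theta SFS is defined for variant counts k >= 1")
    out = (eff.theta_E / k) * np.exp(k * math.log1p(-eff.gamma_E / (eff.gamma_E + n)))
    return out if out.ndim else float(out)


def expected_summary_stats(
    eff: EffectiveParams, pop: PopulationParams, n: int, M: int = 1
) -> SummaryStatExpectations:
    """Expected SFS summary statistics for sample size ``n`` over ``M`` sites."""
    ratio = eff.theta_E / eff.gamma_E
    if not math.isclose(ratio, pop.mu / pop.s, rel_tol=1e-9):
        raise ValueError(
            f"effective params (theta_E/gamma_E={ratio:.6g}) inconsistent with "
            f"pop (mu/s={pop.mu / pop.s:.6g})"
        )
    p0 = float(sfs_pmf(eff, n, 0))
    p1 = float(sfs_pmf(eff, n, 1))
    p_variant = 1.0 - p0
    mean_freq_all = pop.mu / pop.s
    # E[K] = theta_E * n / gamma_E, E[K^2] = Var + E[K]^2
    ek = eff.theta_E * n / eff.gamma_E
    vark = eff.theta_E * n * (eff.gamma_E + n) / eff.gamma_E**2
    het_exact = 2.0 * ek / n - 2.0 * (vark + ek**2) / n**2
    return SummaryStatExpectations(
        p_variant=p_variant,
        p_singleton=p1,
        mean_freq_variant=mean_freq_all / p_variant if p_variant > 0 else math.nan,
        mean_freq_all=mean_freq_all,
        het=2.0 * mean_freq_all,
        het_exact=het_exact,
        cmaf=M * mean_freq_all,
    )


def afd_distribution(eff: EffectiveParams):
    """Frozen Gamma(shape=theta_E, rate=gamma_E) allele-frequency distribution."""
    return stats.gamma(a=eff.theta_E, scale=1.0 / eff.gamma_E)


def population_afd_density(eff: EffectiveParams, x):
    """Stationary density of the kernel-weighted allele frequency at ``x > 0``.

    Gamma with shape ``theta_E`` and rate ``gamma_E``: mean ``mu/s``,
    variance ``theta_E / gamma_E**2``.  The ``x -> 1`` tail of the
    panmictic density is dropped (rare-allele approximation).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    out = afd_distribution(eff).pdf(x)
    return out if out.ndim else float(out)
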