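"""Canned validation experiments: simulator-versus-theory cross checks.

These are the study designs used to validate the analytic machinery:

* :func:`recovery_experiment` — method-of-moments recovery of the
  effective parameters from branching-process family ensembles across
  sampling breadths, including the uniform (panmictic) limit.
* :func:`sfs_gof_experiment` — chi-square goodness of fit of a
  Poisson-sampled simulated SFS against the Negative Binomial theory.
* :func:`cohort_experiment` — the end-to-end synthetic-cohort
  resampling study: discovery, dilution, mean-frequency invariance and
  per-class contrasts across Gaussian sampling breadths.

Each function is deterministic given its seed and returns plain data
structures, so the same computations back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    DEFAULT_CLASS_MU,
    DEFAULT_CLASS_S,
    ResampleSpec,
    generate_synthetic_cohort,
    resampling_report,
)
from .params import PopulationParams, SamplingKernel
from .sfs import SampleSFS
from .simulate import (
    SimulationConfig,
    build_sim_sfs,
    estimate_effective_params,
    run_branching,
    simulate_family_moments,
)
from .theory import characteristic_length, effective_params, sfs_pmf

__all__ = [
    "RecoveryResult",
    "recovery_experiment",
    "sfs_gof_experiment",
    "cohort_experiment",
]


@dataclass(frozen=True)
class RecoveryResult:
    label: str
    theta_hat: float
    gamma_hat: float
    se_theta: float
    se_gamma: float
    theta_true: float
    gamma_true: float

    @property
    def z_theta(self) -> float:
        return (self.theta_hat - self.theta_true) / self.se_theta

    @property
    def z_gamma(self) -> float:
        return (self.gamma_hat - self.gamma_true) / self.se_gamma


def recovery_experiment(
    seed: int,
    n_families: int = 150_000,
    width_ratios: tuple[float, ...] = (0.3, 1.0, 3.0),
) -> list[RecoveryResult]:
    """Effective-parameter recovery across sampling breadths.

    Design: sigma=2, s=0.1, rho=20, L=1000; Gaussian kernels at
    ``w/ell_c`` in ``width_ratios`` plus the uniform kernel, estimated
    from one importance-sampled ensemble of independent mutation
    families.  The uniform kernel's targets are ``N*mu`` and ``N*s``.
    """
    pop = PopulationParams(sigma=2.0, rho=20.0, mu=1e-9, s=0.1, L=1000.0)
    ell = characteristic_length(pop.sigma, pop.s)
    kernels = [SamplingKernel.gaussian(width=r * ell, center=(500.0, 500.0))
               for r in width_ratios]
    kernels.append(SamplingKernel.uniform())
    fm = simulate_family_moments(pop, kernels, n_families, seed=seed)
    fits = estimate_effective_params(fm, seed=seed + 1)
    out = []
    for kern, fit, r in zip(kernels, fits, list(width_ratios) + [None]):
        eff = effective_params(pop, kern)
        label = "uniform" if r is None else f"w/lc={r:g}"
        out.append(RecoveryResult(label, fit.theta, fit.gamma, fit.se_theta,
                                  fit.se_gamma, eff.theta_E, eff.gamma_E))
    return out


def sfs_gof_experiment(seed: int, n: int = 10_000, sites: int = 4_000,
                       n_records: int = 60):
    """Simulated-versus-theoretical sample SFS, chi-square goodness of fit.

    Design: sigma=2, s=0.05, rho=100, L=200; Gaussian kernel at
    ``w = sqrt(2) * ell_c``; records spaced four selection timescales
    apart so successive spectra are effectively independent.  The
    density is chosen so the continuum-sampling assumption
    ``n << 2*pi*rho*w**2`` holds (a single carrier under the kernel
    carries ~0.2 sample copies, not ~1); at low density the sampled
    spectrum develops a genuine carrier-granularity singleton excess
    the continuum theory does not describe.  Variant classes are binned
    so every expected count is at least 5; the remaining NegBin tail
    mass is folded into the last bin.

    Returns ``(chi2, pvalue, n_variant_sites, table, sfs)``.
    """
    pop = PopulationParams(sigma=2.0, rho=100.0, mu=1.2e-8, s=0.05, L=200.0)
    ell = characteristic_length(pop.sigma, pop.s)
    kern = SamplingKernel.gaussian(width=math.sqrt(2.0) * ell, center=(100.0, 100.0))
    cfg = SimulationConfig(
        pop=pop, kernels=[kern], seed=seed, sites=sites,
        burn_in=200.0, record_every=80.0, total_time=200.0 + 80.0 * n_records,
    )
    res = run_branching(cfg)
    sfs = build_sim_sfs(res.records, n=n, M=sites, seed=seed + 1,
                        times=res.record_times)
    eff = effective_params(pop, kern)
    return (*sfs_theory_chi2(sfs, eff), sfs)


def sfs_theory_chi2(sfs: SampleSFS, eff, min_expected: float = 5.0):
    """Chi-square test of an observed SFS against the NegBin theory.

    Bins: the monomorphic class, then runs of variant counts merged
    until each bin's expected count reaches ``min_expected``.
    """
    M = sfs.M
    kmax = max(sfs.counts)
    obs_k = np.zeros(kmax + 1)
    for k, c in sfs.counts.items():
        obs_k[k] = c
    exp_k = M * sfs_pmf(eff, sfs.n, np.arange(kmax + 1))
    bins: list[list[int]] = [[0]]
    cur: list[int] = []
    for k in range(1, kmax + 1):
        cur.append(k)
        if exp_k[cur].sum() >= min_expected and k < kmax:
            bins.append(cur)
            cur = []
    if cur:
        if exp_k[cur].sum() >= min_expected:
            bins.append(cur)
        else:
            bins[-1].extend(cur)
    exp_b = np.array([exp_k[b].sum() for b in bins])
    obs_b = np.array([obs_k[b].sum() for b in bins])
    exp_b[-1] += M - exp_k.sum()  # NegBin tail mass beyond kmax
    chi2, p = sps.chisquare(obs_b, exp_b * obs_b.sum() / exp_b.sum())
    table = pd.DataFrame({
        "k_lo": [b[0] for b in bins], "k_hi": [b[-1] for b in bins],
        "observed": obs_b, "expected": exp_b,
    })
    n_variant = int(obs_k[1:].sum())
    return float(chi2), float(p), n_variant, table


#: Study design of the synthetic-cohort resampling experiment.
COHORT_DESIGN = {
    "sigma": 40.0,
    "L": 1000.0,
    "n_individuals": 60_000,
    "sites_per_class": 1_000,
    "widths": (135.0, 180.0, 230.0),
    "centers": ((250.0, 250.0), (500.0, 500.0), (750.0, 750.0)),
    "size": 10_000,
    "replicates_per_center": 4,
}


def cohort_experiment(seed: int):
    """End-to-end discovery/dilution study on a synthetic cohort.

    A three-class cohort (:data:`~spatialsfs.cohort.DEFAULT_CLASS_S`) is
    resampled at three Gaussian breadths — each averaged over three
    sampling centers, as multi-center biobank designs are — plus a
    uniform design.  Returns ``(per_class, aggregate, contrasts)``
    where contrasts map class label to the uniform-to-narrowest ratio
    of mean discovered variant sites.
    """
    d = COHORT_DESIGN
    rho = d["n_individuals"] / d["L"] ** 2
    pop = PopulationParams(sigma=d["sigma"], rho=rho, mu=1e-6,
                           s=next(iter(DEFAULT_CLASS_S.values())), L=d["L"])
    cohort = generate_synthetic_cohort(
        pop, d["n_individuals"], d["sites_per_class"], seed=seed)
    specs: list[ResampleSpec] = []
    i = 0
    for w in d["widths"]:
        for c in d["centers"]:
            specs.append(ResampleSpec(
                size=d["size"], center=c, width=w,
                replicates=d["replicates_per_center"], seed=seed + 1000 + i,
                density_adjust="hist", label=f"w={w:g}"))
            i += 1
    n_uni = d["replicates_per_center"] * len(d["centers"])
    specs.append(ResampleSpec(size=d["size"], width=None, replicates=n_uni,
                              seed=seed + 1000 + i, label="uniform"))
    per_class = resampling_report(cohort, specs, L=d["L"])
    aggregate = resampling_report(cohort, specs, L=d["L"], by_class=False)
    narrow = f"w={d['widths'][0]:g}"
    pc = per_class.set_index(["s_class", "design"])
    contrasts = {
        lab: pc.loc[(lab, "uniform"), "variant_sites_mean"]
        / pc.loc[(lab, narrow), "variant_sites_mean"]
        for lab in DEFAULT_CLASS_S
    }
    return per_class, aggregate, contrasts
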