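"""In-model Gillespie simulation of the spatial branching process.

Two complementary modes:

* :func:`run_branching` — a coupled whole-habitat simulation.  New
  alleles arise by a Poisson process with rate ``rho * L**2 * mu *
  sites`` (infinite sites: every mutation gets a fresh allele id and a
  uniform random position); every carrier reproduces at rate ``1 - s``
  (offspring at the parent's position) and dies at rate 1; carriers
  diffuse with per-axis variance ``sigma**2 / 2`` per generation.
  Positions are advanced lazily — Brownian increments are exact for any
  elapsed time, so a carrier is only touched at its own birth/death
  events and at recording times.

* :func:`simulate_family_moments` — because carriers of different
  alleles evolve independently, the stationary law of the per-site
  weighted frequency is a superposition of independent single-mutation
  "family" processes arriving at rate ``rho * L**2 * mu`` per site.
  This mode simulates families one at a time from origin to extinction
  and accumulates the occupation integrals ``int x_w dt`` and
  ``int x_w**2 dt``, optionally importance-sampling the mutation origin
  towards the sampling kernel.  It is the low-variance route to the
  effective-parameter estimates.

Per-site moments follow from the superposition: with per-site influx
``Lambda = rho * L**2 * mu``,

    E[X]   = Lambda * E[int x_w dt]          ( = mu / s exactly )
    Var[X] = Lambda * E[int x_w**2 dt]       (connected/compound-Poisson)

The effective-parameter theory describes the continuum (measure-valued)
limit of the particle process.  At finite turnover the particle pair
correlation is ``(1 - s)`` times the continuum one, plus an atomic
self-pair ("shot noise") term ``sum_i phi(p_i)**2 / rho**2``; for the
uniform kernel the two finite-size effects cancel exactly
(``(1-s)/s**2 + 1/s = 1/s**2``).  The moment estimators therefore use

    Var_continuum = (int x_w**2 dt  -  shot) / (1 - s),

which is exact in the uniform limit for every ``s`` and recovers the
exponential-integral theory for concentrated Gaussian kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import kernel_density
from .params import PopulationParams, SamplingKernel
from .sfs import SampleSFS
from .theory import characteristic_length

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "FamilyMoments",
    "GammaMoMFit",
    "run_branching",
    "simulate_family_moments",
    "weighted_frequency",
    "sample_allele_count",
    "estimate_effective_params",
    "build_sim_sfs",
]


# ---------------------------------------------------------------------------
# numerical cores (numba-jitted when available)
# ---------------------------------------------------------------------------


def _kdens_scalar(x, y, kind, cx, cy, w, L):
    """Kernel density at one point; kind 0 = uniform, 1 = wrapped gaussian."""
    if kind == 0:
        return 1.0 / (L * L)
    dx = (x - cx + 0.5 * L) % L - 0.5 * L
    dy = (y - cy + 0.5 * L) % L - 0.5 * L
    nim = int(6.0 * w / L) + 1
    sx = 0.0
    sy = 0.0
    for k in range(-nim, nim + 1):
        sx += math.exp(-((dx + k * L) ** 2) / (2.0 * w * w))
        sy += math.exp(-((dy + k * L) ** 2) / (2.0 * w * w))
    return sx * sy / (2.0 * math.pi * w * w)


def _coupled_core(
    seed, L, sigma, s, lam, t_burn, rec_every, n_rec,
    kkind, kcx, kcy, kw, rho, max_carriers, rec_cap,
):
    """Coupled Gillespie run. Returns (status, records..., final state).

    status: 0 ok, 1 carrier cap exceeded, 2 record buffer overflow.
    """
    np.random.seed(seed)
    nk = kkind.shape[0]
    cap = max_carriers
    px = np.empty(cap)
    py = np.empty(cap)
    lt = np.empty(cap)
    al = np.empty(cap, np.int64)
    C = 0
    t = 0.0
    next_allele = 0
    sdf = sigma / math.sqrt(2.0)

    rec_t = np.empty(rec_cap)
    rec_al = np.empty(rec_cap, np.int64)
    rec_x = np.empty((rec_cap, nk))
    rec_shot = np.empty((rec_cap, nk))
    n_rows = 0
    rec_csize = np.zeros(n_rec, np.int64)
    irec = 0

    while irec < n_rec:
        rate = lam + C * (2.0 - s)
        dt = np.random.exponential(1.0 / rate)
        # emit any record times falling before the next event
        while irec < n_rec and t_burn + irec * rec_every <= t + dt:
            tr = t_burn + irec * rec_every
            for i in range(C):
                el = tr - lt[i]
                if el > 0.0:
                    sd = sdf * math.sqrt(el)
                    px[i] = (px[i] + np.random.normal(0.0, sd)) % L
                    py[i] = (py[i] + np.random.normal(0.0, sd)) % L
                    lt[i] = tr
            rec_csize[irec] = C
            if C > 0:
                order = np.argsort(al[:C], kind="mergesort")
                j = 0
                while j < C:
                    a = al[order[j]]
                    if n_rows >= rec_cap:
                        return (2, rec_t[:n_rows], rec_al[:n_rows], rec_x[:n_rows],
                                rec_shot[:n_rows], rec_csize, px[:C], py[:C],
                                al[:C], next_allele, t)
                    for q in range(nk):
                        rec_x[n_rows, q] = 0.0
                        rec_shot[n_rows, q] = 0.0
                    while j < C and al[order[j]] == a:
                        i = order[j]
                        for q in range(nk):
                            d = _kdens_scalar(px[i], py[i], kkind[q], kcx[q], kcy[q], kw[q], L)
                            rec_x[n_rows, q] += d / rho
                            rec_shot[n_rows, q] += (d / rho) ** 2
                        j += 1
                    rec_t[n_rows] = tr
                    rec_al[n_rows] = a
                    n_rows += 1
            irec += 1
        t += dt
        if np.random.random() < lam / rate:
            if C >= cap:
                return (1, rec_t[:n_rows], rec_al[:n_rows], rec_x[:n_rows],
                        rec_shot[:n_rows], rec_csize, px[:C], py[:C], al[:C],
                        next_allele, t)
            px[C] = np.random.random() * L
            py[C] = np.random.random() * L
            lt[C] = t
            al[C] = next_allele
            next_allele += 1
            C += 1
        elif C > 0:
            i = np.random.randint(0, C)
            el = t - lt[i]
            if el > 0.0:
                sd = sdf * math.sqrt(el)
                px[i] = (px[i] + np.random.normal(0.0, sd)) % L
                py[i] = (py[i] + np.random.normal(0.0, sd)) % L
            lt[i] = t
            if np.random.random() < (1.0 - s) / (2.0 - s):
                if C >= cap:
                    return (1, rec_t[:n_rows], rec_al[:n_rows], rec_x[:n_rows],
                            rec_shot[:n_rows], rec_csize, px[:C], py[:C], al[:C],
                            next_allele, t)
                px[C] = px[i]
                py[C] = py[i]
                lt[C] = t
                al[C] = al[i]
                C += 1
            else:
                C -= 1
                px[i] = px[C]
                py[i] = py[C]
                lt[i] = lt[C]
                al[i] = al[C]
    return (0, rec_t[:n_rows], rec_al[:n_rows], rec_x[:n_rows], rec_shot[:n_rows],
            rec_csize, px[:C], py[:C], al[:C], next_allele, t)


def _family_core(
    seed, n_fam, ox, oy, L, sigma, s, rec_dt, t_cap,
    kkind, kcx, kcy, kw, rho, max_carriers,
):
    """Independent single-mutation families; occupation integrals per kernel.

    i1[f, q] ~ int x_w dt,  i2[f, q] ~ int (x_w**2 - shot) dt.
    status 0 ok, 1 a family hit the carrier cap.
    """
    np.random.seed(seed)
    nk = kkind.shape[0]
    i1 = np.zeros((n_fam, nk))
    i2 = np.zeros((n_fam, nk))
    sdf = sigma / math.sqrt(2.0)
    cap = max_carriers
    px = np.empty(cap)
    py = np.empty(cap)
    lt = np.empty(cap)
    status = 0
    for f in range(n_fam):
        px[0] = ox[f]
        py[0] = oy[f]
        lt[0] = 0.0
        C = 1
        t = 0.0
        # random grid phase: the occupation Riemann sum is then unbiased
        # even when x_w fluctuates faster than rec_dt
        tnext = np.random.random() * rec_dt
        while C > 0 and t < t_cap:
            rate = C * (2.0 - s)
            dt = np.random.exponential(1.0 / rate)
            while tnext <= t + dt and tnext < t_cap:
                for i in range(C):
                    el = tnext - lt[i]
                    if el > 0.0:
                        sd = sdf * math.sqrt(el)
                        px[i] = (px[i] + np.random.normal(0.0, sd)) % L
                        py[i] = (py[i] + np.random.normal(0.0, sd)) % L
                        lt[i] = tnext
                for q in range(nk):
                    sphi = 0.0
                    sphi2 = 0.0
                    for i in range(C):
                        d = _kdens_scalar(px[i], py[i], kkind[q], kcx[q], kcy[q], kw[q], L)
                        sphi += d
                        sphi2 += d * d
                    xw = sphi / rho
                    i1[f, q] += xw * rec_dt
                    i2[f, q] += (xw * xw - sphi2 / (rho * rho)) * rec_dt
                tnext += rec_dt
            t += dt
            i = np.random.randint(0, C)
            el = t - lt[i]
            if el > 0.0:
                sd = sdf * math.sqrt(el)
                px[i] = (px[i] + np.random.normal(0.0, sd)) % L
                py[i] = (py[i] + np.random.normal(0.0, sd)) % L
            lt[i] = t
            if np.random.random() < (1.0 - s) / (2.0 - s):
                if C >= cap:
                    status = 1
                    break
                px[C] = px[i]
                py[C] = py[i]
                lt[C] = t
                C += 1
            else:
                C -= 1
                px[i] = px[C]
                py[i] = py[C]
                lt[i] = lt[C]
    return status, i1, i2


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _kdens_scalar = njit(cache=True)(_kdens_scalar)
    _coupled_core = njit(cache=True)(_coupled_core)
    _family_core = njit(cache=True)(_family_core)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Schedule and scope of a coupled branching simulation.

    ``burn_in`` defaults to ``10 / s`` generations and ``record_every``
    to ``1 / s`` (roughly one decorrelation time of family turnover).
    ``sites`` is the number of mutational sites the run represents: the
    total mutation influx is ``rho * L**2 * mu * sites`` per generation
    while ``mu`` stays the per-site rate used by the theory.
    """

    pop: PopulationParams
    kernels: list[SamplingKernel]
    seed: int
    total_time: float | None = None
    burn_in: float | None = None
    record_every: float | None = None
    sites: int = 1
    max_carriers: int = 1_000_000

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = 10.0 / self.pop.s
        if self.record_every is None:
            self.record_every = 1.0 / self.pop.s
        if self.total_time is None:
            self.total_time = self.burn_in + 100.0 * self.record_every
        if not self.record_every > 0:
            raise ValueError("record_every must be positive")
        if not self.burn_in < self.total_time:
            raise ValueError("burn_in must be smaller than total_time")
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if not self.kernels:
            raise ValueError("at least one sampling kernel is required")

    @property
    def n_records(self) -> int:
        return 1 + int(math.floor((self.total_time - self.burn_in) / self.record_every))

    @property
    def influx(self) -> float:
        """Total mutation influx Lambda = rho * L**2 * mu * sites."""
        p = self.pop
        return p.rho * p.L**2 * p.mu * self.sites


@dataclass
class SimulationResult:
    """Records plus final carrier state of a coupled run."""

    config: SimulationConfig
    records: pd.DataFrame  # time, allele_id, kernel_id, x_w, shot
    carrier_counts: np.ndarray  # per record time
    final_positions: np.ndarray  # (C, 2)
    final_alleles: np.ndarray  # (C,)
    n_alleles_total: int

    @property
    def record_times(self) -> np.ndarray:
        cfg = self.config
        return cfg.burn_in + cfg.record_every * np.arange(cfg.n_records)


def run_branching(config: SimulationConfig) -> SimulationResult:
    """Run the coupled Gillespie simulation described by ``config``.

    Raises ``RuntimeError`` with a diagnostic if the carrier population
    exceeds ``max_carriers`` (the chosen regime then violates the
    rare-variant assumption: compare the expected stationary count
    ``influx / s`` with the neighborhood size ``4*pi*sigma**2*rho``).
    """
    pop = config.pop
    kk, kcx, kcy, kw = _pack_kernels(config.kernels)
    n_rec = config.n_records
    lam = config.influx
    if not lam > 0:
        raise ValueError("mutation influx is zero (mu=0); nothing to simulate")
    exp_carriers = lam / pop.s
    exp_alleles = max(lam * math.log(1.0 / pop.s), 1.0)
    rec_cap = int(n_rec * (8 * exp_alleles + 64) + 1024)
    out = _coupled_core(
        int(config.seed) % 2**31, pop.L, pop.sigma, pop.s, lam,
        float(config.burn_in), float(config.record_every), n_rec,
        kk, kcx, kcy, kw, pop.rho, int(config.max_carriers), rec_cap,
    )
    status, rec_t, rec_al, rec_x, rec_shot, rec_csize, fpx, fpy, fal, n_alleles, t_end = out
    if status == 1:
        raise RuntimeError(
            f"carrier count exceeded max_carriers={config.max_carriers} at t={t_end:.1f}; "
            f"expected stationary count is influx/s = {exp_carriers:.3g} and the "
            f"neighborhood size is {pop.neighborhood_size:.3g} — the parameter regime "
            "may violate the rarity assumption"
        )
    if status == 2:
        raise RuntimeError("record buffer overflow; reduce record count or influx")
    nk = len(config.kernels)
    n_rows = len(rec_t)
    records = pd.DataFrame(
        {
            "time": np.repeat(rec_t, nk),
            "allele_id": np.repeat(rec_al, nk),
            "kernel_id": np.tile(np.arange(nk), n_rows),
            "x_w": rec_x.ravel(),
            "shot": rec_shot.ravel(),
        }
    )
    # Rarity check is local: a surviving family of typical size
    # 1/(s*ln(1/s)) concentrates ~4/ln(1/s) carriers within one dispersal
    # radius (sigma^2/ell_c^2 = 4s of its mass); this must stay small
    # against the neighborhood size 4*pi*sigma^2*rho.
    local = 4.0 / math.log(1.0 / pop.s)
    if local > 0.25 * pop.neighborhood_size:
        import warnings

        warnings.warn(
            f"local carrier count ~{local:.3g} approaches the neighborhood size "
            f"{pop.neighborhood_size:.3g}; the independent-carriers approximation "
            "may be strained",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimulationResult(
        config=config,
        records=records,
        carrier_counts=rec_csize,
        final_positions=np.column_stack([fpx, fpy]),
        final_alleles=fal.copy(),
        n_alleles_total=int(n_alleles),
    )


def _pack_kernels(kernels):
    kk = np.array([0 if k.kind == "uniform" else 1 for k in kernels], np.int64)
    kcx = np.array([k.center[0] for k in kernels], float)
    kcy = np.array([k.center[1] for k in kernels], float)
    kw = np.array([k.width if k.width else 1.0 for k in kernels], float)
    return kk, kcx, kcy, kw


# ---------------------------------------------------------------------------
# per-family ensemble mode
# ---------------------------------------------------------------------------


@dataclass
class FamilyMoments:
    """Occupation integrals of an ensemble of independent families.

    ``i1``/``i2`` have shape (n_families, n_kernels); ``weights`` are the
    importance weights of the mutation origins (1 when origins were
    drawn uniformly).  ``lam_site = rho * L**2 * mu`` is the per-site
    mutation influx that scales occupation integrals into per-site
    moments.
    """

    pop: PopulationParams
    kernels: list[SamplingKernel]
    i1: np.ndarray
    i2: np.ndarray
    weights: np.ndarray

    @property
    def lam_site(self) -> float:
        p = self.pop
        return p.rho * p.L**2 * p.mu

    @property
    def n_families(self) -> int:
        return self.i1.shape[0]


def _sample_origins(pop, kernels, n, rng):
    """Origins from a defensive mixture proposal, with importance weights.

    Half the mass is uniform (bounding weights by 2); the rest is spread
    over wrapped Gaussians centred on each Gaussian kernel, widened by
    the family dispersal scale so that everything that can contribute to
    the occupation integrals is well covered.
    """
    L = pop.L
    gauss = [k for k in kernels if k.kind == "gaussian"]
    if not gauss:
        ox = rng.uniform(0, L, n)
        oy = rng.uniform(0, L, n)
        return ox, oy, np.ones(n)
    ell = characteristic_length(pop.sigma, pop.s)
    widths = [min(math.hypot(k.width, 4.0 * ell), L) for k in gauss]
    comp = rng.integers(0, 2 * len(gauss), n)  # evens: uniform, odds: gaussians
    ox = rng.uniform(0, L, n)
    oy = rng.uniform(0, L, n)
    for j, (k, wq) in enumerate(zip(gauss, widths)):
        m = comp == 2 * j + 1
        nm = int(m.sum())
        ox[m] = (k.center[0] + rng.normal(0, wq, nm)) % L
        oy[m] = (k.center[1] + rng.normal(0, wq, nm)) % L
    # proposal density (uniform half + equal-weight gaussian halves)
    pts = np.column_stack([ox, oy])
    q = np.full(n, 0.5 / L**2)
    for k, wq in zip(gauss, widths):
        prop = SamplingKernel.gaussian(width=wq, center=k.center)
        q += (0.5 / len(gauss)) * kernel_density(prop, pts, L)
    return ox, oy, (1.0 / L**2) / q


def simulate_family_moments(
    pop: PopulationParams,
    kernels: list[SamplingKernel],
    n_families: int,
    seed: int,
    record_dt: float | None = None,
    t_cap: float | None = None,
    importance_sampling: bool = True,
    max_carriers: int = 100_000,
) -> FamilyMoments:
    """Simulate ``n_families`` independent mutation families.

    ``record_dt`` defaults to ``0.1 / s`` (ten occupation samples per
    expected family timescale); ``t_cap`` defaults to ``40 / s``, beyond
    which the survival probability is ~``s * exp(-40)`` and the
    truncated occupation mass is negligible.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    if record_dt is None:
        record_dt = 0.1 / pop.s
    if t_cap is None:
        t_cap = 40.0 / pop.s
    if importance_sampling:
        ox, oy, wts = _sample_origins(pop, kernels, n_families, rng)
    else:
        ox = rng.uniform(0, pop.L, n_families)
        oy = rng.uniform(0, pop.L, n_families)
        wts = np.ones(n_families)
    kk, kcx, kcy, kw = _pack_kernels(kernels)
    status, i1, i2 = _family_core(
        int(rng.integers(2**31)), n_families, ox, oy, pop.L, pop.sigma, pop.s,
        float(record_dt), float(t_cap), kk, kcx, kcy, kw, pop.rho, max_carriers,
    )
    if status != 0:
        raise RuntimeError(
            f"a family exceeded max_carriers={max_carriers}; the regime violates "
            "the rare-variant assumption"
        )
    return FamilyMoments(pop=pop, kernels=list(kernels), i1=i1, i2=i2, weights=wts)


# ---------------------------------------------------------------------------
# frequency functionals and estimators
# ---------------------------------------------------------------------------


def weighted_frequency(positions, kernel: SamplingKernel, pop: PopulationParams) -> float:
    """Kernel-weighted frequency ``x_w = sum_i phi(p_i) / rho`` of one allele.

    For the uniform kernel this reduces to (number of carriers)/N.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        return 0.0
    return float(kernel_density(kernel, positions.reshape(-1, 2), pop.L).sum() / pop.rho)


def sample_allele_count(x_w: float, n: int, rng: np.random.Generator) -> int:
    """Poisson(n * x_w) draw of the sample allele count."""
    if x_w < 0:
        raise ValueError("x_w must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(rng.poisson(n * x_w))


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class GammaMoMFit:
    """Method-of-moments gamma fit (shape=theta, rate=gamma) with bootstrap SEs."""

    theta: float
    gamma: float
    se_theta: float
    se_gamma: float
    mean: float
    var: float
    n: int


def _mom_fit(m1: float, var: float) -> tuple[float, float]:
    if not var > 0:
        raise EstimationError("nonpositive variance; cannot fit gamma moments")
    if not m1 > 0:
        raise EstimationError("nonpositive mean; cannot fit gamma moments")
    return m1 * m1 / var, m1 / var


def estimate_effective_params(
    data,
    *,
    n_boot: int = 200,
    seed: int = 0,
    block: int | None = None,
    segregating_only: bool = False,
    include_shot_noise: bool = False,
):
    """Method-of-moments (theta_E, gamma_E) estimates with bootstrap SEs.

    Accepts either

    * a :class:`FamilyMoments` ensemble — per-site mean and connected
      variance are ``lam_site * E[int x dt]`` and ``lam_site *
      E[int x**2 dt]`` (superposition of independent families); the
      bootstrap resamples families.  Returns a list of
      :class:`GammaMoMFit`, one per kernel.

    * a :class:`SimulationResult` — per-record sums over alleles give
      the same two moments (per-site accounting via ``config.sites``)
      and a circular moving-block bootstrap over record times gives the
      SEs.  Returns a dict kernel_id -> fit.

    * a 1-D array of per-site frequency draws (zeros included) —
      ordinary MoM ``shape = mean**2/var``, ``rate = mean/var`` with an
      iid (or block, if ``block>1``) bootstrap.  Returns one fit.

    ``segregating_only=True`` fits the conditional (positive-mass)
    distribution instead: informative about gamma_E alone, since the
    zero class carries the mutation-supply information.
    """
    rng = np.random.default_rng(seed)
    if isinstance(data, FamilyMoments):
        return _estimate_from_families(data, n_boot, rng, include_shot_noise)
    if isinstance(data, SimulationResult):
        return _estimate_from_records(data.records, int(data.config.sites),
                                      data.config.pop.s, n_boot, rng, block,
                                      include_shot_noise)
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise EstimationError("need at least two frequency draws")
    if segregating_only:
        x = x[x > 0]
        if x.size < 2:
            raise EstimationError("fewer than two segregating draws")
    m1 = x.mean()
    var = x.var(ddof=1)
    theta, gamma = _mom_fit(m1, var)
    block = int(block or 1)
    ths, gms = [], []
    nblocks = max(1, x.size // block)
    for _ in range(n_boot):
        if block > 1:
            starts = rng.integers(0, x.size, nblocks)
            idx = (starts[:, None] + np.arange(block)) % x.size
            xb = x[idx.ravel()]
        else:
            xb = x[rng.integers(0, x.size, x.size)]
        try:
            th, gm = _mom_fit(xb.mean(), xb.var(ddof=1))
        except EstimationError:
            continue
        ths.append(th)
        gms.append(gm)
    return GammaMoMFit(theta, gamma, _sd(ths), _sd(gms), m1, var, x.size)


def _sd(v):
    return float(np.std(v)) if len(v) > 1 else float("nan")


def _estimate_from_families(fm: FamilyMoments, n_boot, rng, include_shot_noise):
    lam = fm.lam_site
    w = fm.weights
    if include_shot_noise:
        raise EstimationError("family moments store shot-corrected integrals only")
    corr = 1.0 - fm.pop.s  # particle-to-continuum pair-correlation factor
    fits = []
    for q in range(len(fm.kernels)):
        a1 = w * fm.i1[:, q]
        a2 = w * fm.i2[:, q] / corr
        m1 = lam * a1.mean()
        var = lam * a2.mean()
        theta, gamma = _mom_fit(m1, var)
        ths, gms = [], []
        F = fm.n_families
        for _ in range(n_boot):
            idx = rng.integers(0, F, F)
            b1 = lam * a1[idx].mean()
            b2 = lam * a2[idx].mean()
            try:
                th, gm = _mom_fit(b1, b2)
            except EstimationError:
                continue
            ths.append(th)
            gms.append(gm)
        fits.append(GammaMoMFit(theta, gamma, _sd(ths), _sd(gms), m1, var, F))
    return fits


def _estimate_from_records(records, sites, s, n_boot, rng, block, include_shot_noise):
    if sites < 1:
        raise EstimationError("sites must be >= 1")
    fits = {}
    corr = 1.0 if include_shot_noise else 1.0 - s
    for kid, sub in records.groupby("kernel_id"):
        x2 = (sub.x_w**2 - (0.0 if include_shot_noise else sub.shot)) / corr
        per_t = pd.DataFrame({"s1": sub.x_w, "s2": x2}).groupby(sub.time).sum()
        times = per_t.index.to_numpy()
        R = len(times)
        m1 = per_t.s1.mean() / sites
        var = per_t.s2.mean() / sites
        theta, gamma = _mom_fit(m1, var)
        blk = int(block) if block else max(1, R // 20)
        nblocks = max(1, R // blk)
        s1 = per_t.s1.to_numpy()
        s2 = per_t.s2.to_numpy()
        ths, gms = [], []
        for _ in range(n_boot):
            starts = rng.integers(0, R, nblocks)
            idx = (starts[:, None] + np.arange(blk)) % R
            idx = idx.ravel()
            try:
                th, gm = _mom_fit(s1[idx].mean() / sites, s2[idx].mean() / sites)
            except EstimationError:
                continue
            ths.append(th)
            gms.append(gm)
        fits[int(kid)] = GammaMoMFit(theta, gamma, _sd(ths), _sd(gms), m1, var, R)
    return fits


# ---------------------------------------------------------------------------
# simulated sample SFS
# ---------------------------------------------------------------------------


def build_sim_sfs(
    records: pd.DataFrame,
    n: int,
    M: int,
    seed: int,
    kernel_id: int = 0,
    times=None,
) -> SampleSFS:
    """Poisson-sample a SampleSFS from recorded weighted frequencies.

    Each recorded allele occupies its own site (infinite sites); the
    remaining ``M - (number of segregating alleles)`` sites at each
    record time are monomorphic.  Allele counts are ``K ~ Poisson(n *
    x_w)``.  With ``times=None`` every record time contributes ``M``
    sites, so the histogram totals ``M * n_times``.
    """
    rng = np.random.default_rng(seed)
    sub = records[records.kernel_id == kernel_id]
    if times is None:
        use_times = np.unique(sub.time.to_numpy())
        if use_times.size == 0:
            raise ValueError("records cover no recording time")
    else:
        use_times = np.atleast_1d(np.asarray(times, dtype=float))
        if use_times.size == 0:
            raise ValueError("no recording times requested")
    counts: dict[int, int] = {}
    for t in use_times:
        grp = sub[sub.time == t]
        seg = len(grp)
        if seg > M:
            raise ValueError(f"M={M} smaller than {seg} segregating alleles at one time")
        ks = rng.poisson(n * grp.x_w.to_numpy())
        ks = np.minimum(ks, n)  # Poisson tail above n is unphysical; clamp
        for k in ks:
            counts[int(k)] = counts.get(int(k), 0) + 1
        counts[0] = counts.get(0, 0) + (M - seg)
    return SampleSFS(n=n, counts=counts)
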