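"""Cohorts of located individuals and weighted (SIR) resampling.

A :class:`Cohort` holds individual 2-D coordinates and a haploid 0/1
genotype matrix (sites x individuals).  :func:`generate_synthetic_cohort`
builds one from the branching-process model: carriers of rare deleterious
alleles — spatially clustered by shared ancestry — are overlaid on
uniformly placed non-carriers, with several selection classes mimicking
annotation severity (LoF > missense > synonymous ordering of ``s``).

:func:`sir_resample` constructs geographically concentrated subsamples:
importance weights are the ratio of a Gaussian target density to the
cohort's empirical sampling density, and each replicate is a weighted
draw without replacement.  This is the in-silico analogue of resampling
a biobank at a chosen geographic breadth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import kernel_density
from .params import PopulationParams, SamplingKernel
from .sfs import SampleSFS, summarize_sfs

__all__ = [
    "Cohort",
    "ResampleSpec",
    "estimate_sampling_density",
    "sir_resample",
    "cohort_sfs",
    "generate_synthetic_cohort",
    "resampling_report",
]

# Severity classes: ell_c = sigma/(2*sqrt(s)) spans tightly-clustered (lof)
# to habitat-wide (synonymous) at the default sigma=40, L=1000 scale.
DEFAULT_CLASS_S = {"lof": 0.1, "missense": 0.01, "synonymous": 0.001}
# Per-class mutation supply chosen so each class yields comparable numbers of
# discoverable sites in a n~2000 subsample (the analogue of analysing
# equal-sized random subsets of variants per annotation class).
DEFAULT_CLASS_MU = {"lof": 3.2e-6, "missense": 7.0e-7, "synonymous": 1.5e-7}


@dataclass
class Cohort:
    """Located individuals with a haploid genotype matrix.

    ``genotypes`` has shape (n_sites, n_individuals) with entries in
    {0, 1}; ``sites`` is a DataFrame with one row per genotype row
    (columns at least ``site_id``; synthetic cohorts add ``s_class``
    and ``s``).
    """

    ids: list[str]
    coords: np.ndarray
    genotypes: np.ndarray
    sites: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n = len(self.ids)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_individuals, 2) aligned to ids")
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != n:
            raise ValueError("genotypes must be (n_sites, n_individuals)")
        if not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("genotype entries must be 0/1 (haploid)")
        if self.sites is not None and len(self.sites) != self.genotypes.shape[0]:
            raise ValueError("sites table must align with genotype rows")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]


@dataclass(frozen=True)
class ResampleSpec:
    """One resampling design: a Gaussian target (or uniform) of given size.

    ``width=None`` means uniform sampling (a simple random sample).
    ``density_adjust`` selects the empirical-density estimator used in
    the importance weights: "kde" (Gaussian KDE, plug-in bandwidth) or
    "hist" (2-D histogram).
    """

    size: int
    center: tuple[float, float] = (0.0, 0.0)
    width: float | None = None
    replicates: int = 1
    seed: int = 0
    density_adjust: str = "kde"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.width is not None and not self.width > 0:
            raise ValueError("width must be positive (or None for uniform)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.density_adjust not in ("kde", "hist"):
            raise ValueError(f"unknown density_adjust {self.density_adjust!r}")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return "uniform" if self.width is None else f"w={self.width:g}"


def estimate_sampling_density(coords, L: float | None = None, method: str = "kde"):
    """Empirical sampling density at each individual's coordinate.

    "kde" uses a Gaussian kernel density estimate with Scott's plug-in
    bandwidth; when ``L`` is given the data are treated as living on an
    ``L x L`` torus and points near the boundary are tiled so the
    estimate has no edge deficit.  "hist" bins coordinates on a 2-D
    grid — cheap and robust for gridded synthetic cohorts.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("coords must be (n >= 2, 2)")
    if np.allclose(coords.std(axis=0), 0):
        raise ValueError("degenerate coordinates: all individuals colocated")
    n = coords.shape[0]
    if method == "hist":
        nb = max(8, int(round(math.sqrt(n / 20.0))))
        lo = coords.min(axis=0) if L is None else np.array([0.0, 0.0])
        hi = coords.max(axis=0) if L is None else np.array([L, L])
        H, ex, ey = np.histogram2d(coords[:, 0], coords[:, 1], bins=nb,
                                   range=[[lo[0], hi[0]], [lo[1], hi[1]]])
        area = (ex[1] - ex[0]) * (ey[1] - ey[0])
        ix = np.clip(np.searchsorted(ex, coords[:, 0], side="right") - 1, 0, nb - 1)
        iy = np.clip(np.searchsorted(ey, coords[:, 1], side="right") - 1, 0, nb - 1)
        return H[ix, iy] / (n * area)
    if method != "kde":
        raise ValueError(f"unknown method {method!r}")
    pts = coords
    scale = 1.0
    if L is not None:
        bw = n ** (-1.0 / 6.0) * coords.std(axis=0).mean()  # Scott, rough
        margin = min(3.0 * bw, L / 2.0)
        tiles = [pts]
        for dx in (-L, 0, L):
            for dy in (-L, 0, L):
                if dx == 0 and dy == 0:
                    continue
                shifted = pts + np.array([dx, dy])
                keep = ((shifted[:, 0] > -margin) & (shifted[:, 0] < L + margin)
                        & (shifted[:, 1] > -margin) & (shifted[:, 1] < L + margin))
                if keep.any():
                    tiles.append(shifted[keep])
        tiled = np.vstack(tiles)
        scale = tiled.shape[0] / n
        pts = tiled
    try:
        kde = stats.gaussian_kde(pts.T)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError(f"degenerate coordinates for KDE: {e}") from e
    dens = kde(coords.T) * scale
    if not np.all(dens > 0):
        raise ValueError("nonpositive density estimate")
    return dens


def sir_resample(
    cohort: Cohort,
    spec: ResampleSpec,
    L: float | None = None,
    empirical_density: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Sampling-importance-resampling index sets, one per replicate.

    Importance weights are ``target(coords_i) / empirical(coords_i)``;
    each replicate is drawn *without replacement* by sequential weighted
    selection.  A uniform spec reduces to a simple random sample.
    Raises ``ValueError`` when the effective sample size of the weights
    is below the requested subsample size (target too narrow for the
    cohort).
    """
    n = cohort.n_individuals
    if spec.size > n:
        raise ValueError(f"size {spec.size} exceeds cohort size {n}")
    rng = np.random.default_rng(spec.seed)
    if spec.width is None:
        return [rng.choice(n, size=spec.size, replace=False) for _ in range(spec.replicates)]
    if empirical_density is None:
        empirical_density = estimate_sampling_density(
            cohort.coords, L=L, method=spec.density_adjust
        )
    if L is not None:
        target_kernel = SamplingKernel.gaussian(width=spec.width, center=spec.center)
        target = kernel_density(target_kernel, cohort.coords, L)
    else:
        d2 = ((cohort.coords - np.asarray(spec.center)) ** 2).sum(axis=1)
        target = np.exp(-d2 / (2.0 * spec.width**2)) / (2.0 * math.pi * spec.width**2)
    w = target / empirical_density
    tot = w.sum()
    ess = tot * tot / (w * w).sum()
    if ess < spec.size:
        raise ValueError(
            f"effective sample size of importance weights ({ess:.0f}) is below the "
            f"requested subsample size ({spec.size}); the target (width {spec.width}) "
            "is too narrow for this cohort"
        )
    # Sequential weighted selection without replacement via the
    # exponential-keys (Gumbel top-k) construction, which draws the same
    # distribution as repeated renormalized weighted picks but in
    # O(N log N) per replicate.
    logw = np.log(w)
    out = []
    for _ in range(spec.replicates):
        keys = logw + rng.gumbel(size=n)
        top = np.argpartition(-keys, spec.size - 1)[: spec.size]
        out.append(np.sort(top))
    return out


def cohort_sfs(cohort: Cohort, indices, sites_mask=None) -> SampleSFS:
    """Sample SFS of a subsample given by ``indices``.

    ``sites_mask`` optionally restricts to a boolean selection of sites
    (e.g. one selection class); M is the number of selected sites.
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty index set")
    if indices.min() < 0 or indices.max() >= cohort.n_individuals:
        raise ValueError("indices out of range")
    geno = cohort.genotypes if sites_mask is None else cohort.genotypes[sites_mask]
    ks = geno[:, indices].sum(axis=1)
    return SampleSFS.from_allele_counts(n=indices.size, ks=ks, M=geno.shape[0])


def generate_synthetic_cohort(
    pop: PopulationParams,
    n_individuals: int,
    sites_per_class: int,
    seed: int,
    class_s: dict[str, float] | None = None,
    class_mu: dict[str, float] | None = None,
) -> Cohort:
    """Synthetic cohort from stationary branching-process snapshots.

    For each selection class the coupled simulator (``pop`` with the
    class's ``s``; mutation influx ``rho * L**2 * mu * sites_per_class``)
    is run to stationarity and its final carriers become cohort
    individuals carrying the derived allele of their family's site.
    Non-carriers are placed uniformly to bring the cohort to
    ``n_individuals``.  Each segregating allele occupies its own site
    (infinite sites); remaining sites are monomorphic.  The true ``s``
    of every site is recorded in ``cohort.sites``.

    ``class_mu`` optionally overrides the per-site mutation rate per
    class (default: ``pop.mu`` for every class; when ``class_s`` is left
    at its default, :data:`DEFAULT_CLASS_MU` is used) so the classes
    yield comparable numbers of discoverable sites.
    """
    from .simulate import SimulationConfig, run_branching

    if class_s is None:
        class_s = DEFAULT_CLASS_S
        if class_mu is None:
            class_mu = DEFAULT_CLASS_MU
    if class_mu is None:
        class_mu = {lab: pop.mu for lab in class_s}
    if set(class_mu) != set(class_s):
        raise ValueError("class_mu labels must match class_s labels")
    rng = np.random.default_rng(seed)
    coords_parts: list[np.ndarray] = []
    geno_cols: list[tuple[int, int]] = []  # (site_row, individual_col)
    site_rows = []
    n_sites_total = sites_per_class * len(class_s)
    row0 = 0
    col = 0
    for label, s_class in class_s.items():
        for j in range(sites_per_class):
            site_rows.append({"site_id": f"{label}_{j}", "s_class": label, "s": s_class})
        if class_mu[label] > 0:
            cpop = dc_replace(pop, s=s_class, mu=class_mu[label])
            burn = 10.0 / s_class
            cfg = SimulationConfig(
                pop=cpop,
                kernels=[SamplingKernel.uniform()],
                seed=int(rng.integers(2**31)),
                sites=sites_per_class,
                burn_in=burn,
                record_every=1.0 / s_class,
                total_time=burn + 1.5 / s_class,  # only the final snapshot is used
            )
            res = run_branching(cfg)
            alleles = np.unique(res.final_alleles)
            if alleles.size > sites_per_class:
                raise ValueError(
                    f"class {label!r}: {alleles.size} segregating alleles exceed "
                    f"sites_per_class={sites_per_class}; raise sites_per_class or lower mu"
                )
            site_of = {a: row0 + j for j, a in enumerate(alleles)}
            for pos, a in zip(res.final_positions, res.final_alleles):
                coords_parts.append(pos)
                geno_cols.append((site_of[int(a)], col))
                col += 1
        row0 += sites_per_class
    n_carriers = col
    if n_carriers > n_individuals:
        raise ValueError(
            f"{n_carriers} carriers exceed n_individuals={n_individuals}; "
            "lower mu or raise the cohort size"
        )
    coords = np.empty((n_individuals, 2))
    if n_carriers:
        coords[:n_carriers] = np.vstack(coords_parts)
    coords[n_carriers:] = rng.uniform(0, pop.L, size=(n_individuals - n_carriers, 2))
    geno = np.zeros((n_sites_total, n_individuals), dtype=np.int8)
    for r, c in geno_cols:
        geno[r, c] = 1
    # shuffle individuals so carrier status is not encoded in the ordering
    perm = rng.permutation(n_individuals)
    coords = coords[perm]
    geno = geno[:, perm]
    ids = [f"ind{i:06d}" for i in range(n_individuals)]
    return Cohort(ids=ids, coords=coords, genotypes=geno, sites=pd.DataFrame(site_rows))


def resampling_report(
    cohort: Cohort,
    specs: list[ResampleSpec],
    L: float | None = None,
    by_class: bool = True,
) -> pd.DataFrame:
    """Summary statistics per design and selection class.

    Returns one row per (design, class) with mean and SD over
    replicates of the :func:`~spatialsfs.sfs.summarize_sfs` statistics,
    plus percent change of the means relative to the first (narrowest)
    design.  With a single design and replicate the means equal the
    statistics of that one subsample.
    """
    if not specs:
        raise ValueError("need at least one resampling design")
    dens = None
    if any(sp.width is not None for sp in specs):
        # estimate once with the first non-uniform spec's method
        method = next(sp.density_adjust for sp in specs if sp.width is not None)
        dens = estimate_sampling_density(cohort.coords, L=L, method=method)
    if by_class and cohort.sites is not None and "s_class" in cohort.sites:
        classes = [(lab, (cohort.sites.s_class == lab).to_numpy())
                   for lab in cohort.sites.s_class.unique()]
    else:
        classes = [("all", np.ones(cohort.n_sites, dtype=bool))]
    stat_cols = ["variant_sites", "singletons", "prop_variant", "prop_singleton",
                 "mean_freq_variant", "mean_freq_all", "het", "cmaf"]
    # Specs sharing a label pool their replicates into one design row —
    # the way multi-center resampling designs are averaged.
    class_geno = {lab: cohort.genotypes[mask] for lab, mask in classes}
    pooled: dict[tuple[str, str], dict] = {}
    design_order: list[str] = []
    for sp in specs:
        if sp.name not in design_order:
            design_order.append(sp.name)
        idx_sets = sir_resample(cohort, sp, L=L, empirical_density=dens)
        for lab, _mask in classes:
            geno = class_geno[lab]
            key = (sp.name, lab)
            entry = pooled.setdefault(
                key, {"width": sp.width, "size": sp.size, "n_reps": 0,
                      **{c: [] for c in stat_cols}})
            for idx in idx_sets:
                ks = geno[:, idx].sum(axis=1)
                summ = summarize_sfs(
                    SampleSFS.from_allele_counts(n=idx.size, ks=ks, M=geno.shape[0]))
                for c in stat_cols:
                    entry[c].append(getattr(summ, c))
            entry["n_reps"] += len(idx_sets)
    rows = []
    for (name, lab), entry in pooled.items():
        row = {"design": name, "width": entry["width"], "s_class": lab,
               "size": entry["size"], "replicates": entry["n_reps"]}
        for c in stat_cols:
            a = np.asarray(entry[c], dtype=float)
            row[f"{c}_mean"] = np.nanmean(a)
            row[f"{c}_sd"] = np.nanstd(a, ddof=1) if len(a) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    base = out[out.design == design_order[0]].set_index("s_class")
    for c in stat_cols:
        ref = out.s_class.map(base[f"{c}_mean"])
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{c}_pct_change"] = 100.0 * (out[f"{c}_mean"] - ref) / ref
    return out
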