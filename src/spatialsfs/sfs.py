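"""Observed site-frequency-spectrum containers and summary statistics.

Spectra are stored unfolded (derived-allele counts ``k`` in ``[0, n]``)
with the monomorphic class ``k = 0`` included, so "proportion of variant
sites" style statistics divide by the full number of surveyed sites
``M``.  Cumulative MAF folds at ``n/2`` via ``min(k, n-k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampleSFS", "SFSSummary", "summarize_sfs", "sfs_ratio"]


@dataclass
class SampleSFS:
    """Histogram of derived-allele counts in a sample.

    Parameters
    ----------
    n : int
        Haploid sample size.
    counts : dict[int, int]
        Map from allele count ``k`` to number of sites; ``k = 0`` holds
        the monomorphic sites.
    """

    n: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        clean: dict[int, int] = {}
        for k, c in self.counts.items():
            k, c = int(k), int(c)
            if k < 0 or k > self.n:
                raise ValueError(f"allele count {k} outside [0, n={self.n}]")
            if c < 0:
                raise ValueError("site counts must be nonnegative")
            if c:
                clean[k] = clean.get(k, 0) + c
        self.counts = clean

    @property
    def M(self) -> int:
        """Total surveyed sites, monomorphic included."""
        return sum(self.counts.values())

    @classmethod
    def from_allele_counts(cls, n: int, ks, M: int | None = None) -> "SampleSFS":
        """Build from per-site allele counts; pad with monomorphic sites to ``M``."""
        ks = np.asarray(ks, dtype=int)
        uniq, cnt = np.unique(ks, return_counts=True)
        counts = {int(k): int(c) for k, c in zip(uniq, cnt)}
        if M is not None:
            seg = len(ks)
            if M < seg:
                raise ValueError(f"M={M} smaller than number of sites provided ({seg})")
            counts[0] = counts.get(0, 0) + (M - seg)
        return cls(n=n, counts=counts)

    def normalized(self) -> pd.Series:
        """Proportion of sites at each observed k (sums to 1)."""
        m = self.M
        if m == 0:
            raise ValueError("empty SFS (M=0)")
        ks = sorted(self.counts)
        return pd.Series([self.counts[k] / m for k in ks], index=ks, name="proportion")

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.counts)
        m = self.M
        return pd.DataFrame(
            {
                "k": ks,
                "count": [self.counts[k] for k in ks],
                "probability": [self.counts[k] / m for k in ks],
            }
        )


@dataclass(frozen=True)
class SFSSummary:
    """Observed analogues of the theoretical summary expectations."""

    n: int
    M: int
    variant_sites: int
    singletons: int
    prop_variant: float
    prop_singleton: float
    mean_freq_variant: float
    mean_freq_all: float
    het: float
    cmaf: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def summarize_sfs(sfs: SampleSFS) -> SFSSummary:
    """Summary statistics of an observed spectrum.

    ``mean_freq_variant`` is reported as NaN when no site is variant.
    Heterozygosity is the exact ``sum 2 (k/n)(1 - k/n)`` form; cumulative
    MAF folds the spectrum at ``n/2``.
    """
    n, M = sfs.n, sfs.M
    if M == 0:
        raise ValueError("empty SFS (M=0)")
    ks = np.array(sorted(sfs.counts), dtype=float)
    cs = np.array([sfs.counts[int(k)] for k in ks], dtype=float)
    variant = cs[ks >= 1].sum()
    singletons = sfs.counts.get(1, 0)
    total_alleles = float((ks * cs).sum())
    het = float((cs * 2.0 * (ks / n) * (1.0 - ks / n)).sum() / M)
    cmaf = float((np.minimum(ks, n - ks) * cs).sum() / n)
    return SFSSummary(
        n=n,
        M=M,
        variant_sites=int(variant),
        singletons=int(singletons),
        prop_variant=variant / M,
        prop_singleton=singletons / M,
        mean_freq_variant=total_alleles / (n * variant) if variant else float("nan"),
        mean_freq_all=total_alleles / (n * M),
        het=het,
        cmaf=cmaf,
    )


def sfs_ratio(sfs_a: SampleSFS, sfs_b: SampleSFS) -> pd.DataFrame:
    """Per-k ratio of normalized spectra (a over b) with crossover location.

    Both spectra must share ``n`` (entries are compared per allele
    count).  Zero-denominator entries are flagged NaN.  The returned
    frame carries ``k_crossover`` in ``attrs``: the smallest variant
    count at which the ratio crosses 1 (NaN when it never does).
    """
    if sfs_a.n != sfs_b.n:
        raise ValueError(f"incompatible sample sizes n={sfs_a.n} vs n={sfs_b.n}")
    ks = sorted(set(sfs_a.counts) | set(sfs_b.counts))
    pa = sfs_a.normalized().reindex(ks, fill_value=0.0)
    pb = sfs_b.normalized().reindex(ks, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pb > 0, pa / pb, np.nan)
    out = pd.DataFrame({"k": ks, "prop_a": pa.values, "prop_b": pb.values, "ratio": ratio})
    variant = out[(out.k >= 1) & np.isfinite(out.ratio)]
    k_cross = float("nan")
    r = variant.ratio.values
    if len(r) > 1 and r[0] != 1.0:
        sign0 = r[0] < 1.0
        for kk, rr in zip(variant.k.values[1:], r[1:]):
            if (rr >= 1.0) == sign0:
                k_cross = float(kk)
                break
    out.attrs["k_crossover"] = k_cross
    return out
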