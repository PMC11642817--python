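"""Parameter containers for the spatial rare-variant model.

Conventions used throughout the package
---------------------------------------
* The habitat is an ``L x L`` two-dimensional torus (periodic boundaries).
* ``sigma`` is the root-mean-squared *two-dimensional* displacement of a
  carrier per generation; equivalently each coordinate axis receives an
  independent Gaussian increment with variance ``sigma**2 / 2`` per
  generation.
* ``w`` (kernel ``width``) is the per-axis standard deviation of the
  Gaussian sampling kernel.
* ``s`` is the heterozygous fitness cost: carriers reproduce at rate
  ``1 - s`` and die at rate 1, so a larger positive ``s`` means stronger
  negative selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PopulationParams:
    """Biological and spatial parameters of the habitat.

    Parameters
    ----------
    sigma : float
        RMS dispersal distance per generation (habitat length units).
    rho : float
        Population density (individuals per unit area).
    mu : float
        Mutation rate per site per generation.
    s : float
        Heterozygous selection coefficient (cost), ``0 < s < 1``.
    L : float
        Habitat side length; the habitat is an ``L x L`` torus.
    """

    sigma: float
    rho: float
    mu: float
    s: float
    L: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not self.mu >= 0:
            # mu=0 is allowed so null cohorts can be generated; the
            # effective-parameter theory itself requires mu > 0.
            raise ValueError(f"mu must be nonnegative, got {self.mu}")
        if not 0 < self.s < 1:
            raise ValueError(f"s must lie in (0, 1), got {self.s}")
        if not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")

    @property
    def N(self) -> float:
        """Total population size ``rho * L**2``."""
        return self.rho * self.L**2

    @property
    def neighborhood_size(self) -> float:
        """Wright's neighborhood size, ``4 * pi * sigma**2 * rho``.

        The branching (independent-carriers) approximation requires the
        number of carriers within a dispersal radius to stay small
        compared to this quantity.
        """
        import math

        return 4.0 * math.pi * self.sigma**2 * self.rho


@dataclass(frozen=True)
class SamplingKernel:
    """Spatial density of sampling probability on the torus.

    ``kind="gaussian"`` is a wrapped Gaussian with per-axis standard
    deviation ``width`` centred at ``center``; ``kind="uniform"`` samples
    every individual with equal probability (``center``/``width`` unused).
    """

    kind: str
    center: tuple[float, float] = (0.0, 0.0)
    width: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.width is None or not self.width > 0:
                raise ValueError("gaussian kernel requires width > 0")
        if len(self.center) != 2:
            raise ValueError("center must be a 2-D coordinate")

    @classmethod
    def gaussian(cls, width: float, center: tuple[float, float] = (0.0, 0.0)) -> "SamplingKernel":
        return cls(kind="gaussian", center=center, width=width)

    @classmethod
    def uniform(cls) -> "SamplingKernel":
        return cls(kind="uniform")
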