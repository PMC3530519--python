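"""Backward-in-time effective-population-size trajectories.

A single size change: the population has current size ``N0`` at
sampling (t = 0), ancestral size ``N1`` for t >= ``T`` generations ago,
and interpolates in between either exponentially, linearly, or not at
all (constant ``N0``).  The cumulative coalescent intensity
``Lambda(t) = integral_0^t du / N(u)`` and its inverse are closed-form
for all three shapes, which makes exact time-rescaled coalescent
simulation and coalescent likelihood evaluation cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

SHAPES = ("constant", "exponential", "linear")


@dataclass(frozen=True)
class DemographicTrajectory:
    """Population size N(t) backward in time (t in generations)."""

    N0: float
    N1: float = None  # type: ignore[assignment]
    T: float = 0.0
    shape: str = "constant"

    def __post_init__(self) -> None:
        if self.N1 is None:
            object.__setattr__(self, "N1", self.N0)
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.N0 <= 0 or self.N1 <= 0:
            raise ValueError("population sizes must be positive")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.shape != "constant" and self.T == 0 and self.N0 != self.N1:
            raise ValueError("size change at T=0 is ill-defined")

    @classmethod
    def constant(cls, N: float) -> "DemographicTrajectory":
        return cls(N0=N, N1=N, T=0.0, shape="constant")

    # ------------------------------------------------------------------
    def size_at(self, t: float) -> float:
        """N(t) for t >= 0 generations before sampling."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if self.shape == "constant" or t >= self.T or self.N0 == self.N1:
            return self.N1 if (t >= self.T and self.shape != "constant") else self.N0
        frac = t / self.T
        if self.shape == "exponential":
            return self.N0 * (self.N1 / self.N0) ** frac
        return self.N0 + (self.N1 - self.N0) * frac

    # ------------------------------------------------------------------
    def intensity(self, t: float) -> float:
        """Cumulative coalescent intensity integral_0^t du/N(u)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if self.shape == "constant" or self.N0 == self.N1 or self.T == 0:
            return t / self.N0 if self.shape == "constant" or self.N0 == self.N1 else t / self.N1
        head = min(t, self.T)
        if self.shape == "exponential":
            beta = math.log(self.N1 / self.N0) / self.T
            lam = (1.0 - math.exp(-beta * head)) / (self.N0 * beta)
        else:  # linear
            c = (self.N1 - self.N0) / self.T
            lam = math.log1p(c * head / self.N0) / c
        if t > self.T:
            lam += (t - self.T) / self.N1
        return lam

    def inverse_intensity(self, x: float) -> float:
        """t such that intensity(t) == x (strictly increasing, so unique)."""
        if x < 0:
            raise ValueError("x must be >= 0")
        if self.shape == "constant" or self.N0 == self.N1 or self.T == 0:
            N = self.N0 if (self.shape == "constant" or self.N0 == self.N1) else self.N1
            return x * N
        lam_T = self.intensity(self.T)
        if x >= lam_T:
            return self.T + (x - lam_T) * self.N1
        if self.shape == "exponential":
            beta = math.log(self.N1 / self.N0) / self.T
            return -math.log1p(-self.N0 * beta * x) / beta
        c = (self.N1 - self.N0) / self.T
        return self.N0 * math.expm1(c * x) / c

    # ------------------------------------------------------------------
    @property
    def is_constant(self) -> bool:
        return self.shape == "constant" or self.N0 == self.N1

    @property
    def ratio(self) -> float:
        """r = N0/N1; r < 1 marks a decline."""
        return self.N0 / self.N1
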