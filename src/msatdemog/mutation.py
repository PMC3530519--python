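"""Microsatellite mutation models: strict stepwise and two-phase.

Under the two-phase model (TPM) a mutation changes allele size by
exactly +/-1 repeat unit with probability ``p_single`` and otherwise by
a signed multistep jump whose magnitude is geometric on {1, 2, ...}.
Two field conventions parameterize that geometric law and both are
supported:

* by the *variance* of the multistep magnitude (heterozygosity-excess
  testing convention; variance 12 gives p = 0.25, mean 4), with
  magnitudes on {1, 2, ...}, and
* by its *mean* (M-ratio convention), where "multistep" means strictly
  greater than one step: magnitudes are 1 + Geometric on {2, 3, ...},
  so mean 3.5 gives p = 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class MutationModel:
    """Two-phase mutation model on the repeat-unit lattice.

    Attributes
    ----------
    p_single
        Proportion of single-step (+/-1) mutations, in [0, 1].
    p_geom
        Success parameter of the geometric multistep-magnitude law;
        irrelevant when ``p_single == 1`` (strict SMM).
    multistep_shift
        Constant added to the geometric draw: 0 puts magnitudes on
        {1, 2, ...}, 1 on {2, 3, ...} (the "greater than one step"
        convention of M-ratio critical-value simulation).
    theta
        Optional scaled mutation rate; its meaning (4*Ne*mu at
        equilibrium, 2*N0*mu inside the size-change model) is supplied
        by the caller.
    mu
        Optional per-locus per-generation mutation rate.
    """

    p_single: float
    p_geom: float = 1.0
    multistep_shift: int = 0
    theta: Optional[float] = None
    mu: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_single <= 1.0:
            raise ValueError(f"p_single must lie in [0,1], got {self.p_single}")
        if not 0.0 < self.p_geom <= 1.0:
            raise ValueError(f"p_geom must lie in (0,1], got {self.p_geom}")
        if self.multistep_shift not in (0, 1):
            raise ValueError("multistep_shift must be 0 or 1")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.mu is not None and self.mu < 0:
            raise ValueError("mu must be >= 0")

    # -- constructors ---------------------------------------------------
    @classmethod
    def smm(cls, theta: Optional[float] = None, mu: Optional[float] = None) -> "MutationModel":
        """Strict stepwise model: every mutation is +/-1."""
        return cls(p_single=1.0, p_geom=1.0, theta=theta, mu=mu)

    @classmethod
    def tpm_variance(
        cls,
        p_single: float,
        variance: float,
        theta: Optional[float] = None,
        mu: Optional[float] = None,
    ) -> "MutationModel":
        """TPM with the multistep magnitude's geometric law fixed by its
        variance: ``(1-p)/p^2 = variance``."""
        if variance <= 0:
            raise ValueError("variance must be > 0")
        p = (-1.0 + math.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)
        return cls(p_single=p_single, p_geom=p, theta=theta, mu=mu)

    @classmethod
    def tpm_mean(
        cls,
        p_single: float,
        mean: float,
        theta: Optional[float] = None,
        mu: Optional[float] = None,
    ) -> "MutationModel":
        """TPM in the M-ratio convention: multistep mutations are those
        greater than one step (magnitude >= 2) with the given mean, so
        the geometric component has mean ``mean - 1``."""
        if mean <= 2:
            raise ValueError("mean multistep size must exceed 2")
        return cls(
            p_single=p_single,
            p_geom=1.0 / (mean - 1.0),
            multistep_shift=1,
            theta=theta,
            mu=mu,
        )

    # -- properties -----------------------------------------------------
    @property
    def multistep_mean(self) -> float:
        return self.multistep_shift + 1.0 / self.p_geom

    @property
    def multistep_variance(self) -> float:
        return (1.0 - self.p_geom) / self.p_geom**2

    @property
    def step_second_moment(self) -> float:
        """E[step^2] of a single signed mutation (signs are symmetric)."""
        m2_multi = self.multistep_variance + self.multistep_mean**2
        return self.p_single * 1.0 + (1.0 - self.p_single) * m2_multi

    # -- sampling -------------------------------------------------------
    def sample_steps(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` signed mutation steps."""
        sizes = np.ones(n, dtype=np.int64)
        multi = rng.random(n) >= self.p_single
        k = int(multi.sum())
        if k:
            sizes[multi] = self.multistep_shift + rng.geometric(self.p_geom, size=k)
        signs = rng.integers(0, 2, size=n) * 2 - 1
        return sizes * signs

    def with_theta(self, theta: float) -> "MutationModel":
        return MutationModel(
            self.p_single, self.p_geom, self.multistep_shift, theta=theta, mu=self.mu
        )

    def with_mu(self, mu: float) -> "MutationModel":
        return MutationModel(
            self.p_single, self.p_geom, self.multistep_shift, theta=self.theta, mu=mu
        )
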