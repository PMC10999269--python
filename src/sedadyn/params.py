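"""Parameter containers for the metacommunity model.

The dynamical model tracks the abundance ``N_ik`` of species ``i`` at site
``k``.  Its per-capita growth rate combines a driver-dependent basal growth
rate, pairwise competition/facilitation, saturating trophic interactions and
site-to-site dispersal.  :class:`MetacommunityParams` holds every rate
constant of that model for ``S`` species at ``L`` sites and serialises
losslessly to a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

import numpy as np
import yaml

__all__ = ["NicheParams", "MetacommunityParams", "DriverSeries"]


def _as_float_array(x, shape, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    return arr


@dataclass
class NicheParams:
    """Gaussian niche response of the basal growth rate to a driver.

    ``b_i(u) = b0_i + r_i * exp(-(u - mu_i)^2 / (2 sigma_i^2))``

    r
        Maximum driver-dependent growth rate (1/year), attained at the
        niche optimum.
    mu
        Niche optimum, in driver units (e.g. degrees C).
    sigma
        Niche breadth (> 0), in driver units.
    b0
        Driver-independent baseline rate (1/year); negative values act as
        background mortality away from the optimum.
    """

    r: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    b0: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.r, dtype=float).shape
        self.r = _as_float_array(self.r, s, "r")
        self.mu = _as_float_array(self.mu, s, "mu")
        self.sigma = _as_float_array(self.sigma, s, "sigma")
        self.b0 = _as_float_array(self.b0, s, "b0")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_species(self) -> int:
        return self.r.size


@dataclass
class MetacommunityParams:
    """All rate constants of the community model for S species at L sites.

    alpha
        S x S interaction matrix; ``alpha[i, j]`` is the per-abundance
        effect of species j on the growth of species i (positive =
        competition, negative = facilitation).
    epsilon
        Trophic conversion efficiency in [0, 1].
    attack
        S x S nonnegative attack-rate matrix; ``attack[i, j]`` is consumer
        i attacking resource j.  An all-zero row and column marks a
        non-trophic species.
    handling
        Half-saturation abundance of the saturating (Holling type II)
        functional response; ``inf`` degenerates to a linear response.
    dispersal
        S x L x L nonnegative rates; ``dispersal[i, l, k]`` is the
        per-capita rate of species i moving from site l to site k.  The
        diagonal is ignored (forced to zero).
    """

    n_species: int
    n_sites: int
    growth: NicheParams
    alpha: np.ndarray
    epsilon: float = 0.0
    attack: np.ndarray | None = None
    handling: float = np.inf
    dispersal: np.ndarray | None = None

    def __post_init__(self) -> None:
        S, L = self.n_species, self.n_sites
        if S < 1 or L < 1:
            raise ValueError("n_species and n_sites must be >= 1")
        if self.growth.n_species != S:
            raise ValueError("growth parameter vectors must have length n_species")
        self.alpha = _as_float_array(self.alpha, (S, S), "alpha")
        if self.attack is None:
            self.attack = np.zeros((S, S))
        self.attack = _as_float_array(self.attack, (S, S), "attack")
        if np.any(self.attack < 0):
            raise ValueError("attack rates must be nonnegative")
        self.epsilon = float(self.epsilon)
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        self.handling = float(self.handling)
        if self.handling <= 0:
            raise ValueError("handling (half-saturation) must be positive")
        if self.dispersal is None:
            self.dispersal = np.zeros((S, L, L))
        self.dispersal = _as_float_array(self.dispersal, (S, L, L), "dispersal")
        if np.any(self.dispersal < 0):
            raise ValueError("dispersal rates must be nonnegative")
        # self-dispersal is meaningless; normalise it away
        for i in range(S):
            np.fill_diagonal(self.dispersal[i], 0.0)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_species": int(self.n_species),
            "n_sites": int(self.n_sites),
            "growth": {
                "r": self.growth.r.tolist(),
                "mu": self.growth.mu.tolist(),
                "sigma": self.growth.sigma.tolist(),
                "b0": self.growth.b0.tolist(),
            },
            "alpha": self.alpha.tolist(),
            "epsilon": float(self.epsilon),
            "attack": self.attack.tolist(),
            "handling": "inf" if np.isinf(self.handling) else float(self.handling),
            "dispersal": self.dispersal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetacommunityParams":
        g = d["growth"]
        handling = d.get("handling", "inf")
        if isinstance(handling, str):
            handling = float(handling)
        return cls(
            n_species=int(d["n_species"]),
            n_sites=int(d["n_sites"]),
            growth=NicheParams(
                r=np.asarray(g["r"], dtype=float),
                mu=np.asarray(g["mu"], dtype=float),
                sigma=np.asarray(g["sigma"], dtype=float),
                b0=np.asarray(g["b0"], dtype=float),
            ),
            alpha=np.asarray(d["alpha"], dtype=float),
            epsilon=float(d.get("epsilon", 0.0)),
            attack=np.asarray(d["attack"], dtype=float) if "attack" in d else None,
            handling=handling,
            dispersal=(
                np.asarray(d["dispersal"], dtype=float) if "dispersal" in d else None
            ),
        )

    def to_yaml(self, stream: Union[str, Path, IO, None] = None):
        payload = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if stream is None:
            return payload
        if isinstance(stream, (str, Path)):
            Path(stream).write_text(payload)
            return None
        stream.write(payload)
        return None

    @classmethod
    def from_yaml(cls, source: Union[str, Path, IO]) -> "MetacommunityParams":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        return cls.from_dict(yaml.safe_load(text))

    def copy(self) -> "MetacommunityParams":
        return MetacommunityParams.from_dict(self.to_dict())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetacommunityParams):
            return NotImplemented
        return (
            self.n_species == other.n_species
            and self.n_sites == other.n_sites
            and np.array_equal(self.growth.r, other.growth.r)
            and np.array_equal(self.growth.mu, other.growth.mu)
            and np.array_equal(self.growth.sigma, other.growth.sigma)
            and np.array_equal(self.growth.b0, other.growth.b0)
            and np.array_equal(self.alpha, other.alpha)
            and self.epsilon == other.epsilon
            and np.array_equal(self.attack, other.attack)
            and (
                self.handling == other.handling
                or (np.isinf(self.handling) and np.isinf(other.handling))
            )
            and np.array_equal(self.dispersal, other.dispersal)
        )


@dataclass
class DriverSeries:
    """Piecewise-linear environmental driver u_k(t) at one site.

    Knot times must be strictly monotone (increasing model years, or
    decreasing ages in years BP).  Evaluation clamps to the end knots, so
    the series is defined on the whole real line.
    """

    times: np.ndarray
    values: np.ndarray
    site: str = "site0"
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 1:
            raise ValueError("driver series needs at least one knot")
        d = np.diff(self.times)
        if np.any(d == 0) or (np.any(d > 0) and np.any(d < 0)):
            raise ValueError("driver knot times must be strictly monotone")
        if self.interpolation != "linear":
            raise ValueError("only linear interpolation is supported")

    def __call__(self, t) -> np.ndarray:
        # np.interp needs increasing x; it clamps beyond end knots
        if self.times.size > 1 and self.times[1] < self.times[0]:
            return np.interp(t, self.times[::-1], self.values[::-1])
        return np.interp(t, self.times, self.values)

    def to_model_time(self, age_max: float) -> "DriverSeries":
        """Convert a years-BP series to forward model time t = age_max - age."""
        t = age_max - self.times
        order = np.argsort(t)
        return DriverSeries(t[order], self.values[order], site=self.site)
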