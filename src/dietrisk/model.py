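"""Core domain types for dietary heavy-metal risk assessment.

Units are fixed throughout the package: contaminant concentrations in food
are μg/kg (dry weight), oral reference doses (RfD) and estimated daily
intakes (EDI) are μg/kg body weight/day, cancer slope factors (SF) are
(mg/kg bw/day)⁻¹, intake rates are kg food/day and body weights are kg.
The μg→mg conversion happens in exactly one place: inside the carcinogenic
risk computation (see :mod:`dietrisk.risk`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
from scipy import stats as sps

#: Contaminants with bundled toxicological reference values. The type system
#: does not restrict elements to this set — any symbol with a ToxRef works.
DEFAULT_ELEMENTS: tuple[str, ...] = ("Cd", "As", "Pb", "Cu")

_FAMILIES = ("point", "normal", "lognormal")


@dataclass(frozen=True)
class DistributionSpec:
    """Parametric model for a positive model input (concentration, intake
    rate or body weight).

    Parameters
    ----------
    family
        One of ``"point"`` (params: ``value``), ``"normal"`` (params:
        ``mean``, ``sd``) or ``"lognormal"`` (params: log-scale location
        ``mu`` and scale ``sigma``, so the median and geometric mean of
        draws are both ``exp(mu)``).
    params
        Family-specific parameter map (see above).
    truncation
        Optional ``(low, high)`` bounds in natural units. Sampling then
        rejects and redraws values outside the bounds; ``high`` may be
        ``inf``. The bounds must admit nonzero probability mass.
    """

    family: str
    params: Mapping[str, float]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        params = {k: float(v) for k, v in dict(self.params).items()}
        object.__setattr__(self, "params", params)
        if self.family == "point":
            if "value" not in params:
                raise ValueError("point distribution requires a 'value' parameter")
        elif self.family == "normal":
            if not {"mean", "sd"} <= params.keys():
                raise ValueError("normal distribution requires 'mean' and 'sd'")
            if params["sd"] < 0:
                raise ValueError("normal sd must be >= 0")
        else:  # lognormal
            if not {"mu", "sigma"} <= params.keys():
                raise ValueError("lognormal distribution requires 'mu' and 'sigma'")
            if params["sigma"] < 0:
                raise ValueError("lognormal sigma must be >= 0")
        if self.truncation is not None:
            low, high = (float(b) for b in self.truncation)
            if not low < high:
                raise ValueError(f"truncation bounds must satisfy low < high, got ({low}, {high})")
            object.__setattr__(self, "truncation", (low, high))
            if self._mass(low, high) <= 0.0:
                raise ValueError(
                    f"truncation bounds ({low}, {high}) admit no probability mass"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": value})

    @classmethod
    def normal(cls, mean: float, sd: float,
               truncation: tuple[float, float] | None = None) -> "DistributionSpec":
        return cls("normal", {"mean": mean, "sd": sd}, truncation)

    @classmethod
    def lognormal(cls, mu: float, sigma: float,
                  truncation: tuple[float, float] | None = None) -> "DistributionSpec":
        return cls("lognormal", {"mu": mu, "sigma": sigma}, truncation)

    @classmethod
    def lognormal_from_mean_cv(cls, mean: float, cv: float,
                               truncation: tuple[float, float] | None = None
                               ) -> "DistributionSpec":
        """Lognormal with a given arithmetic mean and coefficient of variation."""
        if mean <= 0:
            raise ValueError("lognormal mean must be > 0")
        if cv < 0:
            raise ValueError("cv must be >= 0")
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return cls.lognormal(mu, math.sqrt(sigma2), truncation)

    # -- analytic summaries (untruncated) ----------------------------------

    def mean(self) -> float:
        """Analytic arithmetic mean (untruncated specs only)."""
        self._require_untruncated("mean")
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "normal":
            return p["mean"]
        return math.exp(p["mu"] + p["sigma"] ** 2 / 2.0)

    def sd(self) -> float:
        """Analytic arithmetic standard deviation (untruncated specs only)."""
        self._require_untruncated("sd")
        p = self.params
        if self.family == "point":
            return 0.0
        if self.family == "normal":
            return p["sd"]
        s2 = p["sigma"] ** 2
        return math.sqrt(math.expm1(s2) * math.exp(2.0 * p["mu"] + s2))

    def median(self) -> float:
        """Analytic median (untruncated specs only)."""
        self._require_untruncated("median")
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "normal":
            return p["mean"]
        return math.exp(p["mu"])

    def _require_untruncated(self, what: str) -> None:
        if self.truncation is not None:
            raise NotImplementedError(
                f"analytic {what} is not provided for truncated distributions"
            )

    # -- sampling ----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values; truncation handled by rejection resampling."""
        draws = self._draw(rng, size)
        if self.truncation is None:
            return draws
        low, high = self.truncation
        for _ in range(1000):
            bad = (draws < low) | (draws > high)
            n_bad = int(bad.sum())
            if n_bad == 0:
                return draws
            draws[bad] = self._draw(rng, n_bad)
        raise RuntimeError(
            f"rejection sampling failed to respect truncation {self.truncation} "
            f"after 1000 rounds (family={self.family}, params={self.params})"
        )

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(size, p["value"], dtype=float)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        return rng.lognormal(p["mu"], p["sigma"], size)

    def _mass(self, low: float, high: float) -> float:
        p = self.params
        if self.family == "point" or (self.family == "normal" and p["sd"] == 0):
            v = p["value"] if self.family == "point" else p["mean"]
            return 1.0 if low <= v <= high else 0.0
        if self.family == "lognormal" and p["sigma"] == 0:
            v = math.exp(p["mu"])
            return 1.0 if low <= v <= high else 0.0
        if self.family == "normal":
            dist = sps.norm(p["mean"], p["sd"])
        else:
            dist = sps.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        return float(dist.cdf(high) - dist.cdf(low))


#: An input model: either a fixed point value or a DistributionSpec.
InputModel = Union[float, DistributionSpec]


@dataclass(frozen=True)
class ToxRef:
    """Toxicological reference values for one contaminant.

    ``rfd`` is the oral reference dose (μg/kg bw/day), ``mac`` the maximum
    allowable concentration in the food commodity (μg/kg), and ``sf`` the
    cancer slope factor in (mg/kg bw/day)⁻¹ — ``None`` for non-carcinogens.
    ``cr_acceptable_low``/``cr_acceptable_high`` bound the conventional
    1e-6–1e-4 acceptability band for lifetime carcinogenic risk.
    """

    element: str
    rfd: float
    mac: float
    sf: float | None = None
    cr_acceptable_low: float = 1.0e-6
    cr_acceptable_high: float = 1.0e-4

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ValueError(f"{self.element}: rfd must be > 0")
        if self.mac <= 0:
            raise ValueError(f"{self.element}: mac must be > 0")
        if self.sf is not None and self.sf < 0:
            raise ValueError(f"{self.element}: sf must be >= 0 when present")
        if not self.cr_acceptable_low < self.cr_acceptable_high:
            raise ValueError(f"{self.element}: risk band bounds out of order")


@dataclass(frozen=True)
class ConcentrationSample:
    """One measured contaminant concentration in one food sample.

    ``strata`` carries free-form labels (province, region, source, ...)
    used for grouping; keys are not interpreted by the core model.
    """

    sample_id: str
    element: str
    concentration: float  # μg/kg dry weight
    strata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"sample {self.sample_id!r} ({self.element}): "
                f"concentration must be >= 0, got {self.concentration}"
            )
        object.__setattr__(self, "strata", dict(self.strata))


@dataclass(frozen=True)
class StratumSummary:
    """Sufficient statistics for a lognormal concentration model in one
    stratum: sample count, geometric mean, arithmetic SD, and range
    (all concentrations in μg/kg)."""

    stratum: str
    element: str
    n: int
    gm: float
    sd: float
    cmin: float
    cmax: float

    def __post_init__(self) -> None:
        label = f"{self.stratum}/{self.element}"
        if self.n < 1:
            raise ValueError(f"{label}: n must be >= 1")
        if self.sd < 0:
            raise ValueError(f"{label}: sd must be >= 0")
        if not self.cmin <= self.gm <= self.cmax:
            raise ValueError(
                f"{label}: requires cmin <= gm <= cmax, "
                f"got ({self.cmin}, {self.gm}, {self.cmax})"
            )


@dataclass(frozen=True)
class PopulationGroup:
    """Exposure parameters for one consumer stratum.

    ``ir`` (intake rate, kg/day) and ``bw`` (body weight, kg) may each be a
    point value or a :class:`DistributionSpec`. ``ef`` is exposure frequency
    (days/year), ``ed`` exposure duration (years) and ``at`` averaging time
    (days); ``at=None`` defaults to ``ed × 365``, making ef·ed/at = 1 so the
    chronic intake equals concentration × IR/BW.
    """

    name: str
    ir: InputModel
    bw: InputModel
    ef: float = 365.0
    ed: float = 30.0
    at: float | None = None

    def __post_init__(self) -> None:
        for label, v in (("ef", self.ef), ("ed", self.ed)):
            if v <= 0:
                raise ValueError(f"group {self.name!r}: {label} must be > 0")
        if self.ef > 366:
            raise ValueError(f"group {self.name!r}: ef must be <= 366 days/year")
        if self.at is not None and self.at <= 0:
            raise ValueError(f"group {self.name!r}: at must be > 0")
        for label, v in (("ir", self.ir), ("bw", self.bw)):
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"group {self.name!r}: point {label} must be > 0")

    @property
    def at_days(self) -> float:
        """Averaging time in days (``ed × 365`` when not set explicitly)."""
        return self.at if self.at is not None else self.ed * 365.0

    @property
    def time_factor(self) -> float:
        """The dimensionless chronic-exposure factor ef·ed/at."""
        return self.ef * self.ed / self.at_days
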