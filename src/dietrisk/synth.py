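"""Synthetic concentration datasets and population parameter draws.

The generator emulates a multi-province food-contamination survey: per
stratum and element, concentrations are drawn from a lognormal fitted by
moment matching to the published sufficient statistics (geometric mean,
arithmetic SD), optionally truncated to the observed range. Randomness is
split into one independent stream per stratum × element, keyed by a stable
hash, so adding strata to a spec never reshuffles existing ones.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .model import ConcentrationSample, DistributionSpec, InputModel, PopulationGroup, StratumSummary


def fit_lognormal_from_summary(summary: StratumSummary,
                               truncate: bool = False) -> DistributionSpec:
    """Fit a lognormal to a (GM, arithmetic SD) summary.

    The geometric mean pins the log-scale location, μ = ln(gm). The
    log-scale σ is then the unique nonnegative root of the arithmetic
    variance identity sd² = (e^{σ²} − 1)·e^{2μ+σ²}: substituting
    t = e^{σ²} gives t(t−1) = (sd/gm)², whose admissible root is
    t = (1 + √(1 + 4(sd/gm)²))/2. The right-hand side is strictly
    increasing in σ, so the root is unique; sd = 0 degenerates to a point
    mass at the GM.

    With ``truncate=True`` the fitted distribution is clipped to the
    summary's observed (min, max) by rejection sampling; note truncation
    perturbs the matched moments, so it is off by default.
    """
    if summary.gm <= 0:
        raise ValueError(f"{summary.stratum}/{summary.element}: gm must be > 0")
    if summary.sd < 0:
        raise ValueError(f"{summary.stratum}/{summary.element}: sd must be >= 0")
    mu = math.log(summary.gm)
    v = (summary.sd / summary.gm) ** 2
    t = (1.0 + math.sqrt(1.0 + 4.0 * v)) / 2.0
    if t < 1.0:
        raise RuntimeError("moment equation has no root with sigma >= 0")  # unreachable
    sigma = math.sqrt(math.log(t))
    truncation = (summary.cmin, summary.cmax) if truncate else None
    return DistributionSpec.lognormal(mu, sigma, truncation)


@dataclass(frozen=True)
class SyntheticSpec:
    """Target summaries for a synthetic survey.

    ``targets`` are the per-stratum cells actually generated; ``national``
    optionally carries pooled all-strata summaries per element (used for
    fitting exposure-side concentration models, not for generation).
    ``n_override`` replaces every cell's sample count, and ``truncate``
    clips draws to each cell's observed range.
    """

    targets: tuple[StratumSummary, ...]
    seed: int = 0
    stratum_key: str = "stratum"
    n_override: int | None = None
    truncate: bool = False
    national: dict[str, StratumSummary] = field(default_factory=dict)

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return SyntheticSpec(self.targets, int(seed), self.stratum_key,
                             self.n_override, self.truncate, dict(self.national))

    def strata(self) -> list[str]:
        out: list[str] = []
        for t in self.targets:
            if t.stratum not in out:
                out.append(t.stratum)
        return out


def stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent, label-addressed random stream.

    The stream for a given (seed, labels) pair is fixed regardless of what
    other streams are drawn from, which keeps generated strata stable when
    a spec grows.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(lab.encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_samples(spec: SyntheticSpec) -> list[ConcentrationSample]:
    """Draw a full synthetic survey dataset from a spec.

    For each stratum × element cell, ``n`` concentrations are drawn from
    the moment-matched lognormal (truncated to the cell's range when the
    spec says so). Sample ids are shared across elements within a stratum,
    mimicking one physical sample measured for every element; element
    draws are independent (no within-sample correlation is modelled).
    """
    samples: list[ConcentrationSample] = []
    for target in spec.targets:
        n = spec.n_override if spec.n_override is not None else target.n
        dist = fit_lognormal_from_summary(target, truncate=spec.truncate)
        rng = stream(spec.seed, target.stratum, target.element)
        draws = dist.sample(rng, n)
        slug = target.stratum.replace(" ", "_")
        for i, value in enumerate(draws):
            samples.append(
                ConcentrationSample(
                    sample_id=f"{slug}-{i + 1:03d}",
                    element=target.element,
                    concentration=float(value),
                    strata={spec.stratum_key: target.stratum},
                )
            )
    return samples


def generate_population(group: PopulationGroup, n_draws: int,
                        seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired (IR, BW) vectors for a population group.

    IR and BW use independent streams; point values are replicated. Draws
    are forced positive: nonpositive values (possible for a normal model)
    are resampled, i.e. the model is truncated at zero from below.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ir = _draw_input(group.ir, n_draws, stream(seed, group.name, "ir"))
    bw = _draw_input(group.bw, n_draws, stream(seed, group.name, "bw"))
    return ir, bw


def _draw_input(model: InputModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, (int, float)):
        return np.full(n, float(model))
    draws = model.sample(rng, n)
    for _ in range(1000):
        bad = draws <= 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            return draws
        draws[bad] = model.sample(rng, n_bad)
    raise RuntimeError("could not draw positive values from input model")
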