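"""Summary statistics and regulatory screening for concentration datasets."""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np

from .model import ConcentrationSample, StratumSummary, ToxRef

POOLED_LABEL = "national"


def summarize(samples: Iterable[ConcentrationSample],
              by: str | None = None,
              pooled_label: str = POOLED_LABEL) -> list[StratumSummary]:
    """Per-stratum, per-element sufficient statistics.

    ``by`` names the stratum label to group on (e.g. ``"province"``);
    ``None`` pools everything under ``pooled_label``. The central tendency
    is the geometric mean, exp(mean of logs), so zero or negative
    concentrations are a hard error; spread is the arithmetic sample SD
    (ddof=1; zero for singletons).
    """
    groups: dict[tuple[str, str], list[ConcentrationSample]] = defaultdict(list)
    for s in samples:
        if s.concentration <= 0:
            raise ValueError(
                f"sample {s.sample_id!r} ({s.element}) has non-positive "
                f"concentration {s.concentration}; geometric mean undefined"
            )
        stratum = pooled_label if by is None else s.strata.get(by, "<missing>")
        groups[(stratum, s.element)].append(s)

    out = []
    for (stratum, element), members in groups.items():
        x = np.array([m.concentration for m in members], dtype=float)
        gm = float(np.exp(np.mean(np.log(x))))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        out.append(
            StratumSummary(
                stratum=stratum, element=element, n=int(x.size),
                gm=gm, sd=sd, cmin=float(x.min()), cmax=float(x.max()),
            )
        )
    return out


def geometric_mean(values: Iterable[float]) -> float:
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of empty collection")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def screen_mac(samples: Iterable[ConcentrationSample],
               tox: Mapping[str, ToxRef]) -> dict[str, list[ConcentrationSample]]:
    """Flag samples whose concentration strictly exceeds the element's MAC.

    Returns element → list of exceeding samples, with an (empty) entry for
    every element present in the data. Equality with the MAC counts as
    compliant. Elements without a MAC entry are a hard error.
    """
    report: dict[str, list[ConcentrationSample]] = {}
    for s in samples:
        if s.element not in tox:
            raise KeyError(f"no MAC reference for element {s.element!r}")
        report.setdefault(s.element, [])
        if s.concentration > tox[s.element].mac:
            report[s.element].append(s)
    return report
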