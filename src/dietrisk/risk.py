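"""Risk characterization: hazard quotients/index and carcinogenic risk.

Non-carcinogenic risk per element is the hazard quotient HQ = EDI/RfD
(both in μg/kg bw/day); the hazard index HI sums HQs across co-occurring
elements. Carcinogenic risk per carcinogen is CR = EDI[mg/kg bw/day] × SF,
with SF the linear cancer slope factor in (mg/kg bw/day)⁻¹ — the single
μg→mg conversion in the package happens here. TCR sums CRs. Conventional
decision thresholds: HQ/HI flagged above 1; CR/TCR negligible below 1e-6,
unacceptable above 1e-4, acceptable in between (all comparisons strict,
boundary values count as compliant).

All operations apply elementwise over Monte Carlo draw vectors, so HI and
TCR percentiles come from the summed draw distribution, never from summed
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exposure import DEFAULT_LEVELS, ExposureResult, percentile_map
from .model import ToxRef

logger = logging.getLogger(__name__)

UG_TO_MG = 1.0e-3


def hazard_quotient(edi, rfd: float):
    """HQ = EDI/RfD, elementwise over draw vectors."""
    if rfd <= 0:
        raise ValueError(f"rfd must be > 0, got {rfd}")
    return np.asarray(edi, dtype=float) / rfd if np.ndim(edi) else float(edi) / rfd


def hazard_index(hqs: Sequence | Mapping):
    """HI = Σ HQ over elements; draw-wise over vectors."""
    values = list(hqs.values()) if isinstance(hqs, Mapping) else list(hqs)
    if not values:
        raise ValueError("hazard_index requires at least one HQ")
    total = values[0] if np.ndim(values[0]) else float(values[0])
    for v in values[1:]:
        total = total + (v if np.ndim(v) else float(v))
    return total


def carcinogenic_risk(edi, sf: float):
    """CR = (EDI converted to mg/kg bw/day) × SF, elementwise."""
    if sf < 0:
        raise ValueError(f"sf must be >= 0, got {sf}")
    scaled = np.asarray(edi, dtype=float) * UG_TO_MG if np.ndim(edi) else float(edi) * UG_TO_MG
    return scaled * sf


def total_carcinogenic_risk(crs: Sequence | Mapping):
    """TCR = Σ CR over carcinogens; draw-wise over vectors."""
    values = list(crs.values()) if isinstance(crs, Mapping) else list(crs)
    if not values:
        raise ValueError("total_carcinogenic_risk requires at least one CR")
    total = values[0] if np.ndim(values[0]) else float(values[0])
    for v in values[1:]:
        total = total + (v if np.ndim(v) else float(v))
    return total


def contribution_shares(components: Mapping[str, float]) -> dict[str, float]:
    """Fraction of the summed metric attributable to each component."""
    if any(v < 0 for v in components.values()):
        raise ValueError("components must be nonnegative")
    total = float(sum(components.values()))
    if total <= 0:
        raise ValueError("cannot compute shares of a zero total")
    return {k: float(v) / total for k, v in components.items()}


def classify_hazard(value: float) -> bool:
    """True when a hazard quotient/index exceeds 1 (strict)."""
    return bool(value > 1.0)


def classify_cancer_risk(value: float, low: float = 1.0e-6,
                         high: float = 1.0e-4) -> str:
    """Three-way classification of a lifetime cancer risk.

    ``"negligible"`` below ``low``, ``"unacceptable"`` above ``high``,
    ``"acceptable"`` in the closed band between them.
    """
    if value < low:
        return "negligible"
    if value > high:
        return "unacceptable"
    return "acceptable"


@dataclass(frozen=True)
class RiskResult:
    """Risk characterization for one population group.

    ``hq``/``cr`` map element → draw vector; ``hi``/``tcr`` are the summed
    draw vectors. Means, percentile maps, threshold flags (evaluated on
    means) and contribution shares (of mean HI and mean TCR) are
    precomputed for reporting.
    """

    group: str
    hq: dict[str, np.ndarray]
    hi: np.ndarray
    cr: dict[str, np.ndarray]
    tcr: np.ndarray | None
    hq_mean: dict[str, float]
    hi_mean: float
    cr_mean: dict[str, float]
    tcr_mean: float | None
    hq_percentiles: dict[str, dict[float, float]]
    hi_percentiles: dict[float, float]
    cr_percentiles: dict[str, dict[float, float]]
    tcr_percentiles: dict[float, float] | None
    flags: dict[str, object]
    hi_shares: dict[str, float]
    tcr_shares: dict[str, float]


def assess(exposures: Mapping[str, ExposureResult],
           tox: Mapping[str, ToxRef],
           levels: Sequence[float] = DEFAULT_LEVELS) -> RiskResult:
    """Full risk characterization from per-element exposure results.

    Every element must resolve to exactly one ToxRef; elements lacking a
    slope factor are excluded from the carcinogenic family with a logged
    notice. All exposures must belong to the same group and share an
    iteration count.
    """
    if not exposures:
        raise ValueError("assess requires at least one exposure result")
    groups = {e.group for e in exposures.values()}
    if len(groups) > 1:
        raise ValueError(f"exposures span multiple groups: {sorted(groups)}")
    sizes = {e.draws.size for e in exposures.values()}
    if len(sizes) > 1:
        raise ValueError("exposure draw vectors have mismatched lengths")

    hq: dict[str, np.ndarray] = {}
    cr: dict[str, np.ndarray] = {}
    for element, exp in exposures.items():
        if element not in tox:
            raise KeyError(f"no toxicological reference for element {element!r}")
        ref = tox[element]
        hq[element] = hazard_quotient(exp.draws, ref.rfd)
        if ref.sf is None:
            logger.info("element %s has no slope factor; excluded from CR/TCR",
                        element)
        else:
            cr[element] = carcinogenic_risk(exp.draws, ref.sf)

    hi = hazard_index(hq)
    tcr = total_carcinogenic_risk(cr) if cr else None

    hq_mean = {el: float(v.mean()) for el, v in hq.items()}
    cr_mean = {el: float(v.mean()) for el, v in cr.items()}
    hi_mean = float(hi.mean())
    tcr_mean = float(tcr.mean()) if tcr is not None else None

    flags: dict[str, object] = {
        **{f"HQ>1 [{el}]": classify_hazard(m) for el, m in hq_mean.items()},
        "HI>1": classify_hazard(hi_mean),
        **{f"CR [{el}]": classify_cancer_risk(m, tox[el].cr_acceptable_low,
                                              tox[el].cr_acceptable_high)
           for el, m in cr_mean.items()},
    }
    if tcr_mean is not None:
        flags["TCR"] = classify_cancer_risk(tcr_mean)

    return RiskResult(
        group=next(iter(groups)),
        hq=hq,
        hi=hi,
        cr=cr,
        tcr=tcr,
        hq_mean=hq_mean,
        hi_mean=hi_mean,
        cr_mean=cr_mean,
        tcr_mean=tcr_mean,
        hq_percentiles={el: percentile_map(v, levels) for el, v in hq.items()},
        hi_percentiles=percentile_map(hi, levels),
        cr_percentiles={el: percentile_map(v, levels) for el, v in cr.items()},
        tcr_percentiles=percentile_map(tcr, levels) if tcr is not None else None,
        flags=flags,
        hi_shares=contribution_shares(hq_mean),
        tcr_shares=contribution_shares(cr_mean) if cr_mean else {},
    )
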