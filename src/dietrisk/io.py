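"""Readers and writers for concentration tables, toxicological reference
tables, population-group configs and synthetic-data specs.

Bundled defaults (FAO/WHO MACs, USEPA RfDs/SFs, the Nepal rice survey
summary targets, and assumption-based population groups) live under
``dietrisk/data`` and are returned when ``source`` is omitted.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConcentrationSample,
    DistributionSpec,
    InputModel,
    PopulationGroup,
    StratumSummary,
    ToxRef,
)

SAMPLE_COLUMNS = ("sample_id", "element", "concentration_ug_per_kg")


def _data_path(name: str):
    return resources.files("dietrisk.data").joinpath(name)


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


# ---------------------------------------------------------------------------
# Toxicological reference table


def load_tox_table(source=None) -> dict[str, ToxRef]:
    """Load a toxicological reference table into an element-keyed dict.

    Expected columns: ``element``, ``rfd_ug_per_kg_day``, ``mac_ug_per_kg``
    and optionally ``sf_per_mg_kg_day`` (blank for non-carcinogens). With no
    ``source`` the bundled FAO/WHO + USEPA defaults are returned.
    """
    if source is None:
        with resources.as_file(_data_path("tox_fao_who.csv")) as p:
            df = pd.read_csv(p)
    else:
        df = _read_table(source)
    if df.empty:
        return {}
    required = {"element", "rfd_ug_per_kg_day", "mac_ug_per_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tox table missing columns: {sorted(missing)}")
    table: dict[str, ToxRef] = {}
    for _, row in df.iterrows():
        element = str(row["element"])
        if element in table:
            raise ValueError(f"duplicate element {element!r} in tox table")
        sf = None
        if "sf_per_mg_kg_day" in df.columns and pd.notna(row["sf_per_mg_kg_day"]):
            sf = float(row["sf_per_mg_kg_day"])
        table[element] = ToxRef(
            element=element,
            rfd=float(row["rfd_ug_per_kg_day"]),
            mac=float(row["mac_ug_per_kg"]),
            sf=sf,
        )
    return table


# ---------------------------------------------------------------------------
# Concentration samples


def read_samples(source) -> list[ConcentrationSample]:
    """Parse a concentration CSV into samples.

    The file must have ``sample_id``, ``element`` and
    ``concentration_ug_per_kg`` columns; any other columns become stratum
    labels. Rows with non-numeric or negative concentrations are rejected
    with their (1-based, header-inclusive) row numbers; duplicate
    (sample_id, element) pairs are a hard error.
    """
    df = _read_table(source)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    stratum_cols = [c for c in df.columns if c not in SAMPLE_COLUMNS]

    conc = pd.to_numeric(df["concentration_ug_per_kg"], errors="coerce")
    bad: list[str] = []
    for idx in df.index[conc.isna() | (conc < 0)]:
        rowno = int(idx) + 2  # +1 header, +1 one-based
        raw = df.at[idx, "concentration_ug_per_kg"]
        bad.append(f"row {rowno}: invalid concentration {raw!r}")
    if bad:
        raise ValueError("rejected rows:\n" + "\n".join(bad))

    dup = df.duplicated(subset=["sample_id", "element"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "element"]].itertuples(index=False)
        listing = ", ".join(f"({s!r}, {e!r})" for s, e in pairs)
        raise ValueError(f"duplicate (sample_id, element) pairs: {listing}")

    samples = []
    for idx, row in df.iterrows():
        strata = {c: str(row[c]) for c in stratum_cols if pd.notna(row[c])}
        samples.append(
            ConcentrationSample(
                sample_id=str(row["sample_id"]),
                element=str(row["element"]),
                concentration=float(conc[idx]),
                strata=strata,
            )
        )
    return samples


def samples_to_frame(samples: Iterable[ConcentrationSample]) -> pd.DataFrame:
    samples = list(samples)
    stratum_cols: list[str] = []
    for s in samples:
        for k in s.strata:
            if k not in stratum_cols:
                stratum_cols.append(k)
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id}
        for c in stratum_cols:
            row[c] = s.strata.get(c, "")
        row["element"] = s.element
        row["concentration_ug_per_kg"] = s.concentration
        rows.append(row)
    cols = ["sample_id", *stratum_cols, "element", "concentration_ug_per_kg"]
    return pd.DataFrame(rows, columns=cols)


def write_samples(samples: Iterable[ConcentrationSample], target) -> None:
    """Write samples as CSV (inverse of :func:`read_samples` on valid data)."""
    samples_to_frame(samples).to_csv(target, index=False)


# ---------------------------------------------------------------------------
# Population groups


def _parse_input_model(raw, context: str) -> InputModel:
    if isinstance(raw, (int, float)):
        return float(raw)
    if not isinstance(raw, dict):
        raise ValueError(f"{context}: expected a number or a distribution mapping")
    raw = dict(raw)
    family = raw.pop("family", None)
    truncation = raw.pop("truncation", None)
    if truncation is not None:
        truncation = (float(truncation[0]), float(truncation[1]))
    if family is None:
        raise ValueError(f"{context}: distribution mapping requires a 'family' key")
    if family == "point":
        return DistributionSpec.point(float(raw["value"]))
    if family == "normal":
        return DistributionSpec.normal(float(raw["mean"]), float(raw["sd"]), truncation)
    if family == "lognormal":
        if "mu" in raw:
            return DistributionSpec.lognormal(
                float(raw["mu"]), float(raw["sigma"]), truncation
            )
        return DistributionSpec.lognormal_from_mean_cv(
            float(raw["mean"]), float(raw["cv"]), truncation
        )
    raise ValueError(f"{context}: unknown distribution family {family!r}")


def read_groups(source=None) -> list[PopulationGroup]:
    """Load population groups from a YAML config.

    Layout: a top-level ``groups`` mapping of name → {ir, bw, ef, ed, at},
    where ``ir``/``bw`` are numbers or distribution mappings
    (``{family: lognormal, mean: .., cv: ..}`` or ``{family: lognormal,
    mu: .., sigma: ..}``; ``normal`` takes ``mean``/``sd``). With no
    ``source`` the bundled assumption-based Nepal groups are returned.
    """
    doc = _load_yaml(source, "population_groups.yaml")
    groups_raw = doc.get("groups")
    if not isinstance(groups_raw, dict) or not groups_raw:
        raise ValueError("groups config requires a non-empty 'groups' mapping")
    groups = []
    for name, g in groups_raw.items():
        g = dict(g)
        groups.append(
            PopulationGroup(
                name=str(name),
                ir=_parse_input_model(g["ir"], f"group {name!r} ir"),
                bw=_parse_input_model(g["bw"], f"group {name!r} bw"),
                ef=float(g.get("ef", 365)),
                ed=float(g.get("ed", 30)),
                at=float(g["at"]) if "at" in g and g["at"] is not None else None,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Synthetic spec (summary targets)


def _load_yaml(source, bundled_name: str) -> dict:
    if source is None:
        text = _data_path(bundled_name).read_text(encoding="utf-8")
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, _io.IOBase):
        text = source.read()
    elif isinstance(source, dict):
        return source
    else:
        raise TypeError(f"cannot load YAML from {type(source)!r}")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    return doc


def read_summary_targets(source=None):
    """Load per-stratum summary targets for the synthetic generator.

    Returns a :class:`dietrisk.synth.SyntheticSpec`. With no ``source``
    the bundled Nepal rice-survey targets (seven provinces plus the
    pooled national row) are used.
    """
    from .synth import SyntheticSpec  # local import to avoid a cycle

    doc = _load_yaml(source, "nepal_table1.yaml")
    stratum_key = str(doc.get("stratum_key", "stratum"))
    targets: list[StratumSummary] = []
    for stratum, block in doc.get("strata", {}).items():
        block = dict(block)
        n = int(block.pop("n"))
        for element, cell in block.items():
            targets.append(_cell_to_summary(str(stratum), str(element), n, cell))
    national: dict[str, StratumSummary] = {}
    nat = doc.get("national")
    if nat:
        nat = dict(nat)
        n = int(nat.pop("n"))
        for element, cell in nat.items():
            national[str(element)] = _cell_to_summary("national", str(element), n, cell)
    if not targets and not national:
        raise ValueError("summary-target config defines no strata")
    return SyntheticSpec(
        targets=tuple(targets),
        seed=int(doc.get("seed", 0)),
        stratum_key=stratum_key,
        national=national,
    )


def _cell_to_summary(stratum: str, element: str, n: int, cell) -> StratumSummary:
    cell = dict(cell)
    return StratumSummary(
        stratum=stratum,
        element=element,
        n=n,
        gm=float(cell["gm"]),
        sd=float(cell["sd"]),
        cmin=float(cell["min"]),
        cmax=float(cell["max"]),
    )


# ---------------------------------------------------------------------------
# Report frames


def summaries_to_frame(summaries: Sequence[StratumSummary],
                       stratum_key: str = "stratum") -> pd.DataFrame:
    """Arrange stratum summaries as a survey-style table (one row per
    stratum × element: n, GM, SD, min, max)."""
    rows = [
        {
            stratum_key: s.stratum,
            "element": s.element,
            "n": s.n,
            "gm_ug_per_kg": s.gm,
            "sd_ug_per_kg": s.sd,
            "min_ug_per_kg": s.cmin,
            "max_ug_per_kg": s.cmax,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
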