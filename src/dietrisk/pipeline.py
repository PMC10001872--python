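"""End-to-end pipeline: ingest/synthesize → summarize → simulate → risk.

Driven by a small YAML/dict config; writes a survey-style summary table,
an exposure table (mean + percentile columns per element × group), a risk
table with threshold flags and contribution shares, and a reproducibility
manifest. A fixed config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as drio
from .exposure import DEFAULT_LEVELS, ExposureResult, edi_mcs
from .model import ConcentrationSample, PopulationGroup, StratumSummary, ToxRef
from .risk import RiskResult, assess
from .stats import POOLED_LABEL, screen_mac, summarize
from .synth import fit_lognormal_from_summary, generate_samples


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def load_config(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("pipeline config must be a YAML mapping")
    return doc


def _level_key(level: float) -> str:
    return f"P{level:g}"


def run_pipeline(config: Mapping, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline described by ``config``.

    Writes ``summary.csv``, ``exposure.csv``, ``risk.csv`` and
    ``manifest.json`` into ``out_dir`` and returns the manifest dict.
    ``seed`` overrides the config's seed when given. On failure, partial
    outputs are removed before the exception propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(dict(config), out_dir, seed, written)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise


def _run(config: dict, out_dir: Path, seed_override: int | None,
         written: list[Path]) -> dict:
    seed = int(seed_override if seed_override is not None
               else config.get("seed", 0))
    iterations = int(config.get("iterations", 10_000))
    levels = tuple(float(v) for v in config.get("levels", DEFAULT_LEVELS))
    mode = str(config.get("mode", "fitted"))
    if mode not in ("fitted", "resample"):
        raise ConfigError(f"unknown concentration mode {mode!r}")

    tox_src = config.get("tox", "default")
    tox = drio.load_tox_table(None if tox_src == "default" else tox_src)
    if not tox:
        raise ConfigError("toxicological reference table is empty")

    samples, stratum_key = _resolve_data(config, seed)

    elements = config.get("elements")
    if elements is not None:
        elements = [str(e) for e in elements]
        unknown = [e for e in elements if e not in tox]
        if unknown:
            raise ConfigError(
                f"elements not present in the toxicological table: {unknown}"
            )
        samples = [s for s in samples if s.element in elements]
        if not samples:
            raise ConfigError("no samples remain after element filtering")
    missing_tox = sorted({s.element for s in samples} - set(tox))
    if missing_tox:
        raise ConfigError(
            f"elements in data without toxicological reference: {missing_tox}"
        )

    groups_src = config.get("groups", "default")
    groups = drio.read_groups(None if groups_src == "default" else groups_src)

    # --- summary + MAC screening
    by_stratum = summarize(samples, by=stratum_key)
    pooled = summarize(samples, by=None)
    exceed = screen_mac(samples, tox)
    summary_df = drio.summaries_to_frame([*by_stratum, *pooled], stratum_key)
    summary_df = summary_df.sort_values([stratum_key, "element"],
                                        kind="stable").reset_index(drop=True)
    summary_df["mac_ug_per_kg"] = [tox[e].mac for e in summary_df["element"]]
    pooled_exceed = {el: len(v) for el, v in exceed.items()}
    summary_df["n_above_mac"] = [
        pooled_exceed[e] if s == POOLED_LABEL else
        sum(1 for smp in exceed[e] if smp.strata.get(stratum_key) == s)
        for s, e in zip(summary_df[stratum_key], summary_df["element"])
    ]

    # --- national concentration model (one model for all groups)
    pooled_by_element = {s.element: s for s in pooled}
    conc_models: dict[str, object] = {}
    for element, summ in pooled_by_element.items():
        if mode == "fitted":
            conc_models[element] = fit_lognormal_from_summary(summ)
        else:
            conc_models[element] = np.array(
                [s.concentration for s in samples if s.element == element]
            )

    # --- exposure + risk
    exposures: dict[str, dict[str, ExposureResult]] = {}
    risks: dict[str, RiskResult] = {}
    for group in groups:
        per_el = {
            element: edi_mcs(conc_models[element], group, iterations, seed,
                             levels, element=element, mode=mode)
            for element in sorted(conc_models)
        }
        exposures[group.name] = per_el
        risks[group.name] = assess(per_el, tox, levels)

    exposure_df = _exposure_frame(exposures, levels)
    risk_df = _risk_frame(risks, levels)

    # --- write outputs
    paths = {name: out_dir / f"{name}.csv"
             for name in ("summary", "exposure", "risk")}
    for df, name in ((summary_df, "summary"), (exposure_df, "exposure"),
                     (risk_df, "risk")):
        df.to_csv(paths[name], index=False)
        written.append(paths[name])

    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "iterations": iterations,
        "mode": mode,
        "levels": list(levels),
        "n_samples": len({s.sample_id for s in samples}),
        "n_groups": len(groups),
        "versions": _versions(),
        "outputs": sorted(p.name for p in paths.values()) + ["manifest.json"],
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    written.append(manifest_path)
    return manifest


def _resolve_data(config: dict, seed: int) -> tuple[list[ConcentrationSample], str]:
    data = config.get("data")
    if not isinstance(data, dict):
        raise ConfigError("config requires a 'data' mapping "
                          "(with 'synthetic' or 'samples')")
    if "synthetic" in data:
        src = data["synthetic"]
        spec = drio.read_summary_targets(None if src in ("default", None) else src)
        if bool(data.get("truncate", False)):
            spec = spec.__class__(spec.targets, spec.seed, spec.stratum_key,
                                  spec.n_override, True, dict(spec.national))
        spec = spec.with_seed(seed)
        return generate_samples(spec), spec.stratum_key
    if "samples" in data:
        samples = drio.read_samples(data["samples"])
        return samples, str(data.get("stratum_key", "province"))
    raise ConfigError("data mapping must name 'synthetic' or 'samples'")


def _exposure_frame(exposures: Mapping[str, Mapping[str, ExposureResult]],
                    levels: Sequence[float]) -> pd.DataFrame:
    rows = []
    for group_name in exposures:
        for element, res in exposures[group_name].items():
            row = {"group": group_name, "element": element,
                   "parameter": "EDI", "average": res.mean}
            row.update({_level_key(lev): res.percentiles[lev] for lev in levels})
            rows.append(row)
    return pd.DataFrame(rows)


def _risk_frame(risks: Mapping[str, RiskResult],
                levels: Sequence[float]) -> pd.DataFrame:
    rows = []
    for group_name, r in risks.items():
        for element in r.hq:
            rows.append(_risk_row(group_name, "HQ", element, r.hq_mean[element],
                                  r.hq_percentiles[element], levels,
                                  flag=str(r.flags[f"HQ>1 [{element}]"]),
                                  share=r.hi_shares[element]))
        rows.append(_risk_row(group_name, "HI", "", r.hi_mean,
                              r.hi_percentiles, levels,
                              flag=str(r.flags["HI>1"]), share=""))
        for element in r.cr:
            rows.append(_risk_row(group_name, "CR", element, r.cr_mean[element],
                                  r.cr_percentiles[element], levels,
                                  flag=str(r.flags[f"CR [{element}]"]),
                                  share=r.tcr_shares[element]))
        if r.tcr_mean is not None:
            rows.append(_risk_row(group_name, "TCR", "", r.tcr_mean,
                                  r.tcr_percentiles, levels,
                                  flag=str(r.flags["TCR"]), share=""))
    return pd.DataFrame(rows)


def _risk_row(group: str, metric: str, element: str, mean: float,
              percentiles: Mapping[float, float], levels: Sequence[float],
              flag: str, share) -> dict:
    row = {"group": group, "metric": metric, "element": element, "mean": mean}
    row.update({_level_key(lev): percentiles[lev] for lev in levels})
    row["flag"] = flag
    row["share"] = share
    return row


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy  # noqa: PLC0415
    return {
        "dietrisk": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
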