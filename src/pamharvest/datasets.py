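"""Packaged reference tables for the Ionian Islands monitoring grid.

The verified per-site gunshot counts (2019-2022 spring seasons) and the
stratum assumptions for the 2021 harvest estimate ship with the package
so the estimation stage runs with zero external data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from pamharvest.harvest import StratumConfig

__all__ = ["ionian_counts", "ionian_strata", "load_counts", "load_strata"]


def _data_path(name: str):
    return resources.files("pamharvest") / "data" / name


def load_counts(path) -> pd.DataFrame:
    """Read a site-season counts CSV (island, site, stratum, year, detected_gunshots)."""
    df = pd.read_csv(path)
    required = {"island", "site", "stratum", "year", "detected_gunshots"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table is missing columns: {sorted(missing)}")
    if (df["detected_gunshots"] < 0).any():
        raise ValueError("detected_gunshots must be non-negative")
    return df


def load_strata(path) -> tuple[dict[str, StratumConfig], float, int | None]:
    """Read a strata YAML into configs plus (recall, factor_precision)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    recall = float(raw.get("recall", StratumConfig.__dataclass_fields__["recall"].default))
    factor_precision = raw.get("factor_precision", 3)
    defaults = raw.get("defaults", {})
    configs = {}
    for label, block in raw["strata"].items():
        merged = {**defaults, **(block or {})}
        configs[label] = StratumConfig(
            posta_fraction=float(merged["posta_fraction"]),
            shots_per_kill=float(merged.get("shots_per_kill", 5)),
            shots_per_killed_or_injured=float(merged.get("shots_per_killed_or_injured", 3)),
            recall=recall,
        )
    return configs, recall, factor_precision


def ionian_counts() -> pd.DataFrame:
    """Verified gunshots per site and spring season, Ionian grid 2019-2022."""
    with resources.as_file(_data_path("ionian_counts.csv")) as p:
        return load_counts(p)


def ionian_strata() -> tuple[dict[str, StratumConfig], float, int | None]:
    """Stratum configs for the 2021 Ionian harvest estimate."""
    with resources.as_file(_data_path("ionian_strata.yaml")) as p:
        return load_strata(p)
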