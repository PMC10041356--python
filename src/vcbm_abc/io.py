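"""Reading and writing the pipeline's text formats.

Time series travel as two-column CSV (``day,volume``); configuration is a
flat key-value YAML file whose keys are the field names of the simulator,
prior, SMC and predictive settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .priors import MarginalPrior, PriorSpec, PARAM_NAMES, default_priors
from .simulator import SimConfig, TumourTimeSeries
from .smc import SMCConfig

__all__ = [
    "SeriesFormatError",
    "read_series",
    "write_series",
    "load_config",
    "config_hash",
]


class SeriesFormatError(ValueError):
    """Malformed time-series file; message names the offending line."""


def read_series(path: str | Path) -> TumourTimeSeries:
    """Read a ``day,volume`` CSV, validating monotone days and
    non-negative volumes."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:  # noqa: BLE001 - surface as format error
        raise SeriesFormatError(f"{path}: cannot parse ({err})") from err
    if list(df.columns[:2]) != ["day", "volume"]:
        raise SeriesFormatError(
            f"{path}: expected header 'day,volume', got {list(df.columns)}"
        )
    days = pd.to_numeric(df["day"], errors="coerce").to_numpy(float)
    vols = pd.to_numeric(df["volume"], errors="coerce").to_numpy(float)
    for k in range(len(df)):
        # +2: header line plus 1-based numbering
        if not np.isfinite(days[k]) or not np.isfinite(vols[k]):
            raise SeriesFormatError(f"{path}: non-numeric value on line {k + 2}")
        if vols[k] < 0:
            raise SeriesFormatError(f"{path}: negative volume on line {k + 2}")
        if k and days[k] <= days[k - 1]:
            raise SeriesFormatError(
                f"{path}: days not strictly increasing at line {k + 2}"
            )
    return TumourTimeSeries(days, vols)


def write_series(series: TumourTimeSeries, path: str | Path) -> None:
    pd.DataFrame({"day": series.days, "volume": series.volumes}).to_csv(
        path, index=False
    )


def _prior_from_flat(cfg: dict) -> PriorSpec:
    defaults = default_priors()
    marginals = {}
    for name in PARAM_NAMES:
        fam = cfg.get(f"{name}_family")
        if fam is None:
            marginals[name] = defaults[name]
        else:
            marginals[name] = MarginalPrior(
                str(fam), float(cfg[f"{name}_a"]), float(cfg[f"{name}_b"])
            )
    return PriorSpec(marginals)


def _pick(cfg: dict, cls):
    names = {f.name for f in dataclasses.fields(cls)}
    return cls(**{k: v for k, v in cfg.items() if k in names})


def load_config(path: str | Path | None) -> dict:
    """Load a flat YAML config into the pipeline's setting objects.

    Unknown keys are ignored by each settings class, so one flat file can
    drive every stage.  Returns a dict with keys ``sim`` (SimConfig),
    ``smc`` (SMCConfig), ``priors`` (PriorSpec), ``band_level``,
    ``n_predictive_draws``, ``metric`` and ``raw`` (the flat mapping).
    """
    flat: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        flat = loaded
    return {
        "sim": _pick(flat, SimConfig),
        "smc": _pick(flat, SMCConfig),
        "priors": _prior_from_flat(flat),
        "band_level": float(flat.get("band_level", 0.95)),
        "n_predictive_draws": int(flat.get("n_predictive_draws", 200)),
        "metric": str(flat.get("metric", "log")),
        "raw": flat,
    }


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable config echo."""

    def _default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not serialisable: {o!r}")

    blob = json.dumps(obj, sort_keys=True, default=_default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
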