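"""Scenario/run configuration parsing and validation.

Configs are YAML or JSON mappings:

.. code-block:: yaml

    sources:
      - {mean: -0.26, variance: 0.25, w: 0.15}
      - {mean: -0.24, variance: 0.23, w: 0.20}
    mixture: {a01: 2, b01: 2, a02: 18, b02: 3}   # optional, shape--rate
    s0: 0.05                                     # optional
    variance: {kind: known, sigma02: 0.35}       # or {kind: invgamma, c: 5}
    ratio: 1                                     # optional, nA/nB

Unknown keys are rejected so typos fail loudly.  A plain CSV table with header
``mean,variance,w`` can stand in for the ``sources`` list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .prior import (
    DEFAULT_MIXTURE,
    DEFAULT_S0,
    HistoricalSummary,
    PrecisionMixturePrior,
)

__all__ = ["RunConfig", "parse_config", "read_sources_csv", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    sources: tuple[HistoricalSummary, ...]
    mixture: PrecisionMixturePrior = DEFAULT_MIXTURE
    s0: float = DEFAULT_S0
    variance: dict | None = None  # {"kind": "known", "sigma02": ...} or {"kind": "invgamma", "c": ..., ["S": ...]}
    ratio: float = 1.0

    def to_dict(self) -> dict:
        d = {
            "sources": [
                {"mean": h.mean, "variance": h.variance, "w": h.w} for h in self.sources
            ],
            "mixture": {
                "a01": self.mixture.a01, "b01": self.mixture.b01,
                "a02": self.mixture.a02, "b02": self.mixture.b02,
            },
            "s0": self.s0,
            "ratio": self.ratio,
        }
        if self.variance is not None:
            d["variance"] = dict(self.variance)
        return d


_TOP_KEYS = {"sources", "mixture", "s0", "variance", "ratio", "name"}
_SOURCE_KEYS = {"mean", "variance", "w"}
_MIXTURE_KEYS = {"a01", "b01", "a02", "b02"}
_VARIANCE_KEYS = {"kind", "sigma02", "c", "S"}


def _require_number(value, key: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{key} must be a number, got {value!r}")
    return float(value)


def _parse_sources(raw) -> tuple[HistoricalSummary, ...]:
    if not isinstance(raw, list) or not raw:
        raise ConfigError("'sources' must be a non-empty list of mappings")
    out = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise ConfigError(f"sources[{i}] must be a mapping")
        unknown = set(entry) - _SOURCE_KEYS
        if unknown:
            raise ConfigError(f"sources[{i}] has unknown keys {sorted(unknown)}")
        for key in ("mean", "variance"):
            if key not in entry:
                raise ConfigError(f"sources[{i}] is missing required key '{key}'")
        mean = _require_number(entry["mean"], f"sources[{i}].mean")
        variance = _require_number(entry["variance"], f"sources[{i}].variance")
        w = _require_number(entry.get("w", 0.0), f"sources[{i}].w")
        if not variance > 0:
            raise ConfigError(f"sources[{i}].variance must be > 0, got {variance}")
        if not 0.0 <= w <= 1.0:
            raise ConfigError(f"sources[{i}].w must lie in [0, 1], got {w}")
        out.append(HistoricalSummary(mean=mean, variance=variance, w=w))
    return tuple(out)


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON scenario configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    if "sources" not in raw:
        raise ConfigError("configuration must define 'sources'")
    sources = _parse_sources(raw["sources"])

    mixture = DEFAULT_MIXTURE
    if "mixture" in raw:
        m = raw["mixture"]
        if not isinstance(m, dict) or set(m) != _MIXTURE_KEYS:
            raise ConfigError(f"'mixture' must define exactly {sorted(_MIXTURE_KEYS)}")
        mixture = PrecisionMixturePrior(
            **{k: _require_number(m[k], f"mixture.{k}") for k in _MIXTURE_KEYS}
        )

    s0 = _require_number(raw.get("s0", DEFAULT_S0), "s0")
    if not s0 > 0:
        raise ConfigError(f"s0 must be > 0, got {s0}")
    ratio = _require_number(raw.get("ratio", 1.0), "ratio")
    if not ratio > 0:
        raise ConfigError(f"ratio must be > 0, got {ratio}")

    variance = None
    if "variance" in raw:
        v = raw["variance"]
        if not isinstance(v, dict) or "kind" not in v:
            raise ConfigError("'variance' must be a mapping with a 'kind' key")
        unknown = set(v) - _VARIANCE_KEYS
        if unknown:
            raise ConfigError(f"'variance' has unknown keys {sorted(unknown)}")
        if v["kind"] == "known":
            sigma02 = _require_number(v.get("sigma02"), "variance.sigma02")
            if not sigma02 > 0:
                raise ConfigError("variance.sigma02 must be > 0")
            variance = {"kind": "known", "sigma02": sigma02}
        elif v["kind"] == "invgamma":
            c = _require_number(v.get("c"), "variance.c")
            if not c > 0:
                raise ConfigError("variance.c must be > 0")
            variance = {"kind": "invgamma", "c": c}
            if "S" in v:
                S = _require_number(v["S"], "variance.S")
                if not S > 0:
                    raise ConfigError("variance.S must be > 0")
                variance["S"] = S
        else:
            raise ConfigError(f"variance.kind must be 'known' or 'invgamma', got {v['kind']!r}")

    return RunConfig(sources=sources, mixture=mixture, s0=s0, variance=variance, ratio=ratio)


def read_sources_csv(path: str | Path) -> tuple[HistoricalSummary, ...]:
    """Read a sources table from CSV with required header ``mean,variance,w``."""
    df = pd.read_csv(path)
    missing = {"mean", "variance", "w"} - set(df.columns)
    if missing:
        raise ConfigError(f"sources CSV is missing columns {sorted(missing)}")
    return _parse_sources(df[["mean", "variance", "w"]].to_dict("records"))
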