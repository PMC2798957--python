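"""Plain-text run configuration: parsing, validation and serialization.

A run config is a YAML (or JSON) mapping that names an experiment or an
explicit segment list, the agonist and concentration, an optional model
variant, and optional rate-constant overrides keyed by the canonical
k-names.  Variant zeroing is applied after overrides and cannot be
overridden in the same run: overriding a rate that the chosen variant
zeroes is rejected rather than silently re-enabling a disabled pathway.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .experiments import VARIANTS, build_standard_protocol, build_variant
from .network import AGONISTS, AgonistSpec, LigandEnvironment, RateSet
from .simulator import Protocol, ProtocolSegment

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_rates", "load_rates"]

_EXPERIMENTS = (
    "phosphorylation",
    "dephosphorylation",
    "internalization",
    "recycling",
    "desensitization",
    "resensitization",
)

_RATE_NAMES = set(RateSet().to_dict())


class ConfigError(ValueError):
    """A run configuration is malformed; the message names the bad key."""


@dataclass
class RunConfig:
    """Validated, resolved run configuration."""

    protocol: Protocol
    rates: RateSet
    agonist: AgonistSpec | None
    concentration: float
    variant: str = "A"
    experiment: str | None = None
    phospho_activity: float = 0.7
    sample_interval: float = 0.01
    raw: dict = field(default_factory=dict)


def _parse_agonist(data: Mapping[str, Any]) -> tuple[AgonistSpec | None, float]:
    name = data.get("agonist", "isoproterenol")
    conc = float(data.get("concentration", 1000.0))
    if name is None:
        return None, 0.0
    if name not in AGONISTS:
        raise ConfigError(f"unknown agonist: {name!r}")
    return AGONISTS[name], conc


def _parse_segment(entry: Mapping[str, Any], default_agonist, default_conc) -> ProtocolSegment:
    if "duration" not in entry:
        raise ConfigError("segment missing required key 'duration'")
    duration = float(entry["duration"])
    washout = entry.get("washout")
    if washout is not None:
        if washout not in ("plain", "instantaneous"):
            raise ConfigError(f"unknown washout mode: {washout!r}")
        entry_action = (
            "instantaneous_dissociation" if washout == "instantaneous" else "none"
        )
        return ProtocolSegment(duration, LigandEnvironment(), entry_action)
    if "agonist" in entry or "concentration" in entry:
        agonist, conc = _parse_agonist(entry)
    else:
        agonist, conc = default_agonist, default_conc
    env = LigandEnvironment(agonist, conc, bool(entry.get("antagonist", False)))
    return ProtocolSegment(duration, env)


def _resolve_rates(data: Mapping[str, Any]) -> tuple[RateSet, str]:
    overrides = data.get("rates", {}) or {}
    if not isinstance(overrides, Mapping):
        raise ConfigError("'rates' must be a mapping of k-names to values")
    unknown = set(overrides) - _RATE_NAMES
    if unknown:
        raise ConfigError(f"unknown rate name(s): {', '.join(sorted(unknown))}")
    variant = str(data.get("variant", "A"))
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant: {variant!r}")
    clobbered = set(overrides) & set(VARIANTS[variant])
    if clobbered:
        raise ConfigError(
            f"rate(s) {', '.join(sorted(clobbered))} are zeroed by variant "
            f"{variant} and cannot be overridden; define a custom rate set instead"
        )
    rates = RateSet().replace(**{k: float(v) for k, v in overrides.items()})
    return build_variant(variant, rates), variant


def load_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a run config from a YAML/JSON file or mapping."""
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")

    rates, variant = _resolve_rates(data)
    agonist, conc = _parse_agonist(data)
    sample_interval = float(data.get("sample_interval", 0.01))

    experiment = data.get("experiment")
    segments_cfg = data.get("segments")
    if experiment is not None and segments_cfg is not None:
        raise ConfigError("give either 'experiment' or 'segments', not both")
    if experiment is not None:
        if experiment not in _EXPERIMENTS:
            raise ConfigError(f"unknown experiment: {experiment!r}")
        params = {
            k: float(v)
            for k, v in data.items()
            if k in ("treat", "follow")
        }
        protocol = build_standard_protocol(
            experiment,
            agonist if agonist is not None else "isoproterenol",
            conc,
            sample_interval=sample_interval,
            **params,
        )
    elif segments_cfg:
        segments = [_parse_segment(s, agonist, conc) for s in segments_cfg]
        protocol = Protocol(segments, sample_interval=sample_interval)
    else:
        raise ConfigError("config needs an 'experiment' name or a 'segments' list")

    activity = float(data.get("phospho_activity", 0.7))
    if not 0.0 <= activity <= 1.0:
        raise ConfigError("phospho_activity must be in [0, 1]")

    return RunConfig(
        protocol=protocol,
        rates=rates,
        agonist=agonist,
        concentration=conc,
        variant=variant,
        experiment=experiment,
        phospho_activity=activity,
        sample_interval=sample_interval,
        raw=data,
    )


def dump_rates(rates: RateSet) -> str:
    """Serialize a rate set to YAML keyed by the canonical k-names."""
    return yaml.safe_dump(rates.to_dict(), sort_keys=True)


def load_rates(text: str) -> RateSet:
    """Inverse of :func:`dump_rates`; round-trips exactly."""
    data = yaml.safe_load(text)
    unknown = set(data) - _RATE_NAMES
    if unknown:
        raise ConfigError(f"unknown rate name(s): {', '.join(sorted(unknown))}")
    return RateSet.from_dict(data)
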