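"""Run configuration: defaults, file loading, override validation, hashing.

A configuration is a flat mapping of kinetic-parameter symbols (the field
names of :class:`~wntapc.parameters.KineticParameters`), an ``experiment``
block with :class:`~wntapc.parameters.ExperimentContext` fields, and a few
run-level keys (``genotype``, ``seed``).  Unknown keys are rejected by
name; value validation is delegated to the dataclass invariants.  The
effective merged configuration and its hash are echoed into every output's
metadata so any result can be reproduced from its own header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .parameters import ExperimentContext, Genotype, KineticParameters

__all__ = ["RunConfig", "load_config", "config_hash"]

_PARAM_KEYS = {f.name for f in fields(KineticParameters)}
_CTX_KEYS = {f.name for f in fields(ExperimentContext)}
_TOP_KEYS = _PARAM_KEYS | {"experiment", "genotype", "seed"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    params: KineticParameters = field(default_factory=KineticParameters)
    context: ExperimentContext = field(default_factory=ExperimentContext)
    genotype: str | None = None
    seed: int = 0

    def genotype_obj(self) -> Genotype | None:
        return Genotype.from_string(self.genotype) if self.genotype else None

    def effective_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = dict(sorted(asdict(self.params).items()))
        d["experiment"] = dict(sorted(asdict(self.context).items()))
        d["genotype"] = self.genotype
        d["seed"] = self.seed
        return d


def _parse_file(path: Path) -> Mapping[str, Any]:
    try:
        loaded = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if loaded is None:
        return {}
    if not isinstance(loaded, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping, got {type(loaded).__name__}")
    return loaded


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, an optional file, and overrides.

    File values override the defaults; inline ``overrides`` override the
    file.  Unknown keys raise :class:`ConfigError` naming the offending key;
    out-of-range values are rejected by the parameter dataclasses with their
    own messages.
    """
    merged: dict[str, Any] = {}
    if path is not None:
        merged.update(_parse_file(Path(path)))
    for src in (overrides or {},):
        for key, value in src.items():
            if key == "experiment" and isinstance(value, Mapping) and isinstance(merged.get("experiment"), Mapping):
                merged["experiment"] = {**merged["experiment"], **value}
            else:
                merged[key] = value

    unknown = set(merged) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    exp = merged.get("experiment") or {}
    if not isinstance(exp, Mapping):
        raise ConfigError("'experiment' must be a mapping of context fields")
    unknown_ctx = set(exp) - _CTX_KEYS
    if unknown_ctx:
        raise ConfigError(f"unknown experiment key(s): {sorted(unknown_ctx)}")

    try:
        params = KineticParameters(**{k: float(merged[k]) for k in _PARAM_KEYS & set(merged)})
        context = ExperimentContext(**{k: float(exp[k]) for k in exp})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration value: {exc}") from exc
    genotype = merged.get("genotype")
    if genotype is not None:
        Genotype.from_string(str(genotype))  # validate labels early
        genotype = str(genotype)
    return RunConfig(params=params, context=context, genotype=genotype, seed=int(merged.get("seed", 0)))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    canonical = json.dumps(cfg.effective_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
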