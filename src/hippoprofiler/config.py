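"""Flat key-value configuration for the pipeline and CLI.

The config file is plain ``key = value`` lines (``#`` comments allowed).
Keys map onto :class:`~hippoprofiler.synthetic.SyntheticConfig` fields and
the analysis parameters below; CLI flags override config keys. Treatments
are encoded as ``label:family:c1|c2|c3`` entries separated by ``;``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields

from .exceptions import ConfigurationError
from .synthetic import SyntheticConfig, Treatment


@dataclass
class AnalysisParams:
    """Analysis-stage knobs surfaced in the manifest."""

    variance_threshold: float = 1e-8
    correlation_threshold: float = 0.9
    vehicle_label: str = "DMSO"
    wt_genotype: str = "WT"
    ko_genotype: str = "YAP_KO"
    contact_low: float = 45.0
    contact_high: float = 55.0
    clamp_floor: float = -10.0
    anchor_early: float = 24.0
    anchor_late: float = 168.0
    anchor_tol: float = 4.0


def load_config(path) -> dict[str, str]:
    """Parse a flat key-value config file into a string mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def _parse_treatments(text: str) -> tuple[Treatment, ...]:
    treatments = []
    for entry in filter(None, (e.strip() for e in text.split(";"))):
        parts = entry.split(":")
        if len(parts) != 3:
            raise ConfigurationError(f"bad treatment spec {entry!r}; want label:family:c1|c2")
        label, family, concs = parts
        treatments.append(Treatment(label, family,
                                    tuple(float(c) for c in concs.split("|"))))
    return tuple(treatments)


def build_configs(mapping: dict[str, str]) -> tuple[SyntheticConfig, AnalysisParams]:
    """Coerce a flat string mapping into typed config objects."""
    syn_kwargs: dict = {}
    ana_kwargs: dict = {}
    syn_fields = {f.name: f for f in fields(SyntheticConfig)}
    ana_fields = {f.name: f for f in fields(AnalysisParams)}
    for key, value in mapping.items():
        if key == "treatments":
            syn_kwargs[key] = _parse_treatments(value)
        elif key == "genotypes":
            syn_kwargs[key] = tuple(g.strip() for g in value.split(","))
        elif key in ("spheroid_times", "times_2d"):
            syn_kwargs[key] = tuple(float(t) for t in value.split(","))
        elif key in syn_fields:
            syn_kwargs[key] = _coerce(value, syn_fields[key].type)
        elif key in ana_fields:
            ana_kwargs[key] = _coerce(value, ana_fields[key].type)
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    return SyntheticConfig(**syn_kwargs), AnalysisParams(**ana_kwargs)


def _coerce(value: str, type_hint) -> object:
    hint = str(type_hint)
    if "int" in hint:
        return int(value)
    if "float" in hint:
        return float(value)
    if "bool" in hint:
        return value.lower() in ("1", "true", "yes")
    return value


def config_hash(*objects) -> str:
    """Stable sha256 over the repr of config objects (recorded in manifests)."""
    digest = hashlib.sha256()
    for obj in objects:
        digest.update(repr(obj).encode())
    return digest.hexdigest()
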