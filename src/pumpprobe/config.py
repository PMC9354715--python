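"""Pipeline configuration: a versioned YAML/JSON schema over the dataclasses.

The config round-trips losslessly: ``load_config(save_config(cfg)) == cfg``.
JSON is accepted interchangeably with YAML (JSON is a YAML subset).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .delineation import DelineationConfig
from .errors import ConfigurationError
from .fitting import FitConfig
from .synthetic import AcquisitionMetadata, NoiseSpec, PhantomSpec

__all__ = ["UnmixConfig", "PipelineConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class UnmixConfig:
    normalize: bool = True
    tolerance_ps: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    unmix: UnmixConfig = field(default_factory=UnmixConfig)
    delineate: DelineationConfig = field(default_factory=DelineationConfig)
    output_dir: str = "results"
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-seed every random stage from one integer (phantom and noise)."""
        phantom = dataclasses.replace(self.phantom, seed=int(seed))
        noise = dataclasses.replace(self.noise, seed=int(seed) + 10007)
        return dataclasses.replace(self, phantom=phantom, noise=noise)


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_encode(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return ".inf" if obj > 0 else "-.inf"
    return obj


def _decode_float(v):
    if v == ".inf":
        return np.inf
    if v == "-.inf":
        return -np.inf
    return v


def _build(cls, doc: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in doc:
            continue
        v = doc[f.name]
        if f.name == "metadata":
            v = AcquisitionMetadata(**{**v, "delays_ps": tuple(v["delays_ps"])})
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else _decode_float(x) for x in v)
        else:
            v = _decode_float(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **_encode(config)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    try:
        # JSON first: PyYAML mis-parses dot-less scientific notation (1e-06)
        doc = json.loads(text)
    except json.JSONDecodeError:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    version = doc.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported schema_version {version}")
    try:
        return PipelineConfig(
            phantom=_build(PhantomSpec, doc.get("phantom", {})),
            noise=_build(NoiseSpec, doc.get("noise", {})),
            fit=_build(FitConfig, doc.get("fit", {})),
            unmix=_build(UnmixConfig, doc.get("unmix", {})),
            delineate=_build(DelineationConfig, doc.get("delineate", {})),
            output_dir=doc.get("output_dir", "results"),
            log_level=doc.get("log_level", "INFO"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
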