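"""Plain-text (YAML) configuration: load, validate, save, ship defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .mc import RunSettings
from .source import SourceSpec
from .tissue import TissueStack

__all__ = ["Config", "load_config", "save_config", "default_config", "default_config_path"]

_TOP_KEYS = {"tissue", "source", "run", "incident_energy_J"}


@dataclass(frozen=True)
class Config:
    """Validated simulation configuration: stack + source + run settings."""

    stack: TissueStack
    source: SourceSpec = field(default_factory=SourceSpec)
    settings: RunSettings = field(default_factory=RunSettings)
    incident_energy_J: float = 10.0

    def to_dict(self) -> dict:
        return {
            "tissue": self.stack.to_dict(),
            "source": self.source.to_dict(),
            "run": self.settings.to_dict(),
            "incident_energy_J": self.incident_energy_J,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(
                f"config: unknown top-level keys {sorted(unknown)}; "
                f"expected a subset of {sorted(_TOP_KEYS)}"
            )
        if "tissue" not in d:
            raise ValueError("config: missing required 'tissue' section")
        errors = []
        stack = source = settings = None
        try:
            stack = TissueStack.from_dict(d["tissue"])
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"tissue: {exc}")
        try:
            source = SourceSpec.from_dict(d.get("source", {}))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"source: {exc}")
        try:
            settings = RunSettings.from_dict(d.get("run", {}))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"run: {exc}")
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
        if stack is not None and source is not None:
            missing = []
            for wl in source.spectrum.discrete_wavelengths:
                for i, layer in enumerate(stack.layers):
                    try:
                        stack.properties_at(i, wl)
                    except ValueError:
                        missing.append(f"layer {layer.name!r} has no properties at {wl} nm")
            if missing:
                raise ValueError("invalid config:\n  " + "\n  ".join(missing))
        return cls(
            stack=stack,
            source=source,
            settings=settings,
            incident_energy_J=float(d.get("incident_energy_J", 10.0)),
        )


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return Config.from_dict(raw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_config(config: Config, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config_path() -> Path:
    """Path of the shipped default configuration file."""
    return Path(str(resources.files("lumiderm").joinpath("data/skin_default.yaml")))


def default_config() -> Config:
    return load_config(default_config_path())
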