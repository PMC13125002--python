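"""Flat key-value run configuration with lossless round-tripping.

The application configuration aggregates every module's tunables into named
sections (``sim``, ``stream``, ``zones``, ``trend``, ``surrogate``, ``run``).
``dump`` renders ``section.key = value`` lines (tuples comma-joined) and
``parse`` restores them with the field types of the dataclass defaults, so
``parse(dump(cfg))`` reproduces ``cfg`` exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

from .detect import TrendConfig, ZoneConfig
from .engine import SurrogateConfig
from .errors import ConfigurationError
from .ingest import StreamWindowSpec
from .simulate import SimulatorConfig


@dataclass
class RunConfig:
    sim: SimulatorConfig = field(default_factory=SimulatorConfig)
    stream: StreamWindowSpec = field(default_factory=StreamWindowSpec)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    seed: int = 0
    n_subjects: int = 20
    predictor: str = "surrogate"
    dialect: str = "simulated"
    gate_window: int = 60
    gate_crossings: int = 45


_SECTIONS = ("sim", "stream", "zones", "trend", "surrogate")


def _render(value) -> str:
    if isinstance(value, tuple):
        return ",".join(_render(v) for v in value)
    return repr(value) if isinstance(value, str) else str(value)


def _cast(text: str, template):
    if isinstance(template, tuple):
        parts = [p for p in text.split(",") if p != ""]
        elem = template[0] if template else 0.0
        return tuple(type(elem)(p) for p in parts)
    if isinstance(template, bool):
        return text == "True"
    if isinstance(template, str):
        return text.strip("'\"")
    return type(template)(text)


def dump(config: RunConfig = RunConfig()) -> str:
    lines = []
    for section in _SECTIONS:
        obj = getattr(config, section)
        for f in dataclasses.fields(obj):
            lines.append(f"{section}.{f.name} = {_render(getattr(obj, f.name))}")
    for f in dataclasses.fields(config):
        if f.name in _SECTIONS:
            continue
        lines.append(f"run.{f.name} = {_render(getattr(config, f.name))}")
    return "\n".join(lines) + "\n"


def parse(text: str) -> RunConfig:
    config = RunConfig()
    updates: dict[str, dict[str, object]] = {s: {} for s in (*_SECTIONS, "run")}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line or "." not in line.split("=", 1)[0]:
            raise ConfigurationError(f"line {lineno}: expected 'section.key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        section, name = key.split(".", 1)
        if section not in updates:
            raise ConfigurationError(f"line {lineno}: unknown section {section!r}")
        target = config if section == "run" else getattr(config, section)
        if not any(f.name == name for f in dataclasses.fields(target)):
            raise ConfigurationError(f"line {lineno}: unknown key {key!r}")
        updates[section][name] = _cast(value, getattr(target, name))
    for section in _SECTIONS:
        if updates[section]:
            config = replace(config, **{section: replace(getattr(config, section),
                                                         **updates[section])})
    if updates["run"]:
        config = replace(config, **updates["run"])
    return config
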