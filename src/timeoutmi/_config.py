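"""Flat key=value config files for the simulator and pipeline."""

from __future__ import annotations

import dataclasses

from .simulate import SimulationConfig


def parse_keyvalue(text: str) -> dict[str, str]:
    """Parse `key = value` lines; '#' starts a comment; blanks ignored."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _coerce(value: str, typ):
    if typ is bool:
        return value.lower() in {"1", "true", "yes", "on"}
    return typ(value)


def sim_config_from_mapping(mapping: dict[str, str], **overrides) -> SimulationConfig:
    fields = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    type_map = {"int": int, "float": float, "bool": bool, "str": str}
    kwargs = {}
    for key, value in mapping.items():
        if key not in fields:
            raise KeyError(f"unknown simulation parameter {key!r}")
        typ = fields[key]
        if isinstance(typ, str):
            typ = type_map.get(typ, str)
        kwargs[key] = _coerce(value, typ)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return SimulationConfig(**kwargs)


def load_sim_config(path=None, **overrides) -> SimulationConfig:
    mapping: dict[str, str] = {}
    if path is not None:
        with open(path) as fh:
            mapping = parse_keyvalue(fh.read())
    return sim_config_from_mapping(mapping, **overrides)


def dump_sim_config(config: SimulationConfig) -> str:
    return (
        "\n".join(
            f"{f.name} = {getattr(config, f.name)}"
            for f in dataclasses.fields(SimulationConfig)
        )
        + "\n"
    )
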