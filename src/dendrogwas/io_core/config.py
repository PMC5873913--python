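"""TOML configuration loading and a minimal writer for run artifacts."""

from __future__ import annotations

import tomllib


def load_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value).__name__} to TOML")


def dump_toml(data: dict, path) -> None:
    """Write a dict (scalars, lists, one level of sub-tables) as TOML."""
    with open(path, "w") as fh:
        tables = {k: v for k, v in data.items() if isinstance(v, dict)}
        for key, value in data.items():
            if key not in tables:
                fh.write(f"{key} = {_fmt(value)}\n")
        for name, table in tables.items():
            fh.write(f"\n[{name}]\n")
            for key, value in table.items():
                fh.write(f"{key} = {_fmt(value)}\n")
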