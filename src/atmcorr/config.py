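"""Interferent configuration files.

A configuration is a JSON object with an ``interferents`` list of
``{name, correct_region: [lo, hi], gamma_region: [lo, hi] | null}`` entries,
processed in listed order. The shipped default covers the standard
atmospheric CO2 and water-vapor absorption regions; overlapping regions
(the CO2 combination bands sit inside the water stretch) are handled by the
sequencing, each correction acting on the previous one's output.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .errors import ConfigError
from .spectra import InterferentSpec, Region

__all__ = ["load_interferents", "default_interferents", "dump_interferents"]


def _parse_region(value, where: str) -> Region:
    try:
        lo, hi = float(value[0]), float(value[1])
    except (TypeError, ValueError, IndexError):
        raise ConfigError(f"{where}: region must be a [lo, hi] pair, got {value!r}")
    try:
        return Region(lo, hi)
    except Exception as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def parse_interferents(obj: dict) -> list[InterferentSpec]:
    if not isinstance(obj, dict) or "interferents" not in obj:
        raise ConfigError("configuration must contain an 'interferents' list")
    specs = []
    for entry in obj["interferents"]:
        name = entry.get("name")
        if not name:
            raise ConfigError("every interferent needs a 'name'")
        cr = _parse_region(entry.get("correct_region"), name)
        gr = entry.get("gamma_region")
        specs.append(
            InterferentSpec(
                name=name,
                correct_region=cr,
                gamma_region=None if gr is None else _parse_region(gr, name),
            )
        )
    if not specs:
        raise ConfigError("'interferents' list is empty")
    return specs


def load_interferents(path: str | Path) -> list[InterferentSpec]:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    return parse_interferents(obj)


def default_interferents() -> list[InterferentSpec]:
    """The shipped default configuration, in processing order."""
    text = resources.files("atmcorr").joinpath("data/default_interferents.json").read_text()
    return parse_interferents(json.loads(text))


def dump_interferents(specs: list[InterferentSpec], path: str | Path) -> None:
    obj = {
        "interferents": [
            {
                "name": s.name,
                "correct_region": list(s.correct_region.as_tuple()),
                "gamma_region": None
                if s.gamma_region is None
                else list(s.gamma_region.as_tuple()),
            }
            for s in specs
        ]
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
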