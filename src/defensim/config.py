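"""Flat-text configuration files and the named preset registry.

Grammar (one dialect, deliberately minimal)::

    # comment
    key = value

Keys are exactly the :class:`~defensim.params.SimulationParams` field names
plus ``mode`` (resource-schedule mode) and ``test`` (invasion test id, or
``NONE`` for invasion-free runs).  Values are integers, floats, booleans
(``true``/``false``) or the enum names.  Unknown, duplicate or ill-typed
keys are configuration errors naming the key.  Every load echoes a fully
resolved configuration (all defaults explicit) via :func:`dump_config`,
and ``load(dump(x)) == x``.

Presets shipped with the package cover the reference experiment regimes
(``fig1c``, ``fig2a``..``fig2f``, ``fig3a``..``fig3i``, ``fig4a``..``fig4d``,
``fig5a``, ``fig5b``, ``s1``..``s6``); they are plain files users can read
and diff, not code constants.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

from .engine import Setup
from .params import (ConfigurationError, InvasionTest, ScheduleMode,
                     SimulationParams)

__all__ = ["load_config", "loads_config", "dump_config", "preset_names",
           "preset_path", "Preset"]

_BOOL = {"true": True, "false": False}


@dataclasses.dataclass
class Preset:
    """A named, provenance-annotated configuration bundle."""

    name: str
    setup: Setup
    provenance: str = ""


def preset_names() -> list[str]:
    """Names of all presets shipped with the package."""
    pkg = resources.files("defensim") / "presets"
    return sorted(p.name[:-4] for p in pkg.iterdir() if p.name.endswith(".cfg"))


def preset_path(name: str) -> Path:
    pkg = resources.files("defensim") / "presets" / f"{name}.cfg"
    with resources.as_file(pkg) as path:
        if not path.exists():
            raise ConfigurationError(
                f"unknown preset {name!r}; available: {', '.join(preset_names())}")
        return path


def _coerce(key: str, raw: str, target_type):
    low = raw.lower()
    try:
        if target_type is bool:
            if low not in _BOOL:
                raise ValueError
            return _BOOL[low]
        if target_type is int:
            return int(raw)
        if target_type is float:
            return float(raw)
    except ValueError:
        raise ConfigurationError(
            f"ill-typed value for key {key!r}: {raw!r} "
            f"(expected {target_type.__name__})") from None
    return raw


def loads_config(text: str, name: str = "<string>") -> Setup:
    """Parse configuration text into a validated :class:`Setup`."""
    field_types = {f.name: f.type for f in dataclasses.fields(SimulationParams)
                   if f.init}
    # dataclass field types are strings under ``from __future__ import annotations``
    type_map = {"int": int, "float": float, "bool": bool, "str": str}
    seen: dict[str, object] = {}
    mode = ScheduleMode.NONE
    test: InvasionTest | None = InvasionTest.TEST1
    provenance = ""
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            if stripped.startswith("# provenance:"):
                provenance = stripped.removeprefix("# provenance:").strip()
            continue
        if "=" not in stripped:
            raise ConfigurationError(f"{name}:{lineno}: expected 'key = value', "
                                     f"got {stripped!r}")
        key, _, raw = stripped.partition("=")
        key, raw = key.strip(), raw.split("#")[0].strip()
        if key in seen or (key == "mode" and "mode" in seen):
            raise ConfigurationError(f"{name}:{lineno}: duplicate key {key!r}")
        if key == "mode":
            try:
                mode = ScheduleMode(raw)
            except ValueError:
                raise ConfigurationError(f"{name}:{lineno}: unknown mode {raw!r}") from None
            seen[key] = raw
        elif key == "test":
            if raw == "NONE":
                test = None
            else:
                try:
                    test = InvasionTest(raw)
                except ValueError:
                    raise ConfigurationError(
                        f"{name}:{lineno}: unknown test {raw!r}") from None
            seen[key] = raw
        elif key in field_types:
            ftype = type_map.get(str(field_types[key]), float)
            seen[key] = _coerce(key, raw, ftype)
        else:
            raise ConfigurationError(f"{name}:{lineno}: unknown key {key!r}")
    params_kwargs = {k: v for k, v in seen.items() if k not in ("mode", "test")}
    params = SimulationParams(**params_kwargs)
    setup = Setup.build(params, mode, test)
    return setup


def load_config(source: str | Path) -> Setup:
    """Load a configuration from a file path or a registered preset name."""
    path = Path(source)
    if not path.exists() and not str(source).endswith(".cfg"):
        path = preset_path(str(source))
    if not path.exists():
        raise ConfigurationError(f"no such configuration file: {source}")
    return loads_config(path.read_text(), name=str(path))


def load_preset(name: str) -> Preset:
    path = preset_path(name)
    text = path.read_text()
    setup = loads_config(text, name=str(path))
    provenance = ""
    for line in text.splitlines():
        if line.strip().startswith("# provenance:"):
            provenance = line.strip().removeprefix("# provenance:").strip()
            break
    return Preset(name=name, setup=setup, provenance=provenance)


def dump_config(setup: Setup, path: str | Path | None = None,
                provenance: str = "") -> str:
    """Serialise a setup with every default made explicit (resolved echo)."""
    lines = []
    if provenance:
        lines.append(f"# provenance: {provenance}")
    lines.append(f"mode = {setup.mode.value}")
    lines.append(f"test = {setup.test.value if setup.test else 'NONE'}")
    for fname in setup.params.field_names():
        value = getattr(setup.params, fname)
        if isinstance(value, bool):
            value = "true" if value else "false"
        lines.append(f"{fname} = {value}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
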