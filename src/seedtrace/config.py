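"""Application configuration for the shell.

A plain ``key = value`` file configures the store path, log verbosity, the
date display format and an optional site dialect for file headers
(``remap.<canonical> = <site name>``, bijective over the names it covers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .formats import validate_remap


@dataclass
class AppConfig:
    store_path: Path = Path("seedtrace.db")
    header_remap: dict[str, str] = field(default_factory=dict)
    date_format: str = "iso"  # iso | dayfirst
    verbosity: str = "info"  # error | info | debug

    def __post_init__(self) -> None:
        if self.date_format not in ("iso", "dayfirst"):
            raise ValidationError("date_format must be 'iso' or 'dayfirst'")
        if self.verbosity not in ("error", "info", "debug"):
            raise ValidationError("verbosity must be error, info or debug")
        validate_remap(self.header_remap)


def config_from_text(text: str) -> AppConfig:
    store_path = Path("seedtrace.db")
    remap: dict[str, str] = {}
    date_format = "iso"
    verbosity = "info"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"config line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "store_path":
            store_path = Path(value)
        elif key == "date_format":
            date_format = value
        elif key == "verbosity":
            verbosity = value
        elif key.startswith("remap."):
            remap[key[len("remap."):]] = value
        else:
            raise ValidationError(f"config line {lineno}: unknown key {key!r}")
    return AppConfig(store_path=store_path, header_remap=remap, date_format=date_format, verbosity=verbosity)


def config_from_file(path: str | Path) -> AppConfig:
    return config_from_text(Path(path).read_text(encoding="utf-8"))
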