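"""Built-in configuration: default QA tolerance tables."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

__all__ = ["load_default_tolerances", "load_tolerances"]


def load_default_tolerances() -> dict:
    """The shipped tolerance tables (PIQT metrics and DSV distortion)."""
    with resources.files("mrlqa.data").joinpath("tolerances.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_tolerances(path: str | Path | None = None) -> dict:
    if path is None:
        return load_default_tolerances()
    return yaml.safe_load(Path(path).read_text())
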