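"""Shared plain-text (YAML) configuration dialect.

Every module reads its constants from the same ``key: value`` dialect; packaged
defaults live under :mod:`divegas.data` and user overrides are merged on top
with :func:`merge`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Load a YAML mapping from a file path."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at top level of {path}")
    return data


def load_packaged(name: str) -> dict[str, Any]:
    """Load a packaged default config (``divegas/data/<name>.yaml``)."""
    text = resources.files("divegas.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def merge(base: Mapping[str, Any], override: Mapping[str, Any] | None) -> dict[str, Any]:
    """Recursively merge ``override`` onto ``base`` (override wins; dicts merge)."""
    out = dict(base)
    for key, val in (override or {}).items():
        if key in out and isinstance(out[key], Mapping) and isinstance(val, Mapping):
            out[key] = merge(out[key], val)
        else:
            out[key] = val
    return out
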