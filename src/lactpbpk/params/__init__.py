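"""Versioned parameter files (YAML) shipped with the package."""

from __future__ import annotations

import functools
from importlib import resources

import yaml


@functools.lru_cache(maxsize=None)
def load_params(name: str) -> dict:
    """Load a named parameter file (e.g. ``"thc"``) from the package."""
    text = resources.files(__package__).joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)
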