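"""Parameter-file handling.

All biophysical constants (maximal conductances, reversals, kinetic rate
constants) live in a versioned JSON file with one block per neuron kind per
species plus shared synapse/transmitter blocks.  Any subset can be overridden
by a user dict or a second JSON file; overrides are deep-merged onto the
defaults.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

SCHEMA_VERSION = "tcloop-params-1"


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_params() -> dict:
    """Load the shipped default parameter set."""
    text = resources.files("tcloop").joinpath("data/default_params.json").read_text()
    params = json.loads(text)
    if params.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unexpected parameter schema: {params.get('schema_version')!r}")
    return params


def load_params(override: Mapping | str | Path | None = None) -> dict:
    """Defaults merged with an override mapping or JSON file path."""
    params = default_params()
    if override is None:
        return params
    if isinstance(override, (str, Path)):
        override = json.loads(Path(override).read_text())
    return _deep_merge(params, override)
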