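"""Access to the versioned default calibration (``paper_defaults.yaml``).

The defaults encode the study conditions the synthetic phantoms emulate:
reported segment perfusion levels, arc offsets, anastomosis profiles,
optics, and the calibrated occlusion noise.  They are data, not code, so
alternative calibrations can be supplied as YAML files.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources
from typing import Any

import yaml


@lru_cache(maxsize=1)
def _load() -> dict[str, Any]:
    text = (
        resources.files("speckleperf").joinpath("data/paper_defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


def paper_defaults(section: str | None = None) -> dict[str, Any]:
    """Return a deep copy of the default calibration (or one section of it)."""
    data = _load()
    if section is not None:
        if section not in data:
            raise KeyError(f"no defaults section named {section!r}")
        return copy.deepcopy(data[section])
    return copy.deepcopy(data)
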