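"""Run configuration: a single TOML file, every default overridable.

The fully resolved configuration is echoed to the log so that a run is
reconstructible from its log alone.
"""

from __future__ import annotations

import logging
import tomllib
from typing import Any

logger = logging.getLogger(__name__)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None, defaults: dict[str, Any] | None = None) -> dict[str, Any]:
    """Read a TOML config file and merge it over ``defaults``."""
    defaults = defaults or {}
    user: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    resolved = _deep_merge(defaults, user)
    logger.info("resolved config: %s", resolved)
    return resolved
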