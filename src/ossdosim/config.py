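"""YAML run configuration: loading, defaults, and config hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohort import CohortConfig
from .grid import TimeGrid, default_grid
from .noise import NoiseConfig
from .search import SearchConfig

__all__ = [
    "load_config",
    "config_hash",
    "cohort_config_from_dict",
    "noise_config_from_dict",
    "search_config_from_dict",
    "grid_from_dict",
]


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, Mapping):
        raise ValueError("configuration root must be a mapping")
    return dict(doc)


def config_hash(doc: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration (canonical-JSON sha256 prefix)."""
    payload = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _pick(doc: Mapping[str, Any], key: str) -> dict:
    sub = doc.get(key, {})
    return dict(sub) if sub else {}


def cohort_config_from_dict(doc: Mapping[str, Any]) -> CohortConfig:
    sub = _pick(doc, "cohort")
    tuple_keys = {"kidney_t_eff", "tumour_t_eff", "kidney_t_max",
                  "tumour_t_max", "kidney_peak_frac", "lesion_peak_frac"}
    kwargs = {k: (tuple(v) if k in tuple_keys else v) for k, v in sub.items()}
    return CohortConfig(**kwargs)


def noise_config_from_dict(doc: Mapping[str, Any]) -> NoiseConfig:
    return NoiseConfig(**_pick(doc, "noise"))


def search_config_from_dict(doc: Mapping[str, Any]) -> SearchConfig:
    return SearchConfig(**_pick(doc, "search"))


def grid_from_dict(doc: Mapping[str, Any]) -> TimeGrid:
    times = doc.get("grid_times")
    return TimeGrid(tuple(times)) if times else default_grid()
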