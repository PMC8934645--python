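"""Run configuration, provenance and YAML plumbing for the CLI."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from typing import Any, Optional

import yaml

from .mining import MinerParams
from .phylo import PhyloParams
from .simulate import SimConfig


def load_yaml(path: Optional[str]) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def _build(cls, section: dict, overrides: dict, what: str):
    known = {f.name for f in dataclasses.fields(cls)}
    merged = {**section, **{k: v for k, v in overrides.items() if v is not None}}
    unknown = set(merged) - known
    if unknown:
        raise ValueError(f"{what}: unknown option(s) {sorted(unknown)}; "
                         f"known: {sorted(known)}")
    for key in ("genes_per_replicon", "acr_length_range", "aca_length_range",
                "intergenic_range", "background_length_range",
                "acr_families", "aca_families"):
        if key in merged and isinstance(merged[key], list):
            merged[key] = tuple(merged[key])
    return cls(**merged)


def build_sim_config(config: dict, **overrides) -> SimConfig:
    return _build(SimConfig, config.get("sim", {}), overrides, "sim config")


def build_miner_params(config: dict, **overrides) -> MinerParams:
    return _build(MinerParams, config.get("miner", {}), overrides, "miner params")


def build_phylo_params(config: dict, **overrides) -> PhyloParams:
    return _build(PhyloParams, config.get("phylo", {}), overrides, "phylo params")


def provenance_block(config_obj: Any, seed: Optional[int],
                     overrides: Optional[dict] = None) -> dict:
    """A reproducibility record: config hash, seed, library versions."""
    import numpy
    import pandas
    import scipy
    import Bio

    from . import __version__

    if dataclasses.is_dataclass(config_obj) and not isinstance(config_obj, type):
        payload = dataclasses.asdict(config_obj)
    else:
        payload = config_obj
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return {
        "config": payload,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "overrides": overrides or {},
        "versions": {
            "acrmine": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "biopython": Bio.__version__,
        },
    }
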