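"""Run configuration: schema-validated YAML/JSON with seeded defaults.

Every stochastic component derives its seed deterministically from the
global seed unless set explicitly, so a config file plus the package
version is a complete provenance record for a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger(__name__)

_SCHEMA: dict[str, dict] = {
    "seed": {"type": int, "default": 0},
    "out_dir": {"type": str, "default": "results"},
    "log_level": {"type": str, "default": "INFO",
                  "choices": ["DEBUG", "INFO", "WARNING", "ERROR"]},
    "phantom": {
        "type": dict, "default": {},
        "keys": {"height": int, "width": int, "cyst_mean": float,
                 "background_mean": float, "texture_sd": float,
                 "n_spots": int},
    },
    "noise": {
        "type": dict, "default": {},
        "keys": {"model": str, "sigma": float, "seed": int},
    },
    "architecture": {
        "type": dict, "default": {},
        "keys": {"preset": str, "depth": int, "base_channels": int,
                 "init_seed": int},
    },
    "training": {
        "type": dict, "default": {},
        "keys": {"epochs": int, "batch_size": int, "learning_rate": float,
                 "loss": str, "optimizer": str, "seed": int,
                 "patch_size": int, "n_images": int},
    },
    "benchmark": {
        "type": dict, "default": {},
        "keys": {"methods": list, "sigmas": list, "n_images": int},
    },
    "clinical_fixture": {"type": (str, type(None)), "default": None},
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    phantom: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    architecture: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    benchmark: dict = field(default_factory=dict)
    clinical_fixture: str | None = None

    def derived_seed(self, component: str) -> int:
        """Deterministic per-component seed (explicit seeds win)."""
        block = getattr(self, component, None)
        if isinstance(block, dict) and "seed" in block:
            return int(block["seed"])
        digest = hashlib.sha256(f"{self.seed}:{component}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)

    def to_dict(self) -> dict:
        return asdict(self)


def _validate(raw: dict) -> dict:
    errors = []
    for key in raw:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    cleaned = {}
    for key, rule in _SCHEMA.items():
        if key not in raw:
            cleaned[key] = rule["default"]
            continue
        val = raw[key]
        want = rule["type"]
        if want is float and isinstance(val, int):
            val = float(val)
        if not isinstance(val, want):
            errors.append(f"{key}: expected {want}, got {type(val).__name__}")
            continue
        if "choices" in rule and val not in rule["choices"]:
            errors.append(f"{key}: {val!r} not one of {rule['choices']}")
        if isinstance(val, dict) and "keys" in rule:
            for sub, subval in val.items():
                if sub not in rule["keys"]:
                    errors.append(f"{key}.{sub}: unknown key")
                    continue
                subwant = rule["keys"][sub]
                if subwant is float and isinstance(subval, int):
                    subval = float(subval)
                    val[sub] = subval
                if not isinstance(subval, subwant):
                    errors.append(f"{key}.{sub}: expected {subwant.__name__}, "
                                  f"got {type(subval).__name__}")
        cleaned[key] = val
    if "noise" in cleaned and cleaned["noise"].get("sigma", 0) < 0:
        errors.append("noise.sigma: must be >= 0")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cleaned


def load_config(path) -> RunConfig:
    """Read and validate a YAML or JSON config; unknown keys are errors.

    The fully defaulted config is echoed to the log for provenance.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    cfg = RunConfig(**_validate(raw))
    log.info("loaded config %s: %s", path, json.dumps(cfg.to_dict()))
    return cfg
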