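"""Run configuration: a single YAML document with full flag override.

Unknown keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .align import AlignParams
from .interface import ContactCriteria
from .numbering import DetectionParams


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    registry_path: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    criteria: ContactCriteria = field(default_factory=ContactCriteria)
    output_format: str = "tsv"
    log_level: str = "INFO"
    seed: int = 0


_DETECTION_KEYS = {"tm_accept", "tm_cluster_shortcut", "top_clusters", "min_segment", "max_iterations"}
_CRITERIA_KEYS = {
    "heavy_atom_cutoff",
    "hbond_donor_acceptor_max",
    "ionic_max",
    "pi_centroid_max",
    "pi_cation_max",
    "halogen_max",
}
_TOP_KEYS = {"registry_path", "detection", "criteria", "output_format", "log_level", "seed"}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    det_raw = data.get("detection", {}) or {}
    if not isinstance(det_raw, dict):
        raise ConfigError("detection: must be a mapping")
    bad = set(det_raw) - _DETECTION_KEYS
    if bad:
        raise ConfigError(f"unknown detection keys: {sorted(bad)}")
    detection = DetectionParams(**det_raw, align=AlignParams())

    crit_raw = data.get("criteria", {}) or {}
    if not isinstance(crit_raw, dict):
        raise ConfigError("criteria: must be a mapping")
    bad = set(crit_raw) - _CRITERIA_KEYS
    if bad:
        raise ConfigError(f"unknown criteria keys: {sorted(bad)}")
    criteria = ContactCriteria(**crit_raw)

    fmt = data.get("output_format", "tsv")
    if fmt not in ("tsv", "json", "pdb_bfactor"):
        raise ConfigError(f"unknown output_format {fmt!r}")
    return RunConfig(
        registry_path=data.get("registry_path"),
        detection=detection,
        criteria=criteria,
        output_format=fmt,
        log_level=str(data.get("log_level", "INFO")),
        seed=int(data.get("seed", 0)),
    )
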