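"""Shared configuration objects for the screening pipeline.

Every tunable threshold of the pipeline lives here so that the scanner, the
classifier, the kinase detector, the aligner and the orchestrating screen all
read from one place.  Configs are plain frozen dataclasses; they can be
overridden from a YAML or JSON file whose keys mirror the dataclass fields.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class EFWeights:
    """Additive scoring weights for one EF-hand loop window.

    The terminal -Z anchor (the bidentate glutamate of canonical loops)
    dominates: a non-acidic residue there makes the window unsalvageable.
    X-position bonuses for A and L apply to the 15-residue loop variant only.
    """

    anchor_e: float = 3.0
    anchor_d: float = 1.5
    anchor_other: float = -5.0
    x_strong: float = 2.0      # D or S at X
    x_n: float = 1.0           # N at X
    x_a_l15: float = 1.0       # A at X, L15 loops only (degenerate sensors)
    x_l_l15: float = 1.5       # L at X, L15 loops only (stramenopile sensors)
    x_other: float = -2.0
    y_coord: float = 1.0       # Y in {D,N,S,T,E,G,Q}
    z_coord: float = 1.0       # Z in {D,N,S,T,E,G,Q}
    minus_x: float = 0.5       # -X in {D,N,S,T,E,G}
    l15_g_bonus: float = 1.0   # G inside the X..Y insertion (L15)
    l15_qhe_bonus: float = 1.0  # Q-[HN]-E in the middle of the loop (L15)


@dataclass(frozen=True)
class EFScanConfig:
    templates: tuple[str, ...] = ("L12", "L14", "L15", "L19")
    threshold: float = 4.0
    max_hits: int = 6
    weights: EFWeights = field(default_factory=EFWeights)


@dataclass(frozen=True)
class ClassifyConfig:
    nterm_window: int = 30
    cterm_window: int = 40


@dataclass(frozen=True)
class NAFConfig:
    threshold: float = 0.0          # bits
    offset_min: int = 6             # allowed window offsets of the N-A-F tripeptide
    offset_max: int = 12
    pseudocount: float = 0.1


@dataclass(frozen=True)
class AlignConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    poisson_correction: bool = False


@dataclass(frozen=True)
class PrefilterConfig:
    #: retain a protein when its best local-alignment score against the query
    #: reaches this fraction of the query self-score
    score_fraction: float = 0.25


@dataclass(frozen=True)
class ScreenConfig:
    efscan: EFScanConfig = field(default_factory=EFScanConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    naf: NAFConfig = field(default_factory=NAFConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    seed: int = 0
    output_format: str = "tsv"

    def config_hash(self) -> str:
        """Stable hash of the full configuration, stamped into every output."""
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class ConfigError(ValueError):
    """Raised for malformed or contradictory configuration input."""


_SECTION_TYPES = {
    "efscan": EFScanConfig,
    "classify": ClassifyConfig,
    "naf": NAFConfig,
    "align": AlignConfig,
    "prefilter": PrefilterConfig,
}


def _build_section(cls, data: Mapping[str, Any]):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is EFScanConfig and "weights" in kwargs:
        kwargs["weights"] = _build_section(EFWeights, kwargs["weights"])
    if cls is EFScanConfig and "templates" in kwargs:
        kwargs["templates"] = tuple(kwargs["templates"])
    return cls(**kwargs)


def screen_config_from_dict(data: Mapping[str, Any]) -> ScreenConfig:
    cfg = ScreenConfig()
    extra = set(data) - set(_SECTION_TYPES) - {"seed", "output_format"}
    if extra:
        raise ConfigError(f"unknown config sections: {sorted(extra)}")
    updates: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            updates[name] = _build_section(cls, data[name])
    for key in ("seed", "output_format"):
        if key in data:
            updates[key] = data[key]
    return replace(cfg, **updates)


def load_screen_config(path: str | Path) -> ScreenConfig:
    """Load a ScreenConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        return ScreenConfig()
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return screen_config_from_dict(data)
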