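"""YAML configuration: grading cutoffs, merge maps, taxonomy, bins, matrix.

Every analysis default is expressible (and overridable) in one YAML
document; :func:`default_config_dict` emits the bundled defaults so a user
can dump, edit and reload them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigError
from .grading import (
    DEFAULT_MERGE_GROUPS,
    MANUFACTURER_CUTOFFS,
    GradingScheme,
    MergeMap,
    default_merge_maps,
    default_schemes,
)
from .risk import (
    DEFAULT_ERROR_TAXONOMY,
    CategoryCondition,
    ErrorDefinition,
    OccurrenceBinning,
    RiskMatrix,
)


@dataclass(frozen=True)
class AnalysisSettings:
    """Materialised configuration objects used by the pipeline."""

    schemes: Mapping[str, GradingScheme]
    merge_maps: Mapping[str, MergeMap]
    error_definitions: tuple[ErrorDefinition, ...]
    binning: OccurrenceBinning
    matrix: RiskMatrix
    occurrence_overrides: Mapping[str, int] = field(default_factory=dict)
    weight_scheme: str = "linear"
    rule: str = "ci_lower"
    threshold: float = 0.6


def default_config_dict() -> dict:
    """The bundled defaults as a plain serialisable mapping."""
    return {
        "grading": {p: list(c) for p, c in MANUFACTURER_CUTOFFS.items()},
        "merge": {p: [list(g) for g in gs] for p, gs in DEFAULT_MERGE_GROUPS.items()},
        "errors": [
            {
                "id": d.error_id,
                "parameter": d.parameter,
                "lo": d.condition.lo,
                "hi": d.condition.hi,
                "severity": d.severity,
            }
            for d in DEFAULT_ERROR_TAXONOMY
        ],
        "occurrence_edges": list(OccurrenceBinning().edges),
        "risk_overrides": [],
        "occurrence_overrides": {},
        "acceptability": {"rule": "ci_lower", "threshold": 0.6, "weights": "linear"},
    }


def settings_from_dict(cfg: Mapping) -> AnalysisSettings:
    """Build :class:`AnalysisSettings` from a (possibly partial) mapping."""
    cfg = dict(cfg or {})
    schemes = default_schemes()
    for p, cuts in (cfg.get("grading") or {}).items():
        schemes[p] = GradingScheme(p, tuple(cuts))
    merge_maps = default_merge_maps(schemes)
    for p, groups in (cfg.get("merge") or {}).items():
        if p not in schemes:
            raise ConfigError(f"merge map for unknown parameter {p!r}")
        merge_maps[p] = MergeMap(p, tuple(tuple(g) for g in groups))
    if "errors" in cfg and cfg["errors"] is not None:
        defs = tuple(
            ErrorDefinition(
                e["id"],
                e["parameter"],
                CategoryCondition(int(e["lo"]), int(e["hi"])),
                int(e["severity"]),
            )
            for e in cfg["errors"]
        )
        if len({d.error_id for d in defs}) != len(defs):
            raise ConfigError("duplicate error ids in taxonomy")
    else:
        defs = DEFAULT_ERROR_TAXONOMY
    edges = cfg.get("occurrence_edges")
    binning = OccurrenceBinning(tuple(edges)) if edges else OccurrenceBinning()
    overrides = {
        (int(o["severity"]), int(o["occurrence"])): o["class"]
        for o in (cfg.get("risk_overrides") or [])
    }
    matrix = RiskMatrix(overrides or None)
    acc = cfg.get("acceptability") or {}
    return AnalysisSettings(
        schemes=schemes,
        merge_maps=merge_maps,
        error_definitions=defs,
        binning=binning,
        matrix=matrix,
        occurrence_overrides={
            str(k): int(v) for k, v in (cfg.get("occurrence_overrides") or {}).items()
        },
        weight_scheme=acc.get("weights", "linear"),
        rule=acc.get("rule", "ci_lower"),
        threshold=float(acc.get("threshold", 0.6)),
    )


def load_settings(path) -> AnalysisSettings:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return settings_from_dict(cfg or {})


def save_config(path, cfg: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg if cfg is not None else default_config_dict(), fh)
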