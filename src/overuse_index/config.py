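"""Configuration: indicator-definition files and pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .indicators import IndicatorDefinition

__all__ = [
    "load_indicator_config",
    "default_indicator_definitions",
    "PipelineConfig",
]

_ALLOWED_KEYS = {
    "indicator_id",
    "name",
    "min_age",
    "max_age",
    "sex",
    "eligibility_dx_codes",
    "eligibility_px_codes",
    "event_codes",
    "attribution",
    "eligibility_window_days",
    "prefix_match",
}


def _parse_indicator_block(block: dict, pos: int) -> IndicatorDefinition:
    if not isinstance(block, dict):
        raise ValueError(f"indicator entry {pos}: expected a mapping, got {type(block).__name__}")
    unknown = set(block) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"indicator entry {pos}: unknown fields {sorted(unknown)}")
    for required in ("indicator_id", "name", "event_codes"):
        if required not in block:
            raise ValueError(f"indicator entry {pos}: missing required field {required!r}")
    kwargs = dict(block)
    for key in ("eligibility_dx_codes", "eligibility_px_codes", "event_codes"):
        if key in kwargs:
            kwargs[key] = tuple(str(c) for c in kwargs[key])
    try:
        return IndicatorDefinition(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"indicator entry {pos}: {exc}") from exc


def load_indicator_config(path) -> list[IndicatorDefinition]:
    """Parse and validate an indicator-definition YAML file.

    The file holds ``indicators:`` followed by one block per indicator.
    Duplicate indicator ids and schema violations are rejected with the
    offending entry named.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not doc or "indicators" not in doc or not doc["indicators"]:
        raise ValueError(f"{path}: no indicator definitions found")
    defs = [_parse_indicator_block(b, i + 1) for i, b in enumerate(doc["indicators"])]
    ids = [d.indicator_id for d in defs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate indicator ids {sorted(dupes)}")
    return defs


def default_indicator_definitions() -> list[IndicatorDefinition]:
    """The bundled default set of 17 indicator definitions."""
    ref = resources.files("overuse_index.data") / "default_indicators.yaml"
    with resources.as_file(ref) as p:
        return load_indicator_config(p)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (see :func:`overuse_index.pipeline.run_pipeline`).

    Paths are input tables as delimited text; ``indicator_config`` of ``None``
    uses the bundled defaults.
    """

    claims_path: str | None = None
    beneficiaries_path: str | None = None
    linkage_path: str | None = None
    characteristics_path: str | None = None
    indicator_config: str | None = None
    output_dir: str = "overuse_output"
    seed: int = 0
    min_eligible: int | None = None
    min_eligible_per_quarter: bool = False
    reference_quarter: int | None = None
    reference_indicator: int | None = None
    reference_system: str | None = None
    standardize_covariates: bool = True
    max_iter: int = 50
    tol: float = 1e-8
    gtol: float = 1e-5
    association_covariates: list = field(
        default_factory=lambda: ["pcp_tertile", "hospitals_tertile", "investor_owned", "major_teaching"]
    )
    association_state_mode: str = "fixed"  # fixed | random | none

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
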