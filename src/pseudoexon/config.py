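"""Pipeline configuration: strictly-validated YAML with sectioned keys.

Every threshold the pipeline applies lives here with its default visible,
so no cut-off is hidden inside a stage.  Unknown keys are rejected rather
than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import yaml

from .acmg import DEFAULT_THRESHOLD, DEFAULT_WEIGHTS
from .exonization import NMD_RULE_NT
from .prioritize import FilterConfig
from .rna_assays import IMBALANCE_THRESHOLD

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, grouped by stage."""

    # filters
    min_dp: int = 20
    min_ad_alt: int = 5
    vf_range: Tuple[float, float] = (0.2, 0.8)
    gene_panel: Tuple[str, ...] = ("SYNGENE1",)
    max_af: float = 0.01
    splice_score_min: float = 0.2
    splice_info_key: str = "SPLICEAI"
    # exonization / NMD
    nmd_threshold_nt: int = NMD_RULE_NT
    # RNA assays
    imbalance_threshold: float = IMBALANCE_THRESHOLD
    # ACMG
    acmg_weights: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    acmg_threshold: int = DEFAULT_THRESHOLD
    # samples and bookkeeping
    affected: str = "PROBAND"
    unaffected: str = "SIBLING"
    output_dir: str = "pseudoexon_out"
    seed: int = 1

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_dp=self.min_dp,
            min_ad_alt=self.min_ad_alt,
            vf_range=tuple(self.vf_range),
            gene_panel=frozenset(self.gene_panel),
            max_af=self.max_af,
            splice_score_min=self.splice_score_min,
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        sections = {
            "filters": {k: d[k] for k in (
                "min_dp", "min_ad_alt", "vf_range", "gene_panel", "max_af",
                "splice_score_min", "splice_info_key")},
            "nmd": {"nmd_threshold_nt": d["nmd_threshold_nt"]},
            "assays": {"imbalance_threshold": d["imbalance_threshold"]},
            "acmg": {"acmg_weights": d["acmg_weights"],
                     "acmg_threshold": d["acmg_threshold"]},
            "run": {k: d[k] for k in ("affected", "unaffected", "output_dir", "seed")},
        }
        return yaml.safe_dump(sections, sort_keys=False)


_SECTION_KEYS = {
    "filters": {"min_dp", "min_ad_alt", "vf_range", "gene_panel", "max_af",
                "splice_score_min", "splice_info_key"},
    "nmd": {"nmd_threshold_nt"},
    "assays": {"imbalance_threshold"},
    "acmg": {"acmg_weights", "acmg_threshold"},
    "run": {"affected", "unaffected", "output_dir", "seed"},
}


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Load a sectioned YAML config; flag overrides win over the file.

    Unknown sections or keys raise :class:`ConfigError` naming the
    offender.
    """
    values: Dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: top level must be a mapping of sections")
        for section, body in doc.items():
            if section not in _SECTION_KEYS:
                raise ConfigError(f"{path}: unknown section {section!r}")
            if body is None:
                continue
            if not isinstance(body, dict):
                raise ConfigError(f"{path}: section {section!r} must be a mapping")
            for key, val in body.items():
                if key not in _SECTION_KEYS[section]:
                    raise ConfigError(f"{path}: unknown key {section}.{key}")
                values[key] = val
    for key, val in overrides.items():
        if val is None:
            continue
        if not any(key in ks for ks in _SECTION_KEYS.values()):
            raise ConfigError(f"unknown config override {key!r}")
        values[key] = val
    if "vf_range" in values:
        values["vf_range"] = tuple(values["vf_range"])
    if "gene_panel" in values:
        panel = values["gene_panel"]
        values["gene_panel"] = tuple([panel] if isinstance(panel, str) else panel)
    try:
        cfg = PipelineConfig(**values)
        cfg.filter_config()  # validate thresholds eagerly
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg
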