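"""Pipeline configuration: a single YAML document with named defaults.

Every study constant is a named, overridable key: QC gates (1500/4000
counts, 30/10% mito, 35/20% ribo, 5000/10000 site minima, 50% and
10–40% global rates), k = 30 mapping neighbours, FDR 0.01 with
|log2FC| >= 1, the 75% pairwise marker rule, and the 50 bp / ±2 kb
profile windows. Unknown keys are rejected with the offending name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .de import DEParams, MarkerParams
from .epigenome import ProfileParams
from .mapping import MappingParams
from .qc import QCParams

__all__ = ["PipelineConfig", "FixtureParams", "StagingParams", "validate_config"]


@dataclass
class FixtureParams:
    """Synthetic fixture sizing for the end-to-end pipeline run."""

    n_cell_types: int = 3
    n_genes: int = 250
    n_markers_per_type: int = 15
    n_embryos_per_stage: int = 3
    n_cells_per_embryo: int = 150
    n_query_embryos: int = 3
    n_query_cells_per_embryo: int = 150
    depleted_cell_type_index: int = 0
    depletion_factor: float = 0.25
    ko_genotype: str = "Dnmt1KO"
    n_nmt_cells_per_genotype: int = 30
    n_features_per_class: int = 12


@dataclass
class StagingParams:
    pseudocount: float = 1.0
    n_pcs: int | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "embryokit_run"
    qc: QCParams = field(default_factory=QCParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    de: DEParams = field(default_factory=DEParams)
    markers: MarkerParams = field(default_factory=MarkerParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    staging: StagingParams = field(default_factory=StagingParams)
    fixtures: FixtureParams = field(default_factory=FixtureParams)

    def effective(self) -> dict:
        """Plain-dict echo of every effective parameter."""
        return dataclasses.asdict(self)


_SECTIONS = {
    "qc": QCParams,
    "mapping": MappingParams,
    "de": DEParams,
    "markers": MarkerParams,
    "profile": ProfileParams,
    "staging": StagingParams,
    "fixtures": FixtureParams,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"type mismatch in '{section}': {exc}") from exc


def validate_config(source) -> PipelineConfig:
    """Load and normalize a config from a YAML path, mapping or None.

    Fills defaults, rejects unknown keys (naming them), and lets each
    parameter dataclass validate its ranges.
    """
    if source is None:
        data = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        raise TypeError("config source must be a path, mapping or None")
    if not isinstance(data, dict):
        raise ValueError("config document must be a mapping")
    top_known = {"seed", "outdir"} | set(_SECTIONS)
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ValueError("key 'seed': expected an integer")
        kwargs["seed"] = data["seed"]
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    for section, cls in _SECTIONS.items():
        sub = data.get(section, {}) or {}
        if not isinstance(sub, dict):
            raise ValueError(f"section '{section}' must be a mapping")
        kwargs[section] = _build_section(cls, sub, section)
    return PipelineConfig(**kwargs)
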