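"""Run configuration: YAML config file with flag overrides.

A config file centralizes everything a published run needs to be
reproducible: structure paths, the cofactor label map, decay constants,
cutoffs, mutation specs, omics table paths and group design, statistical
thresholds, and seeds. Command-line flags override config values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .mutagenesis import MutationSpec
from .pathways import DecayModel


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # structural arm
    structure: str | None = None
    cofactors: dict[str, str] = field(default_factory=dict)
    donor: str | None = None
    acceptor: str | None = None
    mutations: list[str] = field(default_factory=list)
    space_cutoff: float = 6.0
    include_waters: bool = False
    k_paths: int = 1
    decay: DecayModel = field(default_factory=DecayModel)
    # omics arm
    omics_table: str | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)
    group_a: str | None = None
    group_b: str | None = None
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    min_set_size: int = 5
    n_perm: int = 1000
    impute_shift: float = 1.8
    impute_width: float = 0.3
    # shared
    seed: int = 0
    out_prefix: str = "etpath_out"

    def mutation_specs(self) -> list[MutationSpec]:
        return [MutationSpec.parse(m) for m in self.mutations]

    def validate(self, require_structure: bool = False, require_omics: bool = False) -> None:
        for thr in (self.p_threshold, self.fdr_threshold):
            if not (0.0 < thr <= 1.0):
                raise ConfigError(f"threshold {thr} outside (0, 1]")
        if self.min_set_size < 1:
            raise ConfigError("min_set_size must be >= 1")
        if require_structure:
            if not self.structure:
                raise ConfigError("no structure file configured")
            if not os.path.exists(self.structure):
                raise ConfigError(f"structure file not found: {self.structure}")
            if len(self.cofactors) < 2:
                raise ConfigError("cofactor label map needs at least two entries")
        if require_omics:
            if not self.omics_table:
                raise ConfigError("no omics table configured")
            if not os.path.exists(self.omics_table):
                raise ConfigError(f"omics table not found: {self.omics_table}")
            if len(self.groups) < 2:
                raise ConfigError("group design needs at least two groups")
        self.mutation_specs()  # raises on malformed specs


def load_config(path: str | None, **overrides) -> RunConfig:
    """Load a YAML config (optional) and apply non-None flag overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    decay_data = data.pop("decay", {})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if decay_data:
        cfg.decay = DecayModel(**decay_data)
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in known:
            raise ConfigError(f"unknown override {key!r}")
        setattr(cfg, key, value)
    return cfg
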