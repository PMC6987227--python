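"""Run configuration: cutoffs, class tables, model hyperparameters, modes.

A flat YAML file can override any default; unknown keys are rejected so
typos fail loudly.  CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .classify import (
    BINDING_CUTOFF,
    DOUBLE_I_MAX_BINDING_PCT,
    DOUBLE_III_MIN_BINDING_PCT,
    DUPLEX_MIN_PAIRED_FRACTION,
    SS_MAX_PAIRED_FRACTION,
)
from .dna import C1C1_RANGE, N1N3_RANGE
from .modeling import StackParams
from .protein import ResidueClassTable


@dataclass
class RunConfig:
    seed: int = 0
    binding_cutoff: float = BINDING_CUTOFF
    n1n3_min: float = N1N3_RANGE[0]
    n1n3_max: float = N1N3_RANGE[1]
    c1c1_min: float = C1C1_RANGE[0]
    c1c1_max: float = C1C1_RANGE[1]
    ss_max_paired_fraction: float = SS_MAX_PAIRED_FRACTION
    duplex_min_paired_fraction: float = DUPLEX_MIN_PAIRED_FRACTION
    double1_max_binding_pct: float = DOUBLE_I_MAX_BINDING_PCT
    double3_min_binding_pct: float = DOUBLE_III_MIN_BINDING_PCT
    sasa_probe: float = 1.4
    sasa_points: int = 960
    selection_top: int = 10
    selection_max_k: int = 5
    selection_epsilon: float = 1e-4
    stack_mode: str = "oof"  # or "paper_naive"
    eval_mode: str = "honest"  # or "paper"
    hydrophobic: str = "AVLIMFWCPG"
    hydrophilic: str = "RNDQEHKSTY"
    aromatic_positive: str = "FWYHRK"
    polar: str = "STNQCY"
    charged: str = "DEKRH"
    stack: StackParams = field(default_factory=StackParams)

    def __post_init__(self):
        if self.stack_mode not in ("oof", "paper_naive"):
            raise ValueError(f"stack_mode {self.stack_mode!r}")
        if self.eval_mode not in ("honest", "paper"):
            raise ValueError(f"eval_mode {self.eval_mode!r}")
        if not self.n1n3_min < self.n1n3_max:
            raise ValueError("n1n3 range inverted")
        if not self.c1c1_min < self.c1c1_max:
            raise ValueError("c1c1 range inverted")
        if self.binding_cutoff <= 0:
            raise ValueError("binding_cutoff must be positive")
        # Validates the partition invariants.
        self.class_table()

    def class_table(self) -> ResidueClassTable:
        return ResidueClassTable(
            hydrophobic=frozenset(self.hydrophobic),
            hydrophilic=frozenset(self.hydrophilic),
            aromatic_positive=frozenset(self.aromatic_positive),
            polar=frozenset(self.polar),
            charged=frozenset(self.charged),
        )

    @property
    def n1n3_range(self) -> tuple[float, float]:
        return (self.n1n3_min, self.n1n3_max)

    @property
    def c1c1_range(self) -> tuple[float, float]:
        return (self.c1c1_min, self.c1c1_max)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stack_data = data.pop("stack", None)
        cfg = cls(**data)
        if stack_data is not None:
            stack_known = {f.name for f in fields(StackParams)}
            stack_unknown = set(stack_data) - stack_known
            if stack_unknown:
                raise ValueError(f"unknown stack keys: {sorted(stack_unknown)}")
            cfg.stack = StackParams(**stack_data)
        return cfg
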