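"""Pipeline configuration: every tunable in one validated dataclass.

Values come from (highest precedence first) CLI flags, a YAML config
file, and the built-in defaults, which follow the published protocol
where it states one: 500-nt windows, the 60-nt / 16-bp hairpin filters,
a 60-nt trimming minimum, a 10-tree ranking forest.  The windowing step
(300, i.e. 200 nt of overlap — longer than any expected plant
pre-miRNA) and both-strand scanning are this package's defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass(frozen=True)
class PipelineConfig:
    window_length: int = 500
    step: int = 300
    strands: tuple[str, ...] = ("+", "-")
    max_n_fraction: float = 0.1
    min_hairpin_length: int = 60
    min_pairs: int = 16
    trim_min_length: int = 60
    trim_min_from_reference: bool = False
    backend: str = "toy"
    min_identity: float = 0.9
    min_coverage: float = 0.9
    n_trees: int = 10
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        if self.window_length <= 0 or self.step <= 0:
            raise ParameterError("window_length and step must be positive")
        if self.step > self.window_length:
            raise ParameterError("step must not exceed window_length")
        if self.min_hairpin_length < 1 or self.trim_min_length < 1:
            raise ParameterError("minimum lengths must be >= 1")
        if self.min_pairs < 0:
            raise ParameterError("min_pairs must be >= 0")
        for t in (self.min_identity, self.min_coverage):
            if not 0.0 < t <= 1.0:
                raise ParameterError("matcher thresholds must lie in (0, 1]")
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ParameterError("max_n_fraction must lie in [0, 1]")
        for s in self.strands:
            if s not in "+-":
                raise ParameterError(f"unknown strand {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "strands" in data:
            data["strands"] = tuple(data["strands"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        if "strands" in clean:
            clean["strands"] = tuple(clean["strands"])
        return replace(self, **clean)
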