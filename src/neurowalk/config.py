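"""YAML pipeline configuration with explicit validation.

The config fully determines a run together with the global seed; it
round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

_CONNECTIVITY = ("pearson", "partial", "tangent")
_METHODS = ("node2vec", "deepwalk", "struc2vec", "awe")
_SCENARIOS = ("s1", "s2", "s3")
_SCHEMES = ("kfold", "loso")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    connectivity_kind: str = "pearson"
    embedding_method: str = "node2vec"
    scenario: str = "s3"
    d: int = 25
    p: float = 1.0
    q: float = 1.0
    K: int = 3
    eta: int = 1000
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    epochs_sg: int = 5
    r: int = 10
    cnn_epochs: int = 100
    cnn_patience: int = 15
    batch_size: int = 16
    learning_rate: float = 1e-3
    scheme: str = "loso"
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.connectivity_kind not in _CONNECTIVITY:
            raise ValueError(f"connectivity_kind must be one of {_CONNECTIVITY}")
        if self.embedding_method not in _METHODS:
            raise ValueError(f"embedding_method must be one of {_METHODS}")
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        for name in ("d", "K", "eta", "walks_per_node", "walk_length", "window",
                     "epochs_sg", "r", "cnn_epochs", "batch_size", "k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.p <= 0 or self.q <= 0 or self.learning_rate <= 0:
            raise ValueError("p, q and learning_rate must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
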