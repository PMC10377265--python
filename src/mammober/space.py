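"""Hyperparameter search space and genome decoding.

The optimizer works on real vectors in the unit hypercube; this module owns
the fixed, ordered list of CNN hyperparameters being searched (three conv
blocks' filter counts and kernel sizes, the dense-layer width, the
activation, the learning rate, the mini-batch size and the dropout rate)
and the decoding of a position vector into a concrete
:class:`CNNConfig`. A categorical parameter with m choices maps coordinate
u to index min(floor(u*m), m-1) — uniform-width bins, so a uniform u picks
each choice with probability 1/m; a continuous parameter maps affinely onto
its bounds. Decoding is total and deterministic, and is invariant under the
optimizer's bound-clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import yaml

__all__ = ["ParamSpec", "SearchSpace", "CNNConfig", "default_space", "decode"]


@dataclass(frozen=True)
class ParamSpec:
    name: str
    kind: str  # "categorical" | "continuous"
    choices: tuple = ()  # categorical: ordered values; continuous: (low, high)

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if len(self.choices) < 1:
                raise ValueError(f"{self.name}: categorical needs >= 1 choice")
        elif self.kind == "continuous":
            if len(self.choices) != 2 or not self.choices[0] < self.choices[1]:
                raise ValueError(f"{self.name}: continuous needs low < high")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def decode_one(self, u: float) -> object:
        if not math.isfinite(u):
            raise ValueError(f"{self.name}: non-finite coordinate {u}")
        if self.kind == "categorical":
            m = len(self.choices)
            idx = min(int(math.floor(u * m)), m - 1)
            idx = max(idx, 0)
            return self.choices[idx]
        low, high = self.choices
        return low + min(max(u, 0.0), 1.0) * (high - low)


@dataclass(frozen=True)
class SearchSpace:
    params: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def dimension(self) -> int:
        return len(self.params)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            [
                {"name": p.name, "kind": p.kind, "choices": list(p.choices)}
                for p in self.params
            ],
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SearchSpace":
        entries = yaml.safe_load(text)
        return cls(
            params=tuple(
                ParamSpec(e["name"], e["kind"], tuple(e["choices"])) for e in entries
            )
        )


@dataclass(frozen=True)
class CNNConfig:
    """A concrete point of the search grid (see :func:`default_space`)."""

    filters_1: int
    ksize_1: int
    filters_2: int
    ksize_2: int
    filters_3: int
    ksize_3: int
    full_hidden1: int
    activation: str
    learning_rate: float
    batch_size: int
    dropout: float

    def as_dict(self) -> dict:
        return {
            "filters_1": self.filters_1, "ksize_1": self.ksize_1,
            "filters_2": self.filters_2, "ksize_2": self.ksize_2,
            "filters_3": self.filters_3, "ksize_3": self.ksize_3,
            "full_hidden1": self.full_hidden1, "activation": self.activation,
            "learning_rate": self.learning_rate, "batch_size": self.batch_size,
            "dropout": self.dropout,
        }


# Versioned, fixed parameter order: positions are portable across runs.
_DEFAULT_PARAMS: tuple[ParamSpec, ...] = (
    ParamSpec("filters_1", "categorical", (16, 32, 64, 96)),
    ParamSpec("ksize_1", "categorical", (3, 4, 5)),
    ParamSpec("filters_2", "categorical", (48, 64, 96, 128)),
    ParamSpec("ksize_2", "categorical", (3, 4, 5)),
    ParamSpec("filters_3", "categorical", (64, 96, 128)),
    ParamSpec("ksize_3", "categorical", (3, 4, 5)),
    ParamSpec("full_hidden1", "categorical", (60, 100, 125)),
    ParamSpec("activation", "categorical", ("relu", "lrelu", "elu")),
    ParamSpec("learning_rate", "categorical", (0.001, 0.003, 0.01, 0.03)),
    ParamSpec("batch_size", "categorical", (16, 32, 64, 128)),
    ParamSpec("dropout", "categorical", (0.2, 0.3, 0.4, 0.5, 0.6)),
)


def default_space() -> SearchSpace:
    """The 11-parameter space: structure (8 params) + training (3 params)."""
    return SearchSpace(params=_DEFAULT_PARAMS)


def decode(position: Sequence[float], space: SearchSpace | None = None) -> CNNConfig:
    """Decode a unit-hypercube position into a :class:`CNNConfig`."""
    space = space or default_space()
    if len(position) != space.dimension:
        raise ValueError(
            f"position has length {len(position)}, expected {space.dimension}"
        )
    values = {p.name: p.decode_one(float(u)) for p, u in zip(space.params, position)}
    return CNNConfig(**values)
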