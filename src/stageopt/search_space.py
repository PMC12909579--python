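"""Typed, box-constrained hyperparameter spaces and genotype encoding.

A :class:`SearchSpace` is an ordered list of :class:`ParamSpec` entries; a
genotype is a plain float array with one value per parameter, in space order.
The three built-in spaces cover the tier-1 CNN and the two tier-2 boosters
(XGBoost, LightGBM).  The single published "cells per layer" range is
expanded into four independent per-layer width parameters (conv1, conv2,
dense1, dense2); widths of layers that the layer-count parameters disable
remain in the genotype but are ignored when the genotype is decoded into a
model, which keeps genotype length fixed for the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ParamSpec",
    "SearchSpace",
    "builtin_space",
    "sample_uniform",
    "repair",
    "space_to_dict",
    "space_from_dict",
    "save_space",
    "load_space",
]

CONTINUOUS = "continuous"
INTEGER = "integer"


@dataclass(frozen=True)
class ParamSpec:
    """One bounded hyperparameter: name, kind and inclusive [low, high] bounds.

    ``active_when`` optionally names a predicate on the full genotype that
    decides whether this parameter is decoded (used for the per-layer widths
    whose layer may be switched off).
    """

    name: str
    kind: str
    low: float
    high: float
    active_when: Optional[Callable[[Sequence[float]], bool]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, INTEGER):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.low > self.high:
            raise ValueError(f"{self.name}: low {self.low} > high {self.high}")
        if self.kind == INTEGER and (
            self.low != int(self.low) or self.high != int(self.high)
        ):
            raise ValueError(f"{self.name}: integer bounds must be integers")


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of parameters; defines the genotype layout."""

    params: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if len(self.params) < 1:
            raise ValueError("a search space needs at least one parameter")

    @property
    def dimensionality(self) -> int:
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def lows(self) -> np.ndarray:
        return np.array([p.low for p in self.params], dtype=float)

    @property
    def highs(self) -> np.ndarray:
        return np.array([p.high for p in self.params], dtype=float)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def decode(self, genotype: Sequence[float]) -> dict[str, float]:
        """Map a genotype to a {name: value} dict, dropping inactive params."""
        g = np.asarray(genotype, dtype=float)
        out: dict[str, float] = {}
        for spec, v in zip(self.params, g):
            if spec.active_when is not None and not spec.active_when(g):
                continue
            out[spec.name] = int(v) if spec.kind == INTEGER else float(v)
        return out


def _cnn_space() -> SearchSpace:
    # lr, dropout, epochs, conv/dense layer counts + 4 per-layer widths = 9
    def _two_conv(g: Sequence[float]) -> bool:
        return int(round(g[3])) >= 2

    def _two_dense(g: Sequence[float]) -> bool:
        return int(round(g[4])) >= 2

    return SearchSpace(
        (
            ParamSpec("learning_rate", CONTINUOUS, 0.0001, 0.003),
            ParamSpec("dropout", CONTINUOUS, 0.05, 0.2),
            ParamSpec("epochs", INTEGER, 10, 30),
            ParamSpec("n_conv_layers", INTEGER, 1, 2),
            ParamSpec("n_dense_layers", INTEGER, 1, 2),
            ParamSpec("conv_width_1", INTEGER, 32, 96),
            ParamSpec("conv_width_2", INTEGER, 32, 96, active_when=_two_conv),
            ParamSpec("dense_width_1", INTEGER, 32, 96),
            ParamSpec("dense_width_2", INTEGER, 32, 96, active_when=_two_dense),
        )
    )


def _xgb_space() -> SearchSpace:
    return SearchSpace(
        (
            ParamSpec("learning_rate", CONTINUOUS, 0.1, 0.9),
            ParamSpec("min_child_weight", CONTINUOUS, 1, 5),
            ParamSpec("subsample", CONTINUOUS, 0.01, 1),
            ParamSpec("colsample_bytree", CONTINUOUS, 0.01, 1),
            ParamSpec("max_depth", INTEGER, 1, 5),
            ParamSpec("gamma", CONTINUOUS, 0, 0.8),
        )
    )


def _lgbm_space() -> SearchSpace:
    return SearchSpace(
        (
            ParamSpec("n_rounds", INTEGER, 5, 20),
            ParamSpec("max_depth", INTEGER, 3, 10),
            ParamSpec("n_leaves", INTEGER, 3, 10),
            ParamSpec("min_child_weight", CONTINUOUS, 1, 5),
            ParamSpec("feature_fraction", CONTINUOUS, 0.1, 0.9),
            ParamSpec("bagging_fraction", CONTINUOUS, 0.5, 1),
            ParamSpec("min_split_gain", CONTINUOUS, 0.001, 0.1),
            ParamSpec("lambda_l1", CONTINUOUS, 0, 5),
            ParamSpec("lambda_l2", CONTINUOUS, 0, 3),
            ParamSpec("learning_rate", CONTINUOUS, 0.01, 0.9),
        )
    )


def builtin_space(layer_id: str) -> SearchSpace:
    """Return one of the three published hyperparameter spaces.

    ``L1_CNN`` has 9 parameters (learning rate, dropout, epochs, conv/dense
    layer counts and four per-layer widths in [32, 96]); ``L2_XGB`` has 6;
    ``L2_LGBM`` has 10.
    """
    if layer_id == "L1_CNN":
        return _cnn_space()
    if layer_id == "L2_XGB":
        return _xgb_space()
    if layer_id == "L2_LGBM":
        return _lgbm_space()
    raise ValueError(f"unknown layer_id {layer_id!r}; expected L1_CNN, L2_XGB or L2_LGBM")


def repair(genotype: Sequence[float], space: SearchSpace) -> np.ndarray:
    """Clip every value into its bounds; round integer dims half-up, then clip.

    Idempotent: repairing an already valid genotype returns it unchanged.
    """
    g = np.asarray(genotype, dtype=float)
    if g.shape != (space.dimensionality,):
        raise ValueError(
            f"genotype length {g.shape} does not match space "
            f"dimensionality {space.dimensionality}"
        )
    out = g.copy()
    for j, spec in enumerate(space.params):
        v = out[j]
        if spec.kind == INTEGER:
            v = math.floor(v + 0.5)  # round half up
        out[j] = min(max(v, spec.low), spec.high)
    return out


def sample_uniform(space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Draw one genotype uniformly inside the box, repaired to the space."""
    g = rng.uniform(space.lows, space.highs)
    return repair(g, space)


# ---------------------------------------------------------------------------
# serialization (active_when predicates are structural and restored by name
# for the builtin CNN space; custom predicates do not round-trip)

def space_to_dict(space: SearchSpace) -> list[dict]:
    return [
        {"name": p.name, "kind": p.kind, "low": p.low, "high": p.high}
        for p in space.params
    ]


def space_from_dict(entries: list[dict]) -> SearchSpace:
    return SearchSpace(
        tuple(
            ParamSpec(e["name"], e["kind"], float(e["low"]), float(e["high"]))
            for e in entries
        )
    )


def save_space(space: SearchSpace, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"params": space_to_dict(space)}, fh, sort_keys=False)


def load_space(path) -> SearchSpace:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return space_from_dict(data["params"])
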