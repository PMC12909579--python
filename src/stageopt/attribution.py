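"""Shapley-value feature attribution for the tier-2 classifier.

Explains single predictions of the booster over CNN embeddings.  Missing
features are handled interventionally: the value of a coalition S is the
model output at the sample with the features outside S replaced by
background rows, averaged over the background set.

Two estimators are provided.  :func:`shapley_exact` enumerates all 2^d
coalitions (the classical definition; usable up to d = 12) and serves as
the reference.  :func:`shapley_kernel` is the weighted-least-squares kernel
estimator: coalitions are sampled with probability proportional to the
Shapley kernel weight (d-1) / (C(d,|S|) |S| (d-|S|)), a linear model is fit
to the coalition values, and the efficiency constraint — attributions sum
to f(x) minus the base value — is enforced by eliminating one coefficient.
When the coalition budget covers every non-trivial subset the kernel
estimate coincides with the exact Shapley values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["AttributionResult", "shapley_exact", "shapley_kernel"]


@dataclass
class AttributionResult:
    """Per-feature attributions for one sample and one output."""

    values: np.ndarray
    base_value: float
    prediction: float

    @property
    def efficiency_gap(self) -> float:
        return abs(self.base_value + float(self.values.sum()) - self.prediction)


def _coalition_values(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """v(S) for each mask row: mean_b f(x_S, b_notS) over the background."""
    n_mask = masks.shape[0]
    n_bg, d = background.shape
    # tile: for each mask, |B| synthetic rows
    synth = np.repeat(background[None, :, :], n_mask, axis=0)  # (m, B, d)
    synth[:, :, :] = np.where(masks[:, None, :], x[None, None, :], synth)
    out = np.asarray(f(synth.reshape(-1, d)), dtype=float)
    return out.reshape(n_mask, n_bg).mean(axis=1)


def shapley_exact(
    f: Callable[[np.ndarray], np.ndarray],
    x,
    background,
    max_features: int = 12,
) -> AttributionResult:
    """Exact Shapley values by full coalition enumeration (d <= 12).

    ``f`` maps an (n, d) array to n scalar outputs (for a classifier, pass
    a closure over the class index of interest).
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if d > max_features:
        raise ValueError(f"exact enumeration limited to {max_features} features")
    masks = np.array(
        list(itertools.product([False, True], repeat=d)), dtype=bool
    )  # 2^d rows; row index = bitmask
    v = _coalition_values(f, x, background, masks)
    index = {tuple(m): i for i, m in enumerate(masks)}
    fact = [math.factorial(k) for k in range(d + 1)]
    phi = np.zeros(d)
    for i in range(d):
        for m in masks[~masks[:, i]]:
            s = int(m.sum())
            weight = fact[s] * fact[d - s - 1] / fact[d]
            with_i = m.copy()
            with_i[i] = True
            phi[i] += weight * (v[index[tuple(with_i)]] - v[index[tuple(m)]])
    base = v[0]  # empty coalition
    pred = v[-1]  # full coalition == f(x)
    return AttributionResult(phi, float(base), float(pred))


def _kernel_weights(d: int) -> np.ndarray:
    """Shapley kernel weight per coalition size 1..d-1."""
    sizes = np.arange(1, d)
    return (d - 1) / (
        np.array([math.comb(d, s) for s in sizes]) * sizes * (d - sizes)
    )


def shapley_kernel(
    f: Callable[[np.ndarray], np.ndarray],
    x,
    background,
    n_coalitions: int,
    seed: int = 0,
) -> AttributionResult:
    """Kernel estimator of the Shapley values.

    If ``n_coalitions`` covers all 2^d - 2 non-trivial coalitions they are
    enumerated with analytic kernel weights (and the estimate is exact);
    otherwise coalitions are sampled with probability proportional to their
    kernel weight and weighted by their sampled frequency.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if n_coalitions < d + 2:
        raise ValueError("need at least d + 2 coalitions")
    rng = np.random.default_rng(seed)

    n_all = 2 ** d - 2
    if n_coalitions >= n_all:
        masks = np.array(
            [m for m in itertools.product([False, True], repeat=d)
             if 0 < sum(m) < d],
            dtype=bool,
        )
        size_w = _kernel_weights(d)
        weights = size_w[masks.sum(axis=1) - 1]
    else:
        size_w = _kernel_weights(d)
        size_p = size_w * np.array([math.comb(d, s) for s in range(1, d)])
        size_p = size_p / size_p.sum()
        sizes = rng.choice(np.arange(1, d), size=n_coalitions, p=size_p)
        mask_list = []
        for s in sizes:
            m = np.zeros(d, dtype=bool)
            m[rng.choice(d, size=int(s), replace=False)] = True
            mask_list.append(m)
        uniq, counts = np.unique(np.array(mask_list), axis=0, return_counts=True)
        masks, weights = uniq, counts.astype(float)
    if len(masks) < d + 1:
        raise ValueError("degenerate coalition sample: too few distinct coalitions")

    empty_full = np.array([[False] * d, [True] * d], dtype=bool)
    v_ends = _coalition_values(f, x, background, empty_full)
    base, pred = float(v_ends[0]), float(v_ends[1])
    v = _coalition_values(f, x, background, masks)

    # weighted least squares with the efficiency constraint
    # sum(phi) = pred - base eliminated through the last coefficient
    z = masks.astype(float)
    y = v - base - z[:, -1] * (pred - base)
    a = z[:, :-1] - z[:, [-1]]
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
    phi = np.empty(d)
    phi[:-1] = coef
    phi[-1] = (pred - base) - coef.sum()
    return AttributionResult(phi, base, pred)
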