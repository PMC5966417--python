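"""Analytic test processes.

Small deterministic generators whose TE or darwin-rate values are known in
closed form, so the analysis stages can be validated without long
simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixtureSpec",
    "make_pair",
    "make_trend",
    "coupled_markov_te",
    "PAIR_KINDS",
    "TREND_KINDS",
]

PAIR_KINDS = ("iid_uniform", "lag1_copy", "coupled_markov")
TREND_KINDS = ("exp_trend", "alternating", "constant")


@dataclass(frozen=True)
class FixtureSpec:
    """Which process to generate, at what length, under which seed.

    ``eps`` applies to coupled_markov; ``r``/``v0`` to exp_trend; ``a``/``b``
    to alternating; ``c`` to constant; ``levels`` to the symbol alphabets.
    """

    kind: str
    length: int
    seed: int = 0
    eps: float = 0.1
    r: float = 0.01
    v0: float = 1.0
    a: float = 1.0
    b: float = math.e
    c: float = 1.0
    levels: int = 5

    def __post_init__(self):
        if self.kind not in PAIR_KINDS + TREND_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must be in [0, 1]")


def make_pair(spec: FixtureSpec,
              rng: np.random.Generator | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """A coupled pair of symbol sequences with known dependence.

    iid_uniform:    x, y independent uniform over the alphabet (TE = 0).
    lag1_copy:      y[t] = x[t-1]; TE(x -> y) = log2(levels).
    coupled_markov: y[t] copies x[t-1] with probability 1 - eps, otherwise
                    uniform; TE(x -> y) = :func:`coupled_markov_te`.
    """
    if spec.kind not in PAIR_KINDS:
        raise ValueError(f"{spec.kind!r} is not a pair fixture")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, k = spec.length, spec.levels
    x = rng.integers(0, k, size=n)
    if spec.kind == "iid_uniform":
        y = rng.integers(0, k, size=n)
    elif spec.kind == "lag1_copy":
        y = np.empty(n, dtype=np.int64)
        y[0] = rng.integers(0, k)
        y[1:] = x[:-1]
    else:  # coupled_markov
        noise = rng.integers(0, k, size=n)
        copy = rng.random(n) < 1.0 - spec.eps
        y = noise.copy()
        y[1:][copy[1:]] = x[:-1][copy[1:]]
    return x, y


def make_trend(spec: FixtureSpec,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """A real-valued series with a closed-form darwin-rate profile.

    exp_trend:   v[t] = v0 * exp(r t) — rate exactly r at every interval.
    alternating: a, b, a, b, ... — |rate| = |ln(b/a)| / dt for odd dt,
                 0 for even dt.
    constant:    all rates 0.
    """
    if spec.kind not in TREND_KINDS:
        raise ValueError(f"{spec.kind!r} is not a trend fixture")
    t = np.arange(spec.length, dtype=float)
    if spec.kind == "exp_trend":
        return spec.v0 * np.exp(spec.r * t)
    if spec.kind == "alternating":
        out = np.where(np.arange(spec.length) % 2 == 0, spec.a, spec.b)
        return out.astype(float)
    return np.full(spec.length, float(spec.c))


def coupled_markov_te(eps: float, levels: int = 5) -> float:
    """Analytic TE(x -> y) in bits for the coupled_markov pair.

    Given x[t], the next y is x[t] with probability 1 - eps + eps/levels and
    each other symbol with probability eps/levels, so
    TE = log2(levels) - H(that distribution).  eps = 1 reduces to
    independence (TE = 0); eps = 0 is the copy channel (TE = log2(levels)).
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must be in [0, 1]")
    k = levels
    p_hit = 1.0 - eps + eps / k
    p_miss = eps / k
    h = 0.0
    if p_hit > 0:
        h -= p_hit * math.log2(p_hit)
    if p_miss > 0:
        h -= (k - 1) * p_miss * math.log2(p_miss)
    return math.log2(k) - h
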