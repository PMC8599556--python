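"""Age target transforms used by the clocks.

Three target scales are supported:

``identity``
    Raw chronological age in years (the single-species blood clock).
``loglinear``
    Logarithmic below the species' age of sexual maturity *m*, linear
    above it, continuous and differentiable at *m*.  Used as the
    regression target for dual-species chronological clocks so that the
    fast juvenile phase and the long adult phase contribute comparable
    dynamic range.
``relative``
    Age divided by the species' maximum recorded lifespan; a
    dimensionless number in [0, 1] that makes species with very
    different lifespans directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgeTransformSpec",
    "loglinear",
    "loglinear_inverse",
    "relative_age",
]

TRANSFORM_KINDS = ("identity", "loglinear", "relative")


def loglinear(age, maturity: float, offset: float = 0.0):
    """Log-linear age transform.

    ``F(a) = log((a + offset) / (m + offset))`` for ``a < m`` and
    ``F(a) = (a - m) / (m + offset)`` for ``a >= m``.  The two branches
    meet at ``F(m) = 0`` with common slope ``1 / (m + offset)``, so the
    transform is continuous and differentiable everywhere.

    Parameters
    ----------
    age : float or array-like
        Chronological age in years, nonnegative.
    maturity : float
        Age of sexual maturity *m* in years, > 0.
    offset : float
        Nonnegative shift in years that keeps the logarithm finite at
        age 0 (required when newborns, ``age == 0``, are present).

    Returns
    -------
    float or ndarray
        Transformed age, strictly increasing in ``age``.
    """
    m = float(maturity)
    off = float(offset)
    if m <= 0:
        raise ValueError(f"maturity must be positive, got {m}")
    if off < 0:
        raise ValueError(f"offset must be nonnegative, got {off}")
    a = np.asarray(age, dtype=float)
    if np.any(a + off <= 0):
        raise ValueError("age + offset must be positive for the log branch")
    young = np.log((a + off) / (m + off))
    adult = (a - m) / (m + off)
    out = np.where(a < m, young, adult)
    return out.item() if np.isscalar(age) or np.ndim(age) == 0 else out


def loglinear_inverse(y, maturity: float, offset: float = 0.0, floor_at_zero: bool = False):
    """Exact inverse of :func:`loglinear` on all of the real line.

    ``age = (m + offset) * exp(y) - offset`` for ``y < 0`` and
    ``age = y * (m + offset) + m`` for ``y >= 0``.  Large negative
    inputs approach ``-offset`` from above; pass ``floor_at_zero`` to
    clip reported ages at 0.
    """
    m = float(maturity)
    off = float(offset)
    if m <= 0:
        raise ValueError(f"maturity must be positive, got {m}")
    if off < 0:
        raise ValueError(f"offset must be nonnegative, got {off}")
    v = np.asarray(y, dtype=float)
    young = (m + off) * np.exp(v) - off
    adult = v * (m + off) + m
    out = np.where(v < 0, young, adult)
    if floor_at_zero:
        out = np.maximum(out, 0.0)
    return out.item() if np.isscalar(y) or np.ndim(y) == 0 else out


def relative_age(age, max_lifespan: float):
    """Relative age: chronological age divided by the species' maximum
    recorded lifespan (e.g. 30 y for domestic cats, 122 y for humans).

    The quotient is returned exactly, not clamped: a record-breaking
    individual can exceed 1.
    """
    L = float(max_lifespan)
    if L <= 0:
        raise ValueError(f"max_lifespan must be positive, got {L}")
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be nonnegative")
    out = a / L
    return out.item() if np.isscalar(age) or np.ndim(age) == 0 else out


@dataclass(frozen=True)
class AgeTransformSpec:
    """Per-species parameterization of an age transform.

    kind : one of ``identity``, ``loglinear``, ``relative``
    maturity, offset : years; used by the loglinear branch
    max_lifespan : years; used by the relative branch
    """

    kind: str = "identity"
    maturity: float = 1.0
    offset: float = 0.0
    max_lifespan: float = 30.0

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; expected one of {TRANSFORM_KINDS}")
        if self.kind == "loglinear":
            if self.maturity <= 0:
                raise ValueError("maturity must be > 0 for loglinear transform")
            if self.offset < 0:
                raise ValueError("offset must be >= 0")
        if self.kind == "relative" and self.max_lifespan <= 0:
            raise ValueError("max_lifespan must be > 0 for relative transform")

    def transform(self, age):
        if self.kind == "identity":
            a = np.asarray(age, dtype=float)
            return a.item() if np.ndim(age) == 0 else a
        if self.kind == "loglinear":
            return loglinear(age, self.maturity, self.offset)
        return relative_age(age, self.max_lifespan)

    def inverse(self, y, floor_at_zero: bool = False):
        if self.kind == "identity":
            v = np.asarray(y, dtype=float)
            if floor_at_zero:
                v = np.maximum(v, 0.0)
            return v.item() if np.ndim(y) == 0 else v
        if self.kind == "loglinear":
            return loglinear_inverse(y, self.maturity, self.offset, floor_at_zero=floor_at_zero)
        # relative: the model already predicts the ratio; optionally clamp
        v = np.asarray(y, dtype=float)
        if floor_at_zero:
            v = np.maximum(v, 0.0)
        return v.item() if np.ndim(y) == 0 else v
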