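"""Monte Carlo machinery: uncertain inputs, draw vectors, summaries.

Uncertainty is propagated by expanding every uncertain input into a vector of
draws (1,000 by default), doing all pipeline arithmetic element-wise on
aligned draws, and reading the 95% uncertainty interval off the 2.5th and
97.5th empirical percentiles of the output draws (linear interpolation
between order statistics, numpy's default "linear"/type-7 rule).

Distribution conventions
------------------------
* ``normal`` — draws ~ Normal(mean, se); used for survey proportions, with
  truncation to the valid support by resampling.
* ``lognormal`` — draws = exp(Normal(mu, s)) with ``s`` the log-scale se.
  By default ``mu = ln(mean) - s**2/2`` so the *mean* of the draws equals the
  stated mean (``anchor="mean"``); ``anchor="median"`` puts the stated value
  at the median instead. An interval (L, U) converts to the sampling-scale se
  as ``(U - L) / 3.92`` (log scale for lognormal).

Seeding: a master seed is combined with a stable hash of each parameter's
label, so adding one parameter never shifts any other parameter's stream.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np

DEFAULT_N_DRAWS = 1000
_Z95 = 3.92  # width of a 95% normal interval in se units (2 x 1.96)


class DrawError(ValueError):
    pass


@dataclass(frozen=True)
class UncertainValue:
    """A scalar input with a mean and an uncertainty level.

    ``spread`` is either a standard error (``se=``) or a 95% interval
    (``lower=``/``upper=``) on the sampling scale. ``distribution`` is
    ``"normal"`` or ``"lognormal"``.
    """

    mean: float
    se: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    distribution: Literal["normal", "lognormal"] = "normal"

    def __post_init__(self) -> None:
        if self.se is not None and self.se < 0:
            raise DrawError("standard error must be >= 0")
        if (self.lower is None) != (self.upper is None):
            raise DrawError("interval needs both lower and upper")
        if self.lower is not None and not (self.lower <= self.mean <= self.upper):
            raise DrawError(
                f"mean {self.mean} outside interval ({self.lower}, {self.upper})"
            )
        if self.distribution == "lognormal" and self.mean <= 0:
            raise DrawError("lognormal requires a positive mean")

    @classmethod
    def exact(cls, mean: float) -> "UncertainValue":
        return cls(mean=mean, se=0.0)

    def scale_se(self) -> float:
        """The se on the sampling scale (log scale for lognormal)."""
        if self.se is not None:
            return float(self.se)
        if self.lower is None:
            return 0.0
        if self.distribution == "lognormal":
            if self.lower <= 0:
                raise DrawError("lognormal interval must be positive")
            return float((np.log(self.upper) - np.log(self.lower)) / _Z95)
        return float((self.upper - self.lower) / _Z95)


@dataclass(frozen=True)
class Draws:
    """An ordered vector of Monte Carlo draws for one quantity."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise DrawError("draws must be a non-empty 1-d vector")
        if not np.all(np.isfinite(arr)):
            raise DrawError(f"non-finite draw in {self.label!r}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def __add__(self, other):
        return combine(self, other, np.add)

    def __sub__(self, other):
        return combine(self, other, np.subtract)

    def __mul__(self, other):
        return combine(self, other, np.multiply)

    def __truediv__(self, other):
        return combine(self, other, np.divide)

    __radd__ = __add__
    __rmul__ = __mul__


@dataclass(frozen=True)
class Summary:
    """Mean and 95% uncertainty interval of a draw vector."""

    mean: float
    lower: float
    upper: float

    def round(self, ndigits: int = 0) -> "Summary":
        return Summary(*(round(x, ndigits) for x in (self.mean, self.lower, self.upper)))


def substream(master_seed: int, label: str) -> np.random.Generator:
    """A reproducible per-parameter random stream derived from a master seed.

    The label is hashed with crc32 (stable across processes and Python
    versions, unlike the builtin ``hash``).
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    )


def make_draws(
    value: UncertainValue,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | np.random.Generator = 0,
    kind: Literal["free", "proportion", "count"] = "free",
    anchor: Literal["mean", "median"] = "mean",
    label: str = "",
) -> Draws:
    """Expand one uncertain scalar into a vector of draws.

    ``kind`` sets the support: proportions are truncated to [0, 1] and counts
    to [0, inf) by resampling out-of-support draws.
    """
    if n_draws < 1:
        raise DrawError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, label or "draws")
    s = value.scale_se()
    if s == 0.0:
        return Draws(np.full(n_draws, float(value.mean)), label=label)

    if value.distribution == "lognormal":
        mu = np.log(value.mean) - (s**2 / 2 if anchor == "mean" else 0.0)
        sample: Callable[[int], np.ndarray] = lambda n: np.exp(rng.normal(mu, s, n))
    else:
        sample = lambda n: rng.normal(value.mean, s, n)

    lo, hi = {"free": (-np.inf, np.inf), "proportion": (0.0, 1.0), "count": (0.0, np.inf)}[kind]
    out = sample(n_draws)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = sample(int(bad.sum()))
    else:  # pragma: no cover - pathological spread
        out = np.clip(out, lo, hi)
    return Draws(out, label=label)


def combine(a: Draws, b, op) -> Draws:
    """Element-wise arithmetic on aligned draw vectors (or a scalar)."""
    if isinstance(b, Draws):
        if len(a) != len(b):
            raise DrawError(f"length mismatch: {len(a)} vs {len(b)}")
        bv = b.values
    else:
        bv = np.asarray(b, dtype=float)
        if bv.ndim not in (0, 1) or (bv.ndim == 1 and bv.size != len(a)):
            raise DrawError("operand must be a scalar or an aligned vector")
    if op in (np.divide, np.true_divide) and np.any(bv == 0):
        raise DrawError("division by a draw vector containing zero")
    return Draws(op(a.values, bv), label=a.label)


def summarize(v, lower_pct: float = 2.5, upper_pct: float = 97.5) -> Summary:
    """Mean and empirical percentile interval of a draw vector."""
    arr = v.values if isinstance(v, Draws) else np.asarray(v, dtype=float)
    if arr.size == 0:
        raise DrawError("cannot summarize an empty vector")
    lo, hi = np.percentile(arr, [lower_pct, upper_pct], method="linear")
    return Summary(mean=float(arr.mean()), lower=float(lo), upper=float(hi))
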