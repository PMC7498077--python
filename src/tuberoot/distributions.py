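"""Sampleable parameter distributions.

Every scalar characterization parameter of the tuber-root model (an angle, a
radius, a length, a count) is described by a :class:`DistributionSpec` — either
a normal law fitted from field measurements, or a piecewise-uniform empirical
law given as interval/probability pairs for parameters whose measurements do
not look normal.  Sampling an empirical spec follows the inverse-CDF interval
walk: draw ``u`` uniform on [0, 1], pick the interval ``i`` with
``u in (cum[i-1], cum[i]]`` (``cum[0] = 0``), then draw uniformly inside
``[a_i, b_i]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "ValidationError",
    "sample_parameter",
    "interval_for_u",
    "fit_distribution",
]

#: intervals are closed [a, b]; printed field bins like [70,85],[86,100] keep
#: their 1-degree gaps verbatim, they are never auto-bridged.
_PROB_TOL = 1e-6


class ValidationError(ValueError):
    """A DistributionSpec or database document violates its invariants."""


@dataclass(frozen=True)
class DistributionSpec:
    """One parameter's sampling law.

    Parameters
    ----------
    kind : {"normal", "empirical"}
    mu, sigma : float
        Mean and standard deviation, normal kind only.  ``sigma >= 0``.
    intervals : list of (a, b)
        Closed, sorted, non-overlapping intervals, empirical kind only.
    probs : list of float
        Interval probabilities, summing to 1 within 1e-6.
    """

    kind: str
    mu: float | None = None
    sigma: float | None = None
    intervals: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    probs: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "normal":
            if self.mu is None or self.sigma is None:
                raise ValidationError("normal spec requires mu and sigma")
            if not (math.isfinite(self.mu) and math.isfinite(self.sigma)):
                raise ValidationError("normal spec requires finite mu, sigma")
            if self.sigma < 0:
                raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        elif self.kind == "empirical":
            ivs = tuple((float(a), float(b)) for a, b in self.intervals)
            probs = tuple(float(p) for p in self.probs)
            object.__setattr__(self, "intervals", ivs)
            object.__setattr__(self, "probs", probs)
            if len(ivs) == 0:
                raise ValidationError("empirical spec requires >= 1 interval")
            if len(ivs) != len(probs):
                raise ValidationError(
                    f"{len(ivs)} intervals but {len(probs)} probs"
                )
            for a, b in ivs:
                if not (math.isfinite(a) and math.isfinite(b)):
                    raise ValidationError("interval bounds must be finite")
                if a > b:
                    raise ValidationError(f"interval [{a}, {b}] has a > b")
            for (a0, b0), (a1, _) in zip(ivs, ivs[1:]):
                if a1 < a0:
                    raise ValidationError("intervals must be sorted by a_i")
                if a1 < b0:
                    raise ValidationError(
                        f"intervals [{a0},{b0}] and starting at {a1} overlap"
                    )
            if any(p < 0 for p in probs):
                raise ValidationError("probs must be >= 0")
            if abs(sum(probs) - 1.0) > _PROB_TOL:
                raise ValidationError(
                    f"probs sum to {sum(probs):.8f}, expected 1 +/- {_PROB_TOL}"
                )
        else:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")

    # -- summary statistics -------------------------------------------------

    def mean(self) -> float:
        """Expected value implied by the spec."""
        if self.kind == "normal":
            return float(self.mu)
        mids = [(a + b) / 2 for a, b in self.intervals]
        return float(sum(p * m for p, m in zip(self.probs, mids)))

    def cdf(self, x: float) -> float:
        """P(X <= x) under the spec (piecewise-linear for empirical)."""
        if self.kind == "normal":
            if self.sigma == 0:
                return float(x >= self.mu)
            return float(stats.norm.cdf(x, self.mu, self.sigma))
        total = 0.0
        for (a, b), p in zip(self.intervals, self.probs):
            if x >= b:
                total += p
            elif x > a:
                total += p * (x - a) / (b - a)
        return total

    def interval_prob(self, lo: float, hi: float) -> float:
        """Probability mass the spec places on [lo, hi]."""
        return self.cdf(hi) - self.cdf(lo)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        if self.kind == "normal":
            return {"kind": "normal", "mu": self.mu, "sigma": self.sigma}
        return {
            "kind": "empirical",
            "intervals": [list(iv) for iv in self.intervals],
            "probs": list(self.probs),
        }

    @classmethod
    def from_dict(cls, d: dict, path: str = "") -> "DistributionSpec":
        try:
            kind = d["kind"]
        except (KeyError, TypeError):
            raise ValidationError(f"{path}: missing 'kind'") from None
        try:
            if kind == "normal":
                return cls(kind="normal", mu=float(d["mu"]),
                           sigma=float(d["sigma"]))
            if kind == "empirical":
                return cls(
                    kind="empirical",
                    intervals=tuple(tuple(iv) for iv in d["intervals"]),
                    probs=tuple(d["probs"]),
                )
        except KeyError as e:
            raise ValidationError(f"{path}: missing field {e}") from None
        except ValidationError as e:
            raise ValidationError(f"{path}: {e}") from None
        raise ValidationError(f"{path}: unknown kind {kind!r}")


def interval_for_u(spec: DistributionSpec, u: float) -> int:
    """Index of the empirical interval selected by the uniform draw ``u``.

    Selection is by cumulative sums: interval ``i`` is chosen when
    ``u in (cum[i-1], cum[i]]`` with ``cum[0] = 0``; ``u = 0`` maps to the
    first interval with positive probability.
    """
    if spec.kind != "empirical":
        raise ValidationError("interval selection applies to empirical specs")
    cum = 0.0
    last_positive = 0
    for i, p in enumerate(spec.probs):
        if p > 0:
            last_positive = i
        cum += p
        if u <= cum and p > 0:
            return i
    return last_positive  # u == 1 up to float round-off


def sample_parameter(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw from a spec: NORMRND-style for normal, interval walk for empirical.

    Returns a float when ``size`` is None, else an ndarray of that length.
    """
    n = 1 if size is None else int(size)
    if spec.kind == "normal":
        out = rng.normal(spec.mu, spec.sigma, size=n)
    else:
        us = rng.uniform(0.0, 1.0, size=n)
        ivs = np.asarray(spec.intervals, dtype=float)
        idx = np.array([interval_for_u(spec, u) for u in us])
        a, b = ivs[idx, 0], ivs[idx, 1]
        out = rng.uniform(0.0, 1.0, size=n) * (b - a) + a
    return float(out[0]) if size is None else out


def sample_nonnegative(
    spec: DistributionSpec, rng: np.random.Generator, max_attempts: int = 100
) -> float:
    """Draw a physically nonnegative value: reject negatives, then clamp.

    Up to ``max_attempts`` rejection redraws; after that the draw is clamped
    to 0 so heavily negative specs still terminate.
    """
    for _ in range(max_attempts):
        x = sample_parameter(spec, rng)
        if x >= 0:
            return x
    return 0.0


def fit_distribution(samples, alpha: float = 0.05,
                     discrete: bool = False) -> DistributionSpec:
    """Fit a spec to measured values: normal if Shapiro-Wilk does not reject.

    With normality rejected at level ``alpha`` the values are binned into
    ``k = ceil(1 + log2 n)`` equal-width intervals (Sturges) over
    [min, max]; empty bins are merged into their neighbour so every stored
    interval carries mass.  Constant samples degenerate to a single
    zero-width interval.

    ``discrete=True`` is for integer-valued quantities (organ counts): the
    fit is the exact frequency table, stored as zero-width intervals, whose
    implied mean is the sample mean of the counts.

    Raises
    ------
    ValidationError
        For fewer than 8 finite samples — supply an explicit spec instead.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValidationError(
            f"fit_distribution needs >= 8 samples (got {x.size}); "
            "supply an explicit DistributionSpec for small data"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")

    lo, hi = float(x.min()), float(x.max())
    if hi == lo:  # zero variance: degenerate one-interval empirical law
        return DistributionSpec(
            kind="empirical", intervals=((lo, lo),), probs=(1.0,)
        )

    _, p_value = stats.shapiro(x)
    if p_value > alpha:
        return DistributionSpec(
            kind="normal", mu=float(x.mean()), sigma=float(x.std(ddof=1))
        )

    if discrete:
        values, counts = np.unique(np.round(x), return_counts=True)
        probs = counts / counts.sum()
        return DistributionSpec(
            kind="empirical",
            intervals=tuple((float(v), float(v)) for v in values),
            probs=tuple(float(p) for p in probs),
        )

    k = math.ceil(1 + math.log2(x.size))
    counts, edges = np.histogram(x, bins=k, range=(lo, hi))
    intervals = [(edges[i], edges[i + 1]) for i in range(k)]
    counts = counts.astype(float)
    # merge empty bins into the previous non-empty one (the first into the next)
    merged_iv: list[tuple[float, float]] = []
    merged_c: list[float] = []
    for iv, c in zip(intervals, counts):
        if merged_iv and (c == 0 or merged_c[-1] == 0):
            merged_iv[-1] = (merged_iv[-1][0], iv[1])
            merged_c[-1] += c
        else:
            merged_iv.append(iv)
            merged_c.append(c)
    probs = np.asarray(merged_c) / np.sum(merged_c)
    probs = probs / probs.sum()
    return DistributionSpec(
        kind="empirical",
        intervals=tuple(merged_iv),
        probs=tuple(float(p) for p in probs),
    )
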