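"""Rank-order estimation of the one-dimensional Wasserstein distance.

The k-th Wasserstein distance between distributions F and G is

    W_k(F, G) = ( ∫₀¹ |F⁻¹(u) − G⁻¹(u)|ᵏ du )^{1/k},

the optimal-transport cost with ground distance |x − y|ᵏ.  For empirical
samples the quantile functions are step functions of the order statistics, so
the integral is a finite sum over ranks — no optimization is ever solved.
For equal sample sizes N and k = 1 this reduces to the mean absolute
difference of sorted samples.  Because only ranks enter, the estimate is
robust to outliers: one corrupted point of N can move W₁ by at most
|outlier|/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmpiricalQuantile",
    "DistanceSpec",
    "ecdf",
    "inverse_ecdf",
    "w_distance",
    "windowed_w_distance",
]


def _as_sample(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("sample must be nonempty")
    return a


@dataclass(frozen=True)
class EmpiricalQuantile:
    """A sorted sample acting as the estimated inverse CDF F⁻¹."""

    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        v = _as_sample(self.sorted_values)
        if np.any(np.diff(v) < 0):
            raise ValueError("values must be nondecreasing")
        object.__setattr__(self, "sorted_values", v)

    @classmethod
    def from_sample(cls, sample) -> "EmpiricalQuantile":
        return cls(np.sort(_as_sample(sample)))

    @property
    def n(self) -> int:
        return self.sorted_values.size

    def __call__(self, u) -> np.ndarray | float:
        """Generalized inverse CDF: the ⌈uN⌉-th order statistic."""
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0) or np.any(u > 1):
            raise ValueError("quantile level must be in (0, 1]")
        idx = np.ceil(u * self.n).astype(int) - 1
        out = self.sorted_values[idx]
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DistanceSpec:
    """Distance order ``k`` (1 = earth mover's distance) and optional
    sliding-window parameters for nonstationary sequences."""

    k: int = 1
    window_len: int | None = None
    window_step: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be ≥ 1")
        if (self.window_len is None) != (self.window_step is None):
            raise ValueError("window_len and window_step must be given together")
        if self.window_len is not None:
            if not self.window_len > self.window_step > 0:
                raise ValueError("require window_len > window_step > 0")


def ecdf(sample, x) -> np.ndarray | float:
    """Empirical CDF: (1/N) Σᵢ I(Xᵢ ≤ x); right-continuous step function."""
    a = np.sort(_as_sample(sample))
    out = np.searchsorted(a, np.asarray(x, dtype=float), side="right") / a.size
    return float(out) if out.ndim == 0 else out


def inverse_ecdf(sample, u) -> np.ndarray | float:
    """Generalized inverse of the empirical CDF at level u ∈ (0, 1]:
    the smallest sample value v with ecdf(v) ≥ u, i.e. the ⌈uN⌉-th order
    statistic."""
    return EmpiricalQuantile.from_sample(sample)(u)


def w_distance(a, b, spec: DistanceSpec = DistanceSpec()) -> float:
    """k-th Wasserstein distance between two empirical samples.

    Equal sizes, k = 1: exactly ``mean(|sort(a) − sort(b)|)``.  In general the
    quantile functions are piecewise constant on a common grid of levels
    {i/Nₐ} ∪ {j/N_b}, and the integral ∫|F⁻¹ − G⁻¹|ᵏ du is the width-weighted
    sum over grid cells, followed by the 1/k-th root.
    """
    av = np.sort(_as_sample(a))
    bv = np.sort(_as_sample(b))
    k = spec.k
    if av.size == bv.size:
        diffs = np.abs(av - bv)
        cost = float(np.mean(diffs ** k))
    else:
        na, nb = av.size, bv.size
        levels = np.union1d(np.arange(1, na) / na, np.arange(1, nb) / nb)
        edges = np.concatenate([[0.0], levels, [1.0]])
        widths = np.diff(edges)
        mids = (edges[:-1] + edges[1:]) / 2
        qa = av[np.minimum((mids * na).astype(int), na - 1)]
        qb = bv[np.minimum((mids * nb).astype(int), nb - 1)]
        cost = float(np.sum(widths * np.abs(qa - qb) ** k))
    return cost ** (1.0 / k)


def windowed_w_distance(a, b, spec: DistanceSpec) -> np.ndarray:
    """Wasserstein distance in aligned sliding windows.

    Windows of ``spec.window_len`` samples advance by ``spec.window_step``;
    the final partial window is dropped.  Returns one distance per window.
    """
    av = _as_sample(a)
    bv = _as_sample(b)
    if spec.window_len is None:
        raise ValueError("spec must define window_len and window_step")
    if av.size != bv.size:
        raise ValueError("sequences must have equal length for aligned windows")
    if spec.window_len > av.size:
        raise ValueError("window longer than the data")
    flat = DistanceSpec(k=spec.k)
    starts = range(0, av.size - spec.window_len + 1, spec.window_step)
    return np.array([
        w_distance(av[s:s + spec.window_len], bv[s:s + spec.window_len], flat)
        for s in starts
    ])
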