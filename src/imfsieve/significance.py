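"""Monte-Carlo significance calls for information-bearing IMFs.

After a joint NA-MEMD run, the m noise-reference channels yield m IMFs at
every scale.  The W₁ distances between all m(m−1)/2 unordered pairs of noise
IMFs form a per-scale null distribution of "how far apart two
information-free IMFs of this scale lie"; its empirical 0.025/0.975 quantiles
define a 95% confidence interval.  A data IMF is called information-bearing
(p < 0.05) when its mean distance to the m noise IMFs falls outside that
interval.  The test is two-sided as stated, although information almost
always inflates the distance; a one-sided variant is available.

Every IMF is standardized by its own temporal mean and SD before distances
are taken, so the comparison is between the *shapes* of the amplitude
distributions, independent of the energy an IMF happens to carry.  This is
what makes the reference usable at all — a 6%-variance noise IMF and a
unit-amplitude sinusoid IMF are compared on equal footing (a unit-SD
sinusoid's arcsine-distributed samples sit at W₁ ≈ 0.25 from a standard
normal, the regime the designed components land in) — and it renders the
calls invariant to rescaling any series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .memd import IMFDecomposition, ROLE_DATA
from .wasserstein import DistanceSpec, w_distance, windowed_w_distance

__all__ = ["NullModel", "SignificanceReport", "build_null",
           "data_noise_distance", "identify", "flag_pattern_scale"]


@dataclass
class NullModel:
    """Per-scale noise-pair distances and their CI bounds."""

    pair_distances: np.ndarray  # (n_scales, n_pairs)
    ci_low: np.ndarray  # (n_scales,)
    ci_high: np.ndarray  # (n_scales,)
    m: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if np.any(self.ci_low > self.ci_high):
            raise ValueError("ci_low must not exceed ci_high")
        if self.pair_distances.shape[1] != self.m * (self.m - 1) // 2:
            raise ValueError("expected m(m−1)/2 pair distances per scale")


@dataclass
class SignificanceReport:
    """Per (scale, data series) distance, CI, and information-bearing call."""

    distances: np.ndarray  # (n_scales, n_data)
    ci_low: np.ndarray  # (n_scales,)
    ci_high: np.ndarray  # (n_scales,)
    significant: np.ndarray  # bool (n_scales, n_data)
    data_labels: list[str]
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    @property
    def n_scales(self) -> int:
        return self.distances.shape[0]

    def flagged(self) -> list[tuple[int, str]]:
        """(scale index, series label) pairs called information-bearing;
        scales are 0-based here, 1-based in written reports."""
        s, c = np.nonzero(self.significant)
        return [(int(i), self.data_labels[int(j)]) for i, j in zip(s, c)]


def _standardized_imfs(dec: IMFDecomposition, edge_guard: float = 0.02) -> np.ndarray:
    """Each IMF centered and divided by its own temporal SD (shape only).

    ``edge_guard`` trims that fraction of samples from each end first: the
    envelope splines are least constrained at the record boundaries and the
    resulting transients would otherwise dominate the distance at fast
    scales.  An exactly constant IMF is left as zeros — maximally unlike any
    oscillatory reference — rather than dividing by zero.
    """
    if not 0 <= edge_guard < 0.5:
        raise ValueError("edge_guard must be in [0, 0.5)")
    g = int(round(dec.n_time * edge_guard))
    imfs = dec.imfs[:, g:dec.n_time - g, :] if g else dec.imfs
    z = imfs - imfs.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    return np.divide(z, sd, out=np.zeros_like(z), where=sd > 0)


def build_null(dec: IMFDecomposition, alpha: float = 0.05,
               edge_guard: float = 0.02) -> NullModel:
    """Null distribution of W₁ between same-scale noise-reference IMFs.

    For each scale, the distance between every unordered pair of the m noise
    IMFs is computed (whole-segment; windowing is handled by
    :func:`identify`); the empirical ``alpha/2`` and ``1 − alpha/2`` quantiles
    give the CI.
    """
    idx = dec.noise_indices
    if len(idx) < 2:
        raise ValueError("need ≥ 2 noise channels for a null")
    noise = _standardized_imfs(dec, edge_guard)[:, :, idx]
    m = noise.shape[2]
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    spec = DistanceSpec(k=1)
    dists = np.empty((dec.n_scales, len(pairs)))
    for s in range(dec.n_scales):
        for p, (i, j) in enumerate(pairs):
            dists[s, p] = w_distance(noise[s, :, i], noise[s, :, j], spec)
    lo, hi = np.quantile(dists, [alpha / 2, 1 - alpha / 2], axis=1)
    return NullModel(dists, lo, hi, m=m, alpha=alpha)


def data_noise_distance(dec: IMFDecomposition, scale: int, series: int,
                        edge_guard: float = 0.02) -> float:
    """Mean W₁ between a data series' IMF at ``scale`` and each of the m
    noise-reference IMFs at the same scale (standardized shapes)."""
    if not 0 <= scale < dec.n_scales:
        raise IndexError(f"scale {scale} out of range [0, {dec.n_scales})")
    if dec.roles[series] != ROLE_DATA:
        raise ValueError(f"series {series} is not a data series")
    imfs = _standardized_imfs(dec, edge_guard)
    noise_idx = dec.noise_indices
    if not noise_idx:
        raise ValueError("decomposition has no noise-reference channels")
    spec = DistanceSpec(k=1)
    return float(np.mean([
        w_distance(imfs[scale, :, series], imfs[scale, :, j], spec)
        for j in noise_idx
    ]))


def identify(dec: IMFDecomposition, window: DistanceSpec | None = None,
             alpha: float = 0.05, one_sided: bool = False,
             edge_guard: float = 0.02) -> SignificanceReport:
    """Information-bearing calls for every (scale, data series).

    Whole-segment mode (default; appropriate for stationary signals): one
    mean data–noise distance per cell, flagged when outside the per-scale
    noise-pair CI.  Windowed mode: distances and window-matched nulls are
    computed per sliding window, the CI levels Bonferroni-adjusted across
    windows, and a cell is flagged if any window's distance leaves its CI —
    this detects ephemeral signals nonstationary over the segment.

    ``one_sided=True`` flags only distances above the upper bound (at level
    ``1 − alpha``), since information inflates the distance.
    """
    data_idx = dec.data_indices
    noise_idx = dec.noise_indices
    if len(noise_idx) < 2:
        raise ValueError("need ≥ 2 noise channels for a null")
    imfs = _standardized_imfs(dec, edge_guard)
    meta = {"m": len(noise_idx), "alpha": alpha, "one_sided": one_sided,
            "windowed": window is not None, "edge_guard": edge_guard}

    if window is None:
        null = build_null(dec, alpha=alpha, edge_guard=edge_guard)
        flat = DistanceSpec(k=1)
        distances = np.empty((dec.n_scales, len(data_idx)))
        for s in range(dec.n_scales):
            for c, i in enumerate(data_idx):
                distances[s, c] = np.mean([
                    w_distance(imfs[s, :, i], imfs[s, :, j], flat)
                    for j in noise_idx
                ])
        lo, hi = null.ci_low, null.ci_high
        if one_sided:
            lo = np.full_like(hi, -np.inf)
            hi = np.quantile(null.pair_distances, 1 - alpha, axis=1)
        significant = (distances < lo[:, None]) | (distances > hi[:, None])
        return SignificanceReport(distances, lo, hi, significant,
                                  [dec.labels[i] for i in data_idx],
                                  alpha=alpha, meta=meta)

    # windowed mode
    pairs = [(i, j) for i in noise_idx for j in noise_idx if i < j]
    n_kept = imfs.shape[1]
    n_win = (n_kept - window.window_len) // window.window_step + 1
    if n_win < 1:
        raise ValueError("window longer than the data")
    level = alpha / n_win  # Bonferroni across windows
    q_lo, q_hi = ((0.0, 1 - level) if one_sided else (level / 2, 1 - level / 2))
    distances = np.empty((dec.n_scales, len(data_idx)))
    significant = np.zeros((dec.n_scales, len(data_idx)), dtype=bool)
    lo_out = np.empty(dec.n_scales)
    hi_out = np.empty(dec.n_scales)
    for s in range(dec.n_scales):
        null_w = np.stack([
            windowed_w_distance(imfs[s, :, i], imfs[s, :, j], window)
            for (i, j) in pairs
        ])  # (n_pairs, n_win)
        lo = np.quantile(null_w, q_lo, axis=0) if not one_sided else np.full(n_win, -np.inf)
        hi = np.quantile(null_w, q_hi, axis=0)
        lo_out[s], hi_out[s] = np.median(lo), np.median(hi)
        for c, i in enumerate(data_idx):
            dw = np.mean([
                windowed_w_distance(imfs[s, :, i], imfs[s, :, j], window)
                for j in noise_idx
            ], axis=0)  # (n_win,)
            distances[s, c] = dw.mean()
            significant[s, c] = bool(np.any((dw < lo) | (dw > hi)))
    return SignificanceReport(distances, lo_out, hi_out, significant,
                              [dec.labels[i] for i in data_idx],
                              alpha=alpha, meta=meta)


def flag_pattern_scale(report: SignificanceReport, present: list[str],
                       absent: list[str] = ()) -> int:
    """Scale whose flag pattern matches "significant in ``present``, not in
    ``absent``".

    If several scales match exactly, the one with the largest mean distance
    in the ``present`` channels wins (the strongest component).  If none
    matches exactly, the closest pattern (fewest disagreeing channels, same
    tie-break) is returned — callers comparing against a designed layout get
    the best available candidate rather than an error.
    """
    pi = [report.data_labels.index(ch) for ch in present]
    ai = [report.data_labels.index(ch) for ch in absent]
    best, best_key = 0, (len(pi) + len(ai) + 1, -np.inf)
    for s in range(report.n_scales):
        mismatches = int(np.sum(~report.significant[s, pi]))
        mismatches += int(np.sum(report.significant[s, ai]))
        strength = float(report.distances[s, pi].mean())
        key = (mismatches, -strength)
        if key < best_key:
            best, best_key = s, key
    return best
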