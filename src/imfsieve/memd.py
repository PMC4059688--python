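"""Multivariate empirical mode decomposition (MEMD).

EMD decomposes a time series into intrinsic mode functions (IMFs) — locally
symmetric oscillatory components ordered from fast to slow — by iteratively
subtracting the mean of the upper/lower extrema envelopes ("sifting").  For a
multichannel signal local extrema are not well defined, so MEMD projects the
n-channel signal onto K quasi-uniform directions of the unit (n−1)-sphere,
interpolates the multivariate samples at each projection's maxima, and uses
the average of these directional envelopes as the local mean.  All channels
are sifted jointly, which yields the same number of IMFs per channel with
matched frequency scales ("scale alignment").

The implementation follows the standard MEMD recipe: Hammersley direction
sampling, natural cubic spline envelopes with mirrored boundary extrema, and
a Rilling-style envelope-amplitude stoppage criterion without the univariate
extrema/zero-crossing equality (which has no multivariate analogue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from ._envelopes import envelope_accumulate

__all__ = [
    "MultichannelSeries",
    "DirectionSet",
    "SiftConfig",
    "IMFDecomposition",
    "ResidueReached",
    "hammersley_directions",
    "project",
    "envelope_mean",
    "sift",
    "memd",
]

_MIN_SAMPLES = 8

ROLE_DATA = "data"
ROLE_NOISE = "noise_ref"


class ResidueReached(Exception):
    """Raised when a signal no longer has enough projection maxima to sift."""


@dataclass
class MultichannelSeries:
    """A time × series real-valued signal with per-series role tags.

    ``roles`` distinguishes observed data channels from appended white-noise
    reference channels (``"data"`` / ``"noise_ref"``).
    """

    values: np.ndarray
    sample_rate_hz: float
    roles: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a time × series matrix")
        n_time, n_series = self.values.shape
        if n_series < 1:
            raise ValueError("at least one series required")
        if n_time < _MIN_SAMPLES:
            raise ValueError(f"at least {_MIN_SAMPLES} time points required, got {n_time}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.roles:
            self.roles = [ROLE_DATA] * n_series
        if len(self.roles) != n_series:
            raise ValueError("roles length must equal number of series")
        bad = set(self.roles) - {ROLE_DATA, ROLE_NOISE}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not self.labels:
            self.labels = [f"s{i}" for i in range(n_series)]
        if len(self.labels) != n_series:
            raise ValueError("labels length must equal number of series")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[1]

    @property
    def data_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == ROLE_DATA]

    @property
    def noise_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == ROLE_NOISE]


@dataclass(frozen=True)
class DirectionSet:
    """K unit vectors sampling the (n−1)-sphere."""

    vectors: np.ndarray  # (K, n)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("vectors must be a K × n matrix with K ≥ 1")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("direction vectors must have unit norm")
        object.__setattr__(self, "vectors", v)

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def n(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class SiftConfig:
    """Sifting controls.

    ``stop_thresholds = (sd, sd2, tol)``: stop when |m(t)| / a(t) — local mean
    over mean directional-envelope amplitude — is below ``sd`` on at least
    ``1 − tol`` of samples and below ``sd2`` everywhere.  These are the
    de-facto MEMD defaults.  ``boundary_mirror_extrema`` extrema are mirrored
    past each edge before spline interpolation to suppress end effects.
    """

    stop_thresholds: tuple[float, float, float] = (0.075, 0.75, 0.075)
    max_sift_iters: int = 15
    max_imfs: int | None = None
    boundary_mirror_extrema: int = 2

    def __post_init__(self) -> None:
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be ≥ 1")
        if any(t <= 0 for t in self.stop_thresholds):
            raise ValueError("stop thresholds must be positive")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be ≥ 1 or None")
        if self.boundary_mirror_extrema < 1:
            raise ValueError("boundary_mirror_extrema must be ≥ 1")


@dataclass
class IMFDecomposition:
    """Joint decomposition: imfs[scale, time, series] plus a residue.

    Per series, ``imfs.sum(axis=0) + residue`` reconstructs the input up to
    float rounding.  ``norm_sds`` records the per-series temporal SDs divided
    out before decomposition (1.0 where no normalization was applied) so the
    normalized-scale decomposition remains recoverable.
    """

    imfs: np.ndarray  # (n_scales, n_time, n_series)
    residue: np.ndarray  # (n_time, n_series)
    sample_rate_hz: float
    roles: list[str]
    labels: list[str]
    norm_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.imfs = np.asarray(self.imfs, dtype=float)
        self.residue = np.asarray(self.residue, dtype=float)
        if self.imfs.ndim != 3:
            raise ValueError("imfs must be scale × time × series")
        if self.residue.shape != self.imfs.shape[1:]:
            raise ValueError("residue shape must match imfs time × series")
        if self.norm_sds is None:
            self.norm_sds = np.ones(self.imfs.shape[2])
        self.norm_sds = np.asarray(self.norm_sds, dtype=float)
        if self.norm_sds.shape != (self.imfs.shape[2],):
            raise ValueError("norm_sds must have one entry per series")

    @property
    def n_scales(self) -> int:
        return self.imfs.shape[0]

    @property
    def n_time(self) -> int:
        return self.imfs.shape[1]

    @property
    def n_series(self) -> int:
        return self.imfs.shape[2]

    @property
    def data_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == ROLE_DATA]

    @property
    def noise_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == ROLE_NOISE]

    def normalized_imfs(self) -> np.ndarray:
        """IMFs with each series divided by its stored temporal SD."""
        return self.imfs / self.norm_sds[None, None, :]

    def reconstruction(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residue


# --- direction sampling -----------------------------------------------------

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61,
           67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113)


def _radical_inverse(base: int, indices: np.ndarray) -> np.ndarray:
    """Van der Corput radical inverse of each index in the given base."""
    k = indices.astype(np.int64).copy()
    out = np.zeros(len(k))
    f = 1.0 / base
    while np.any(k > 0):
        out += f * (k % base)
        k //= base
        f /= base
    return out


def hammersley_directions(n: int, K: int) -> DirectionSet:
    """K quasi-uniform unit vectors on the (n−1)-sphere from a Hammersley set.

    ⌈K/2⌉ base points of the Hammersley set in the unit n-cube (index/K plus
    radical inverses in the first primes) are pushed through the inverse
    normal CDF — low-discrepancy draws from an isotropic Gaussian — and
    normalized to unit length; the set is completed antithetically with the
    negations of the base directions.  The ±pairing is the multivariate
    analogue of interpolating both maxima and minima envelopes in univariate
    EMD: projection maxima along −d are the minima along d, so a sign-
    balanced set samples tops and bottoms of every oscillation evenly and a
    symmetric signal gets an exactly zero envelope mean.  Deterministic for
    a given (n, K).
    """
    if n < 2:
        raise ValueError("multivariate input required (n ≥ 2)")
    if K < 1:
        raise ValueError("K must be ≥ 1")
    if n > len(_PRIMES) + 1:
        raise ValueError(f"dimension {n} exceeds supported maximum {len(_PRIMES) + 1}")
    half = (K + 1) // 2
    idx = np.arange(1, half + 1)
    u = np.empty((half, n))
    u[:, 0] = (idx - 0.5) / half
    for j in range(1, n):
        u[:, j] = _radical_inverse(_PRIMES[j - 1], idx)
    # radical inverses of indices ≥ 1 lie strictly inside (0, 1)
    z = ndtri(u)
    base = z / np.linalg.norm(z, axis=1, keepdims=True)
    return DirectionSet(np.vstack([base, -base[:K - half]]))


def project(signal: MultichannelSeries | np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Inner product of each time sample with a direction vector."""
    values = signal.values if isinstance(signal, MultichannelSeries) else np.asarray(signal)
    direction = np.asarray(direction, dtype=float)
    if values.shape[1] != direction.shape[0]:
        raise ValueError(
            f"direction dimension {direction.shape[0]} does not match "
            f"{values.shape[1]} series"
        )
    return values @ direction


# --- envelopes and sifting --------------------------------------------------

def envelope_mean(signal: MultichannelSeries | np.ndarray, directions: DirectionSet,
                  mirror: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean m(t) of directional envelopes, and the mean envelope amplitude.

    For each direction θ_k the signal is projected, the projection's maxima
    located, and the multivariate samples at those time points interpolated;
    m(t) averages the K envelope curves.  Directions whose projection has
    fewer than 3 maxima are skipped; once every direction is exhausted the
    signal is declared a residue (keeping the decomposition going while any
    projection still oscillates is what lets the slow end of the cascade
    unfold fully).

    Returns ``(m, amp)`` where ``amp[t]`` is the mean over live directions of
    the envelope's Euclidean norm — the amplitude reference of the stoppage
    criterion.
    """
    values = signal.values if isinstance(signal, MultichannelSeries) else np.asarray(signal)
    values = np.ascontiguousarray(values, dtype=float)
    if directions.n != values.shape[1]:
        raise ValueError("direction dimension does not match number of series")
    env_sum, amp_sum, n_live = envelope_accumulate(
        values, np.ascontiguousarray(directions.vectors), mirror)
    if n_live == 0:
        raise ResidueReached(
            f"no projection of {directions.K} has ≥ 3 maxima"
        )
    return env_sum / n_live, amp_sum / n_live


def sift(signal: MultichannelSeries, directions: DirectionSet,
         cfg: SiftConfig = SiftConfig()) -> tuple[np.ndarray, MultichannelSeries]:
    """Extract one multivariate IMF from ``signal`` by iterative sifting.

    The candidate detail starts as the signal itself; each iteration subtracts
    the directional-envelope mean until the envelope-symmetry criterion is met
    or ``max_sift_iters`` is reached.  Returns ``(imf, residue_signal)`` with
    ``imf + residue_signal.values == signal.values`` exactly.

    Raises :class:`ResidueReached` if the signal cannot be sifted at all.
    """
    sd, sd2, tol = cfg.stop_thresholds
    detail = signal.values.copy()
    for it in range(cfg.max_sift_iters):
        try:
            mean_env, amp = envelope_mean(detail, directions, cfg.boundary_mirror_extrema)
        except ResidueReached:
            if it == 0:
                raise
            break
        sx = np.linalg.norm(mean_env, axis=1) / np.maximum(amp, 1e-30)
        if np.mean(sx > sd) < tol and np.all(sx < sd2):
            break
        detail = detail - mean_env
    residue = MultichannelSeries(
        signal.values - detail, signal.sample_rate_hz,
        roles=list(signal.roles), labels=list(signal.labels),
    )
    return detail, residue


def memd(signal: MultichannelSeries, K: int = 64,
         cfg: SiftConfig = SiftConfig()) -> IMFDecomposition:
    """Full multivariate EMD of an n-channel signal.

    Repeatedly sifts IMFs out of successive residues until the residue no
    longer has enough projection maxima (a multivariate proxy for
    monotonicity) or ``cfg.max_imfs`` scales have been extracted.  With
    ``max_imfs=None`` the depth is capped at ⌈log₂ N⌉ + 2: broadband content
    supports about log₂ N dyadic scales in an N-sample record, plus a couple
    of trend-like scales; anything beyond is residue wiggle with too few
    extrema to carry a meaningful amplitude distribution.  The decomposition
    is joint: every series receives the same number of scale-aligned IMFs,
    and ``Σ_j c_j(t) + r(t) = x(t)`` holds per series to float rounding.
    """
    if signal.n_series < 2:
        raise ValueError("multivariate input required (≥ 2 series)")
    directions = hammersley_directions(signal.n_series, K)
    max_imfs = cfg.max_imfs
    if max_imfs is None:
        max_imfs = int(np.ceil(np.log2(signal.n_time))) + 2
    imfs: list[np.ndarray] = []
    residue = signal
    while len(imfs) < max_imfs:
        try:
            imf, residue = sift(residue, directions, cfg)
        except ResidueReached:
            break
        imfs.append(imf)
    if not imfs:
        raise ResidueReached("input has no oscillatory component to extract")
    return IMFDecomposition(
        imfs=np.stack(imfs), residue=residue.values,
        sample_rate_hz=signal.sample_rate_hz,
        roles=list(signal.roles), labels=list(signal.labels),
    )
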