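"""Noise-assisted MEMD: preprocessing and composite decomposition.

Electrophysiology data typically arrive as Time × Channels × Trials tensors.
MEMD operates on a two-dimensional Time × Series matrix, so trials are
unfolded into extra series (keeping time as rows), which is precisely what
aligns IMF scales across both channels and trials in the joint decomposition.
Each series is normalized by its temporal standard deviation before sifting
(inter-trial amplitude variability otherwise distorts the multivariate
projections) and the SDs are restored on the output IMFs.

White-noise reference channels of a small fraction (default 6%) of the data
variance are appended before decomposition; their IMFs are the reference the
significance machinery compares against.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .memd import (
    ROLE_DATA,
    ROLE_NOISE,
    IMFDecomposition,
    MultichannelSeries,
    SiftConfig,
    memd,
)

__all__ = [
    "TrialTensor",
    "NoiseConfig",
    "reshape_trials",
    "normalize_sd",
    "restore_sd",
    "make_noise_channels",
    "na_memd_decompose",
]


@dataclass
class TrialTensor:
    """Time × Channels × Trials array with a sample rate."""

    values: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be time × channels × trials")
        if self.values.shape[0] < 8:
            raise ValueError("at least 8 time points required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """Reference-noise settings: ``m`` channels at ``variance_fraction`` of
    the (normalized) data variance.  2%–10% is the recommended range; larger
    fractions start to drive the decomposition, smaller ones leave too little
    dyadic structure to reference against."""

    m: int = 15
    variance_fraction: float = 0.06
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("at least one noise reference channel required")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        if not 0.02 <= self.variance_fraction <= 0.10:
            warnings.warn(
                f"variance_fraction {self.variance_fraction} outside the "
                "recommended 2%-10% range", stacklevel=2)


def reshape_trials(t: TrialTensor) -> tuple[MultichannelSeries, list[tuple[int, int]]]:
    """Unfold Time × Channels × Trials into Time × (Channels·Trials).

    Returns the series and the column → (channel, trial) mapping.  Rows stay
    time so the joint decomposition aligns scales across channels *and*
    trials.
    """
    n_time, n_ch, n_tr = t.values.shape
    mapping = [(c, r) for r in range(n_tr) for c in range(n_ch)]
    flat = t.values.transpose(0, 2, 1).reshape(n_time, n_ch * n_tr)
    labels = [f"ch{c}_tr{r}" for c, r in mapping]
    series = MultichannelSeries(flat, t.sample_rate_hz,
                                roles=[ROLE_DATA] * (n_ch * n_tr), labels=labels)
    return series, mapping


def fold_trials(series_values: np.ndarray, mapping: list[tuple[int, int]],
                sample_rate_hz: float) -> TrialTensor:
    """Inverse of :func:`reshape_trials` for a matrix with the same columns."""
    n_time = series_values.shape[0]
    n_ch = max(c for c, _ in mapping) + 1
    n_tr = max(r for _, r in mapping) + 1
    out = np.empty((n_time, n_ch, n_tr))
    for col, (c, r) in enumerate(mapping):
        out[:, c, r] = series_values[:, col]
    return TrialTensor(out, sample_rate_hz)


def normalize_sd(s: MultichannelSeries) -> tuple[MultichannelSeries, np.ndarray]:
    """Divide each series by its temporal SD; return the SDs for restoration."""
    sds = s.values.std(axis=0, ddof=0)
    zero = np.nonzero(sds == 0)[0]
    if len(zero):
        names = ", ".join(s.labels[i] for i in zero)
        raise ValueError(f"zero-variance series cannot be normalized: {names}")
    normalized = MultichannelSeries(
        s.values / sds, s.sample_rate_hz, roles=list(s.roles), labels=list(s.labels))
    return normalized, sds


def restore_sd(d: IMFDecomposition, sds: np.ndarray) -> IMFDecomposition:
    """Multiply data-series IMF/residue columns by their stored SDs.

    ``sds`` has one entry per *data* series (noise-reference columns are left
    untouched); the SDs are recorded on the result so distance computations
    can return to the normalized scale.
    """
    sds = np.asarray(sds, dtype=float)
    data_idx = d.data_indices
    if sds.shape != (len(data_idx),):
        raise ValueError(
            f"expected {len(data_idx)} SDs for the data series, got {sds.shape}")
    full = np.ones(d.n_series)
    full[data_idx] = sds
    return IMFDecomposition(
        imfs=d.imfs * full[None, None, :],
        residue=d.residue * full[None, :],
        sample_rate_hz=d.sample_rate_hz,
        roles=list(d.roles),
        labels=list(d.labels),
        norm_sds=d.norm_sds * full,
    )


def make_noise_channels(n_time: int, cfg: NoiseConfig,
                        reference_variance: float = 1.0) -> MultichannelSeries:
    """``cfg.m`` i.i.d. Gaussian white-noise series, each with variance
    ``cfg.variance_fraction × reference_variance``, tagged ``noise_ref``."""
    if n_time < 8:
        raise ValueError("n_time must be ≥ 8")
    rng = np.random.default_rng(cfg.seed)
    sd = float(np.sqrt(cfg.variance_fraction * reference_variance))
    values = rng.normal(0.0, sd, size=(n_time, cfg.m))
    return MultichannelSeries(
        values, 1.0, roles=[ROLE_NOISE] * cfg.m,
        labels=[f"noise{i + 1}" for i in range(cfg.m)])


def na_memd_decompose(data: MultichannelSeries | TrialTensor,
                      cfg: NoiseConfig = NoiseConfig(),
                      K: int = 64,
                      sift_cfg: SiftConfig = SiftConfig()) -> IMFDecomposition:
    """Full NA-MEMD pipeline.

    Reshape (if given a trial tensor) → SD-normalize → append ``cfg.m``
    white-noise reference channels at ``cfg.variance_fraction`` of the
    normalized data variance (= the fraction itself, since normalized series
    have unit variance) → joint MEMD → restore data SDs.  Roles are preserved
    so downstream code can separate data IMFs from noise IMFs.
    """
    if isinstance(data, TrialTensor):
        data, _ = reshape_trials(data)
    normalized, sds = normalize_sd(data)
    noise = make_noise_channels(data.n_time, cfg, reference_variance=1.0)
    composite = MultichannelSeries(
        np.hstack([normalized.values, noise.values]),
        data.sample_rate_hz,
        roles=list(normalized.roles) + list(noise.roles),
        labels=list(normalized.labels) + list(noise.labels),
    )
    dec = memd(composite, K=K, cfg=sift_cfg)
    return restore_sd(dec, sds)
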