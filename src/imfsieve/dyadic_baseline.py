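"""White-noise dyadic-filter significance test (comparison baseline).

EMD of white noise behaves like a dyadic filter bank, and the product of an
IMF's energy density Ē = mean(c²) and its mean period T̄ is approximately
constant across scales.  The classical significance test exploits this: on
log axes the white-noise IMFs fall on the line ln Ē = −ln T̄, with spread

    ln Ē = −ln T̄ ± z_{1−α/2} · sqrt(2/N) · exp(ln T̄ / 2),

shrinking as 1/√N since an IMF of period T̄ averages ≈ N/T̄ independent
oscillations.  An IMF lying outside the band is declared significant.

Because real recordings are not unit-variance white noise, the line is
anchored per channel at scale 1 (the fastest IMF, in practice almost pure
noise) rather than at the theoretical unit-energy intercept.  The test
assumes the background noise is white and the scales dyadic — the assumption
whose failure motivates the Wasserstein reference-channel procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .memd import IMFDecomposition

__all__ = ["EnergyPeriodPoint", "energy_period", "spread_bounds",
           "dyadic_significance"]


@dataclass(frozen=True)
class EnergyPeriodPoint:
    """One IMF's position in the (log mean period, log energy) plane."""

    scale: int
    log_energy: float
    log_mean_period: float  # natural log, period in samples
    mean_period_s: float


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s[s == 0] = 1  # exact zeros counted with the following sign
    return int(np.sum(s[1:] != s[:-1]))


def energy_period(imf, fs: float, scale: int = 0) -> EnergyPeriodPoint:
    """Energy density and mean period of a single IMF.

    Energy is the mean squared amplitude; the mean period is 2N divided by
    the number of zero crossings (two crossings per cycle), in samples.
    """
    x = np.asarray(imf, dtype=float).ravel()
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("constant IMF has no period or energy scale")
    zc = _zero_crossings(x)
    if zc == 0:
        raise ValueError("IMF has no zero crossings; period undefined")
    energy = float(np.mean(x ** 2))
    period = 2.0 * x.size / zc
    return EnergyPeriodPoint(scale=scale, log_energy=float(np.log(energy)),
                             log_mean_period=float(np.log(period)),
                             mean_period_s=period / fs)


def spread_bounds(log_period, N: int, alpha: float = 0.05
                  ) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Lower/upper log-energy bounds of the white-noise energy spread
    function at the given log mean period (natural log, samples)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(log_period, dtype=float)
    z = ndtri(1 - alpha / 2)
    half = z * np.sqrt(2.0 / N) * np.exp(x / 2)
    lower, upper = -x - half, -x + half
    if x.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def dyadic_significance(dec: IMFDecomposition, alpha: float = 0.05) -> np.ndarray:
    """Per (scale, data series) significance by the energy-spread test.

    Energies are computed on the SD-normalized IMFs.  Real recordings are
    not unit-variance white noise, so for each data series the level of the
    white-noise line is estimated from the series itself: the median of
    ln Ē + ln T̄ over scales 2–7, where the dyadic law holds for broadband
    noise (the first IMF is known to sit off the line, and the slowest
    scales have too few oscillations).  A scale is flagged when its log
    energy relative to that line leaves the spread band at its period.
    Scales whose IMF has no zero crossing (trend-like) are compared with the
    period clipped to the record length.
    """
    data_idx = dec.data_indices
    imfs = dec.normalized_imfs()
    N = dec.n_time
    out = np.zeros((dec.n_scales, len(data_idx)), dtype=bool)
    for c, i in enumerate(data_idx):
        points = []
        for s in range(dec.n_scales):
            x = imfs[s, :, i]
            try:
                points.append(energy_period(x, dec.sample_rate_hz, scale=s))
            except ValueError:
                e = float(np.mean(x ** 2))
                points.append(EnergyPeriodPoint(
                    scale=s,
                    log_energy=float(np.log(e)) if e > 0 else -np.inf,
                    log_mean_period=float(np.log(2 * N)),
                    mean_period_s=2 * N / dec.sample_rate_hz))
        products = [p.log_energy + p.log_mean_period for p in points]
        mid = products[1:min(7, len(products))] or products[:1]
        anchor = float(np.median(mid))
        for s, pt in enumerate(points):
            lo, hi = spread_bounds(pt.log_mean_period, N, alpha)
            dev = pt.log_energy - anchor  # energy relative to the noise line
            out[s, c] = not (lo <= dev <= hi)
    return out
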