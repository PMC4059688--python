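# imfsieve

Identify the information-bearing intrinsic mode functions (IMFs) in
multichannel time series.

Multivariate empirical mode decomposition (MEMD) splits an n-channel signal
x(t) into scale-aligned oscillatory modes, x(t) = Σⱼ cⱼ(t) + r(t), without
choosing a basis in advance — attractive for electrophysiology (LFP, EEG),
where the rhythms of interest are nonstationary and not known a priori.  The
decomposition, however, returns a dozen IMFs per channel and says nothing
about which of them are signal and which are filtered noise.  `imfsieve`
answers that question with a noise-assisted statistical test:

1. append m channels of Gaussian white noise (default m = 15 at 6% of the
   data variance) and run **one** joint MEMD on the composite — the noise
   IMFs are scale-matched references;
2. at each scale j, estimate the first Wasserstein distance
   W₁(F, G) = ∫₀¹ |F⁻¹(u) − G⁻¹(u)| du between IMF amplitude distributions
   from rank-order statistics (for equal N: the mean absolute difference of
   sorted samples), after standardizing each IMF so only the distribution's
   *shape* matters;
3. build the Monte-Carlo null from the m(m−1)/2 noise-pair distances at
   that scale and take its [0.025, 0.975] quantiles;
4. flag the data IMF cⱼ of a channel as information-bearing (p < 0.05) when
   its mean distance to the noise references falls outside that interval.

Because the test compares rank-based distribution shapes rather than
energies, it is robust to outliers and to a mismatch between the reference
noise (white) and the noise actually contaminating the data (pink,
anti-persistent, …) — in contrast to the classical white-noise dyadic
significance test, which is also implemented here as a baseline
(`dyadic_significance`).

## Worked example

```python
import numpy as np
from imfsieve import (FixtureSpec, NoiseConfig, dominant_frequency,
                      identify, make_fixture, na_memd_decompose)

# trivariate benchmark: 50 Hz on X,Y,Z; 12 Hz on X,Y; 26 Hz on X,Z; noise
spec = FixtureSpec(seed=3)
fixture = make_fixture(spec)

dec = na_memd_decompose(fixture, NoiseConfig(m=15, variance_fraction=0.06,
                                             seed=4))
report = identify(dec)
for s in range(7):
    f = dominant_frequency(dec.imfs[s, :, 0], dec.sample_rate_hz)
    stars = "".join("*" if report.significant[s, c] else "." for c in range(3))
    print(f"C{s+1}: {f:6.1f} Hz   d(X,Y,Z) = {np.round(report.distances[s],3)}   "
          f"CI = [{report.ci_low[s]:.3f}, {report.ci_high[s]:.3f}]   {stars}")
```

prints

```
C1:  429.7 Hz   d(X,Y,Z) = [0.028 0.026 0.026]   CI = [0.018, 0.043]   ...
C2:  189.2 Hz   d(X,Y,Z) = [0.037 0.024 0.027]   CI = [0.016, 0.046]   ...
C3:  128.2 Hz   d(X,Y,Z) = [0.03  0.025 0.028]   CI = [0.017, 0.053]   ...
C4:   50.0 Hz   d(X,Y,Z) = [0.216 0.22  0.217]   CI = [0.024, 0.069]   ***
C5:   25.9 Hz   d(X,Y,Z) = [0.201 0.056 0.22 ]   CI = [0.025, 0.074]   *.*
C6:   12.0 Hz   d(X,Y,Z) = [0.234 0.227 0.065]   CI = [0.041, 0.145]   **.
C7:    4.6 Hz   d(X,Y,Z) = [0.108 0.115 0.103]   CI = [0.065, 0.255]   ...
```

Read it row by row: the fast scales C1–C3 are pure noise — their distances
to the references (~0.03) sit inside the noise-pair confidence intervals.
C4 oscillates at 50 Hz and is flagged (`*`) in all three channels; C5
(26 Hz) is flagged in X and Z but not Y; C6 (12 Hz) in X and Y but not Z —
exactly the designed layout.  A flagged distance ≈ 0.2 is the scale of
W₁ between a unit-SD sinusoid's arcsine distribution and a Gaussian
(≈ 0.25); an unflagged Y-distance at C5 (0.056) means Y's content at that
scale is indistinguishable in shape from the references.

The same pipeline runs from the shell:

```
imfsieve decompose --input data.tsv --fs 1000 --noise-channels 15 \
    --noise-var 0.06 --seed 42 --out dec.h5
imfsieve identify --decomposition dec.h5 --out report.tsv
imfsieve baseline --decomposition dec.h5 --alpha 0.05 --out baseline.tsv
```

Input is a TSV/CSV with one column per series (header row = labels) or an
HDF5 Time × Channels × Trials tensor; `report.tsv` has one row per
(scale, series) with the distance, CI and the boolean call, plus a JSON
mirror carrying the run configuration.

## Library layout

| module | contents |
| --- | --- |
| `imfsieve.memd` | MEMD core: Hammersley/antithetic direction sets, projections, spline envelope means, sifting, `memd()` |
| `imfsieve.na_memd` | trial reshaping, SD normalization/restoration, reference-noise channels, `na_memd_decompose()` |
| `imfsieve.wasserstein` | empirical CDF/quantiles, `w_distance()`, sliding-window variant |
| `imfsieve.significance` | noise-pair null, CIs, `identify()` |
| `imfsieve.dyadic_baseline` | classical white-noise energy-spread test |
| `imfsieve.synth` | trivariate fixture, white/pink/fGn generators, Type I/II trial scoring, SNR sweeps |
| `imfsieve.io`, `imfsieve.cli` | TSV/HDF5 readers and writers, run configs, the `imfsieve` command |

See `docs/methods.md` for the model assumptions, all tunable parameters
with their defaults and rationale, and known limitations.

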