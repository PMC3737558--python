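"""Error bars for correlated series: blocking and autocorrelation time.

Monte Carlo samples taken every fixed number of iterations are serially
correlated, so the naive standard error underestimates the true
uncertainty.  The blocking method (iterated pairwise block averaging)
recovers an honest error bar: block the series pairwise, recompute the
standard error of the block means, and repeat; once blocks are longer
than the correlation time the estimate plateaus, and the plateau value
is the reported error.

The integrated autocorrelation time uses the convention ``tau = 1/2 +
sum_{t>=1} rho(t)``, so an uncorrelated series has ``tau = 0.5`` and the
effective number of independent samples is ``n / (2 tau)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockingResult",
    "AutocorrelationTime",
    "blocking_error",
    "autocorrelation_time",
]

TAU_CONVENTION = "integrated autocorrelation time; tau = 0.5 for iid samples"

_MIN_SERIES = 32
_MIN_BLOCKS = 32


@dataclass
class BlockingResult:
    """Mean, blocking error bar and the full block-size curve."""

    mean: float
    stderr: float
    block_curve: list = field(default_factory=list)  # (block_size, stderr, nblocks)
    plateau_block_size: int | None = None
    plateau_found: bool = True


def blocking_error(series) -> BlockingResult:
    """Blocking (iterated pairwise averaging) error estimate.

    At each level the series is halved by averaging adjacent pairs and
    the standard error of the block means is recorded; levels stop once
    fewer than 32 blocks remain.  The plateau is the first level whose
    estimate agrees with the next level's to within its own statistical
    uncertainty (``stderr / sqrt(2 (n_blocks - 1))``).  If no plateau is
    found the largest level estimate is returned, flagged as
    non-plateaued — a conservative choice.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("blocking_error expects a one-dimensional series")
    if len(x) < _MIN_SERIES:
        raise ValueError(f"series of length {len(x)} is too short for a "
                         f"reliable blocking plateau (need >= {_MIN_SERIES})")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")

    mean = float(x.mean())
    curve = []
    arr = x
    block = 1
    while len(arr) >= _MIN_BLOCKS:
        nb = len(arr)
        se = float(arr.std(ddof=1) / math.sqrt(nb))
        curve.append((block, se, nb))
        arr = arr[: 2 * (nb // 2)].reshape(-1, 2).mean(axis=1)
        block *= 2

    for (bs, se, nb), (_, se_next, _) in zip(curve, curve[1:]):
        uncertainty = se / math.sqrt(2.0 * (nb - 1))
        if abs(se_next - se) <= uncertainty:
            return BlockingResult(mean, se, curve, bs, True)

    best = max(se for _, se, _ in curve)
    return BlockingResult(mean, best, curve, None, False)


@dataclass(frozen=True)
class AutocorrelationTime:
    """Integrated autocorrelation time with its summation window."""

    tau: float
    window: int
    convention: str = TAU_CONVENTION

    def __float__(self) -> float:
        return self.tau


def autocorrelation_time(series, c: float = 6.0) -> AutocorrelationTime:
    """Integrated autocorrelation time with an automatic window.

    ``tau = 1/2 + sum_{t=1}^{W} rho(t)`` where the window ``W`` is the
    smallest lag satisfying ``W >= c * tau(W)`` (self-consistent
    truncation; ``c = 6`` balances bias against noise).  Warns when the
    series is shorter than ``100 tau``, where the estimate itself becomes
    unreliable.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("autocorrelation_time expects a 1-d series, n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")

    n = len(x)
    xm = x - x.mean()
    var = float((xm * xm).sum())
    if var == 0.0:
        return AutocorrelationTime(0.5, 0)

    # FFT autocovariance (zero-padded to avoid circular wrap-around).
    size = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xm, n=size)
    acov = np.fft.irfft(f * np.conj(f), n=size)[:n].real
    rho = acov / acov[0]

    tau = 0.5
    window = 0
    for t in range(1, n):
        tau += rho[t]
        window = t
        if t >= c * tau:
            break

    tau = max(tau, 0.5 * 1e-3)  # guard against pathological anticorrelation
    if n < 100 * tau:
        warnings.warn(
            f"series length {n} is below 100 tau ({100 * tau:.0f}); the "
            "autocorrelation time estimate may be unreliable", RuntimeWarning)
    return AutocorrelationTime(float(tau), window)
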