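"""Auto- and cross-correlation estimators for binned count traces.

Both estimators compute the normalized fluctuation correlation

    G(tau) = <dF_A(t) dF_B(t+tau)> / (<F_A> <F_B>),

with the *symmetric* normalization: at lag k the means of channel A and of
channel B are taken over their respective overlapping segments, which makes
the estimator robust to residual slow drifts.  An uncorrelated pair gives
G ~ 0 at all lags.

``correlate_direct`` evaluates every integer lag up to ``max_lag`` and
serves as the brute-force reference.  ``correlate_multitau`` implements the
standard quasi-logarithmic multi-tau scheme (m linear lags per level, counts
rebinned by 2 between levels); at level 0 it performs arithmetic identical
to the direct estimator.  Per-lag errors come from the dispersion of
block-wise estimates over contiguous trace segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import IntensityTrace, mean_count_rate

__all__ = ["CorrelationCurve", "correlate_direct", "correlate_multitau",
           "zero_lag_amplitude"]

_PAIRS = {"GG": ("G", "G"), "RR": ("R", "R"), "GR": ("G", "R")}

#: a multi-tau level is kept only if it retains at least this many bins
#: per linear lag requested (blocks must still hold enough lag pairs);
#: the resulting grid reaches deep enough into the tail to anchor the
#: fitted baseline offset
_MIN_BINS_PER_LAG = 16


@dataclass
class CorrelationCurve:
    lags: np.ndarray          # s, strictly increasing
    G: np.ndarray
    G_err: np.ndarray
    pair: str                 # GG, RR or GR
    mean_rate_A: float        # Hz
    mean_rate_B: float
    duration: float           # s

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.G_err = np.asarray(self.G_err, dtype=float)
        if not (self.lags.shape == self.G.shape == self.G_err.shape):
            raise ValueError("lags, G and G_err must have equal shapes")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


def _corr_at_lag(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Symmetric-normalization correlation estimate at integer lag k >= 1."""
    n = a.size
    left = a[: n - k]
    right = b[k:]
    ma = left.mean()
    mb = right.mean()
    if ma <= 0 or mb <= 0:
        return 0.0
    return float(np.dot(left, right) / ((n - k) * ma * mb) - 1.0)


def _block_error(a: np.ndarray, b: np.ndarray, k: int, n_blocks: int) -> float:
    """Standard error of the lag-k estimate over contiguous trace blocks."""
    n = a.size
    block = n // n_blocks
    if block <= k + 1:
        return np.nan
    vals = []
    for i in range(n_blocks):
        sl = slice(i * block, (i + 1) * block)
        vals.append(_corr_at_lag(a[sl], b[sl], k))
    vals = np.asarray(vals)
    return float(vals.std(ddof=1) / np.sqrt(n_blocks))


def _finite_errors(err: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Replace non-finite error entries by the largest finite one (or |G|)."""
    err = np.asarray(err, dtype=float)
    bad = ~np.isfinite(err)
    if bad.any():
        finite = err[~bad]
        fallback = float(finite.max()) if finite.size else float(
            np.abs(G).max() if np.isfinite(G).any() else 1.0)
        err = err.copy()
        err[bad] = fallback if fallback > 0 else 1.0
    return err


def _channels(trace: IntensityTrace, pair: str):
    try:
        ca, cb = _PAIRS[pair]
    except KeyError:
        raise ValueError(f"pair must be one of {sorted(_PAIRS)}, got {pair!r}")
    return trace.counts(ca).astype(float), trace.counts(cb).astype(float), ca, cb


def correlate_direct(trace: IntensityTrace, pair: str, max_lag: float,
                     n_blocks: int = 10) -> CorrelationCurve:
    """Exact lag-by-lag correlation at every multiple of the bin width.

    O(n * n_lags); intended as the reference estimator for moderate lag
    counts.  ``max_lag`` must be below half the trace duration.
    """
    a, b, ca, cb = _channels(trace, pair)
    if max_lag >= trace.duration / 2:
        raise ValueError("max_lag must be < duration/2")
    k_max = int(np.floor(max_lag / trace.bin_width))
    if k_max < 1:
        raise ValueError("max_lag is below one bin width")
    ks = np.arange(1, k_max + 1)
    G = np.array([_corr_at_lag(a, b, int(k)) for k in ks])
    err = np.array([_block_error(a, b, int(k), n_blocks) for k in ks])
    return CorrelationCurve(
        lags=ks * trace.bin_width, G=G, G_err=_finite_errors(err, G), pair=pair,
        mean_rate_A=mean_count_rate(trace, ca),
        mean_rate_B=mean_count_rate(trace, cb),
        duration=trace.duration)


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = (x.size // 2) * 2
    return x[:n].reshape(-1, 2).sum(axis=1)


def correlate_multitau(trace: IntensityTrace, pair: str, m_per_octave: int = 16,
                       max_lag: float | None = None,
                       n_blocks: int = 10) -> CorrelationCurve:
    """Multi-tau correlation on a quasi-logarithmic lag grid.

    Level 0 evaluates lags 1..m in units of the base bin; every further
    level halves the time resolution by summing neighboring bins and adds
    lags m/2+1..m in units of the coarser bin.  Levels whose rebinned trace
    becomes too short for a block-error estimate are dropped with a warning.
    """
    if m_per_octave < 4 or m_per_octave % 2:
        raise ValueError("m_per_octave must be an even number >= 4")
    a, b, ca, cb = _channels(trace, pair)
    if max_lag is None:
        max_lag = min(1.0, trace.duration / 5.0)

    lags, G, err = [], [], []
    level = 0
    bin_width = trace.bin_width
    exhausted = False
    while True:
        ks = (range(1, m_per_octave + 1) if level == 0
              else range(m_per_octave // 2 + 1, m_per_octave + 1))
        if a.size < _MIN_BINS_PER_LAG * m_per_octave:
            if not exhausted and lags and bin_width <= max_lag:
                warnings.warn(
                    f"multi-tau: level {level} dropped, trace too short "
                    f"({a.size} bins at bin width {bin_width:.3g} s)")
            break
        done = False
        for k in ks:
            lag = k * bin_width
            if lag > max_lag:
                done = True
                break
            lags.append(lag)
            G.append(_corr_at_lag(a, b, k))
            err.append(_block_error(a, b, k, n_blocks))
        if done:
            break
        a = _rebin2(a)
        b = _rebin2(b)
        bin_width *= 2.0
        level += 1

    if not lags:
        raise ValueError("trace too short for the requested multi-tau grid")
    G = np.asarray(G)
    return CorrelationCurve(
        lags=np.asarray(lags), G=G,
        G_err=_finite_errors(np.asarray(err), G), pair=pair,
        mean_rate_A=mean_count_rate(trace, ca),
        mean_rate_B=mean_count_rate(trace, cb),
        duration=trace.duration)


def zero_lag_amplitude(curve: CorrelationCurve, n_points: int = 6) -> tuple[float, float]:
    """Short-lag correlation amplitude and its standard error.

    Inverse-variance weighted mean of the first ``n_points`` lags; the
    cross-correlation readout used to decide whether two labels co-diffuse.
    Estimates at lags well below the diffusion time share the same slow
    occupancy noise, so averaging them reduces the error very little; the
    reported SE conservatively assumes fully correlated noise (it is the
    weighted mean of the per-lag errors, not shrunk by 1/sqrt(n)).
    """
    n = min(n_points, curve.lags.size)
    if n < 1:
        raise ValueError("empty curve")
    g = curve.G[:n]
    e = curve.G_err[:n]
    ok = np.isfinite(e) & (e > 0)
    if ok.sum() >= 2:
        w = 1.0 / e[ok] ** 2
        amp = float(np.sum(w * g[ok]) / w.sum())
        se = float(np.sqrt(ok.sum() / w.sum()))
    else:
        amp = float(g.mean())
        se = float(g.std(ddof=1)) if n > 1 else float("inf")
    return amp, se
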