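"""Photobleaching compensation and background correction.

Slow photobleaching makes the mean intensity decay over the acquisition,
which inflates correlation amplitudes if left in place.  We fit a
mono-exponential to the coarsely rebinned intensity and apply the standard
square-root detrending transform

    F_c(t) = F(t) / sqrt(f(t)) + F0 * (1 - sqrt(f(t))) * bin_width,

with f(t) = exp(-t / tau_b), which restores a stationary mean while
preserving fluctuation statistics to first order.

Uncorrelated background (detector dark counts, cellular autofluorescence)
attenuates the correlation amplitude by ((F - B)/F)^2; the apparent particle
number from a fit is corrected by the same factor.  B is an ensemble-median
scalar per channel and compartment, measured on untagged cells and supplied
via configuration — it is never estimated from the analyte trace itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import IntensityTrace, mean_count_rate

__all__ = ["BleachModel", "BackgroundEstimate", "fit_bleach", "detrend",
           "correct_background"]

#: fitted decay over the trace below this fraction counts as no bleaching
_NEGLIGIBLE_DECAY = 0.02


@dataclass(frozen=True)
class BleachModel:
    """Mono-exponential intensity decay F(t) = F0 * exp(-t / tau_b)."""

    F0: float                 # initial rate (Hz)
    tau_b: float              # decay time (s); inf when negligible
    channel: str
    negligible: bool = False

    def f(self, t) -> np.ndarray:
        """Normalized decay F_fit(t)/F0 in (0, 1]."""
        t = np.asarray(t, dtype=float)
        if self.negligible or not np.isfinite(self.tau_b):
            return np.ones_like(t)
        return np.exp(-t / self.tau_b)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Ensemble-median background count rates per channel (Hz)."""

    B_G: float
    B_R: float
    source: str = ""          # compartment label
    n_cells: int = 1

    def __post_init__(self):
        if self.B_G < 0 or self.B_R < 0:
            raise ValueError("background rates must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def rate(self, channel: str) -> float:
        if channel == "G":
            return self.B_G
        if channel == "R":
            return self.B_R
        raise ValueError(f"unknown channel {channel!r}")


def fit_bleach(trace: IntensityTrace, channel: str,
               coarse_bin: float | None = None) -> BleachModel:
    """Fit a mono-exponential decay to the coarsely rebinned intensity.

    The coarse rebinning (default 1 s, shortened for brief traces)
    decouples the s-scale decay from ms-scale diffusion fluctuations.  If
    the fitted decay over the whole trace is below 2%, or the fit does not
    converge, the model is flagged negligible and detrending becomes the
    identity.
    """
    if coarse_bin is None:
        coarse_bin = min(1.0, trace.duration / 20.0)
    if trace.duration < 10 * coarse_bin:
        raise ValueError("trace must span at least 10 coarse bins")
    counts = trace.counts(channel)
    per = max(1, int(round(coarse_bin / trace.bin_width)))
    n_coarse = counts.size // per
    coarse = counts[: n_coarse * per].reshape(n_coarse, per).sum(axis=1)
    rate = coarse / (per * trace.bin_width)
    t = (np.arange(n_coarse) + 0.5) * per * trace.bin_width
    F_mean = mean_count_rate(trace, channel)

    if F_mean <= 0:
        return BleachModel(F0=0.0, tau_b=np.inf, channel=channel, negligible=True)

    # endpoint ratio for the initial decay-time guess
    q = max(2, n_coarse // 5)
    r0, r1 = rate[:q].mean(), rate[-q:].mean()
    if r1 >= r0 or r1 <= 0:
        return BleachModel(F0=F_mean, tau_b=np.inf, channel=channel, negligible=True)
    tau0 = min(trace.duration / np.log(r0 / r1), 100 * trace.duration)

    try:
        popt, _ = curve_fit(
            lambda tt, F0, tau: F0 * np.exp(-tt / tau), t, rate,
            p0=(r0, tau0), bounds=([0, trace.bin_width], [np.inf, np.inf]),
            maxfev=10000)
        F0, tau_b = float(popt[0]), float(popt[1])
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"bleach fit did not converge ({exc}); assuming no bleaching")
        return BleachModel(F0=F_mean, tau_b=np.inf, channel=channel, negligible=True)

    negligible = trace.duration / tau_b < -np.log1p(-_NEGLIGIBLE_DECAY)
    return BleachModel(F0=F0, tau_b=tau_b, channel=channel, negligible=negligible)


def detrend(trace: IntensityTrace, model: BleachModel) -> IntensityTrace:
    """Apply the square-root bleaching correction to the model's channel.

    With a negligible model the input trace is returned unchanged.  The
    corrected trace is stationary in mean at the initial-intensity scale.
    """
    if model.negligible:
        return trace
    t = (np.arange(trace.n_bins) + 0.5) * trace.bin_width
    f = model.f(t)
    if np.any(f <= 0):
        raise ValueError("bleach model reaches zero intensity inside the trace")
    root = np.sqrt(f)
    counts = trace.counts(model.channel)
    corrected = counts / root + model.F0 * trace.bin_width * (1.0 - root)
    return trace.with_counts(model.channel, corrected)


def correct_background(N_apparent: float, mean_rate: float,
                       background: BackgroundEstimate,
                       channel: str) -> tuple[float, float]:
    """Correct an apparent particle number for uncorrelated background.

    Background dilutes the relative fluctuations, attenuating the measured
    amplitude by ((F - B)/F)^2, so the fitted N overestimates the true
    occupancy by the inverse factor.  Returns ``(N_corrected, factor)`` with
    N_corrected = N_apparent * ((F - B)/F)^2.
    """
    if N_apparent <= 0:
        raise ValueError("N_apparent must be positive")
    B = background.rate(channel)
    if mean_rate <= B:
        raise ValueError(
            f"mean rate {mean_rate:.3g} Hz does not exceed background "
            f"{B:.3g} Hz in channel {channel}; measurement unusable")
    factor = ((mean_rate - B) / mean_rate) ** 2
    return N_apparent * factor, factor
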