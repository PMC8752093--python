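"""Single-component 3D free-diffusion model and weighted curve fitting.

The model for free diffusion through a 3D-Gaussian observation volume is

    G(tau) = offset + (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(kappa^2 tau_D))^-1/2,

with mean occupancy N, diffusion time tau_D and fixed structure parameter
kappa (jointly floating kappa and tau_D is poorly identifiable on
single-cell curves).  Fits are weighted least squares with weights
1/G_err^2; the shortest lags (default below 5x the base lag) are excluded
to suppress shot-noise artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .correlate import CorrelationCurve

__all__ = ["DiffusionFit", "model_3d_diffusion", "fit_curve"]

_N_BOUNDS = (1e-3, 1e6)


def model_3d_diffusion(tau, N, tau_D, kappa, offset=0.0):
    """Correlation of one freely diffusing species in a 3D-Gaussian volume."""
    tau = np.asarray(tau, dtype=float)
    x = tau / tau_D
    return offset + (1.0 / N) / ((1.0 + x) * np.sqrt(1.0 + x / kappa**2))


@dataclass(frozen=True)
class DiffusionFit:
    N: float                  # mean occupancy = 1 / amplitude
    tau_D: float              # s
    offset: float
    kappa: float              # fixed during the fit
    chi2_reduced: float
    se_N: float
    se_tauD: float
    converged: bool
    message: str = ""

    @property
    def amplitude(self) -> float:
        return 1.0 / self.N


def _failed(kappa: float, message: str) -> DiffusionFit:
    return DiffusionFit(N=np.nan, tau_D=np.nan, offset=np.nan, kappa=kappa,
                        chi2_reduced=np.nan, se_N=np.nan, se_tauD=np.nan,
                        converged=False, message=message)


def fit_curve(curve: CorrelationCurve, kappa: float,
              weights: np.ndarray | None = None,
              min_lag: float | None = None,
              float_offset: bool = True) -> DiffusionFit:
    """Weighted least-squares fit of the 3D-diffusion model to a curve.

    Initial guesses: N0 = 1/max(G), tau_D0 = lag at half maximum.  Bounds:
    N in [1e-3, 1e6], tau_D in [shortest lag, duration/10].  A curve whose
    amplitude is indistinguishable from zero (all-zero or negative) returns
    ``converged=False`` rather than silent defaults.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    lags = curve.lags
    if min_lag is None:
        min_lag = 5.0 * lags[0] if lags.size else 0.0
    mask = lags >= min_lag
    lags = lags[mask]
    G = curve.G[mask]
    if lags.size < 8:
        return _failed(kappa, "too few lags after the short-lag cut")
    if not np.all(np.isfinite(G)) or np.nanmax(G) <= 0:
        return _failed(kappa, "no positive correlation amplitude")

    if weights is None:
        err = curve.G_err[mask]
        ok = np.isfinite(err) & (err > 0)
        if ok.sum() >= lags.size // 2:
            err = err.copy()
            if (~ok).any():
                err[~ok] = np.median(err[ok])
            weights = 1.0 / err
        else:
            weights = np.ones_like(G)

    g_max = float(np.max(G))
    # lag where G first drops below half maximum, as the tau_D guess
    below = np.nonzero(G <= g_max / 2.0)[0]
    tau0 = float(lags[below[0]]) if below.size else float(lags[lags.size // 2])
    tau_lo, tau_hi = float(lags[0]), curve.duration / 10.0
    tau0 = float(np.clip(tau0, tau_lo, tau_hi))

    params = lmfit.Parameters()
    params.add("N", value=float(np.clip(1.0 / g_max, *_N_BOUNDS)),
               min=_N_BOUNDS[0], max=_N_BOUNDS[1])
    params.add("tau_D", value=tau0, min=tau_lo, max=tau_hi)
    params.add("offset", value=0.0, vary=float_offset,
               min=-0.5 * g_max, max=0.5 * g_max)

    def residual(p):
        model = model_3d_diffusion(lags, p["N"].value, p["tau_D"].value,
                                   kappa, p["offset"].value)
        return (G - model) * weights

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
    except Exception as exc:  # lmfit raises on pathological inputs
        return _failed(kappa, f"fit error: {exc}")

    p = result.params
    nvary = sum(1 for q in p.values() if q.vary)
    ndof = max(1, lags.size - nvary)
    chi2_red = float(np.sum(np.asarray(result.residual) ** 2) / ndof)

    def stderr(name):
        s = p[name].stderr
        return float(s) if s is not None else np.nan

    fit = DiffusionFit(
        N=float(p["N"].value), tau_D=float(p["tau_D"].value),
        offset=float(p["offset"].value), kappa=float(kappa),
        chi2_reduced=chi2_red, se_N=stderr("N"), se_tauD=stderr("tau_D"),
        converged=bool(result.success), message=str(result.message))
    if not (fit.N > 0 and fit.tau_D > 0 and np.isfinite(fit.N)):
        return _failed(kappa, "non-physical parameter estimate")
    return fit
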