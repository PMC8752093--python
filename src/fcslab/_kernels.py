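"""Numba inner loop for Brownian propagation through a 3D-Gaussian detection profile.

Gaussian increments are produced from uniform variates via an inverse-CDF
rational approximation (Acklam's algorithm, relative error ~1e-9, exact
moments to float precision), fused into the propagation loop; uniform
blocks are cheaper to draw from numpy generators than normals, and the
transform vectorizes well inside the jitted loop.
"""

import numpy as np
from numba import njit

# lowest admissible uniform: float32 blocks can contain exact zeros
_U_FLOOR = 1e-12


@njit(inline="always", fastmath=True)
def _ndtri(p):
    """Inverse standard-normal CDF (Acklam's rational approximation)."""
    if p < 0.02425:
        q = np.sqrt(-2.0 * np.log(p))
        return -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                    - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                  + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif p > 0.97575:
        q = np.sqrt(-2.0 * np.log(1.0 - p))
        return (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                   - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                 + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    q = p - 0.5
    r = q * q
    return (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
               - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
             - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
        (((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
            - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
          - 1.328068155288572e+01) * r + 1.0)


@njit(cache=True, fastmath=True)
def propagate_and_detect(
    pos,            # (P, 3) float64, particle positions, updated in place
    uniforms,       # (n_steps, P, 3) float32 in [0, 1)
    sigma,          # float, step standard deviation per axis (um)
    steps_per_bin,  # int
    inv_wxy2,       # 1 / omega_xy^2 (um^-2)
    inv_wz2,        # 1 / omega_z^2 (um^-2)
    half_x, half_y, half_z,  # box half-widths (um), periodic wrap at +-half
    death_step,     # (P,) int64, global step at which the particle goes dark
    mdf_sum,        # (n_bins,) float64, accumulates sum over steps of MDF
    start_step,     # int, global index of uniforms[0]
):
    n_steps = uniforms.shape[0]
    n_particles = pos.shape[0]
    for s in range(n_steps):
        g = start_step + s
        b = g // steps_per_bin
        acc = 0.0
        for p in range(n_particles):
            ux = max(np.float64(uniforms[s, p, 0]), _U_FLOOR)
            uy = max(np.float64(uniforms[s, p, 1]), _U_FLOOR)
            uz = max(np.float64(uniforms[s, p, 2]), _U_FLOOR)
            x = pos[p, 0] + sigma * _ndtri(ux)
            if x > half_x:
                x -= 2.0 * half_x
            elif x < -half_x:
                x += 2.0 * half_x
            y = pos[p, 1] + sigma * _ndtri(uy)
            if y > half_y:
                y -= 2.0 * half_y
            elif y < -half_y:
                y += 2.0 * half_y
            z = pos[p, 2] + sigma * _ndtri(uz)
            if z > half_z:
                z -= 2.0 * half_z
            elif z < -half_z:
                z += 2.0 * half_z
            pos[p, 0] = x
            pos[p, 1] = y
            pos[p, 2] = z
            # MDF(r) = exp(-2 (x^2+y^2)/w_xy^2 - 2 z^2/w_z^2); skip when < ~1e-13
            # or when the particle has photobleached (gone dark)
            if g < death_step[p]:
                e = -2.0 * (x * x + y * y) * inv_wxy2 - 2.0 * z * z * inv_wz2
                if e > -30.0:
                    acc += np.exp(e)
        mdf_sum[b] += acc
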