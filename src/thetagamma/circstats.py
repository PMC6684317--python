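"""Circular statistics helpers.

Weighted circular moments for gamma-field gravity features and the
circular-linear regression/correlation used for theta phase precession
(Kempter et al., J Neurosci Methods 2012).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def circ_mean(angles, weights=None):
    """Weighted circular mean of angles (radians), in (-pi, pi]."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    resultant = np.sum(weights * np.exp(1j * angles))
    return float(np.angle(resultant))


def circ_r(angles, weights=None):
    """Weighted mean resultant length, in [0, 1]."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float(np.abs(np.sum(weights * np.exp(1j * angles))) / total)


def circ_sd(angles, weights=None):
    """Weighted circular standard deviation sqrt(-2 ln R) (radians)."""
    r = circ_r(angles, weights)
    r = min(max(r, 1e-300), 1.0)
    return float(np.sqrt(max(-2.0 * np.log(r), 0.0)))


def wrap_angle(angles):
    """Wrap to (-pi, pi]."""
    wrapped = np.angle(np.exp(1j * np.asarray(angles, dtype=float)))
    # np.angle returns [-pi, pi); move -pi to +pi for the (-pi, pi] convention
    if np.ndim(wrapped) == 0:
        return float(np.pi) if wrapped == -np.pi else float(wrapped)
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped


def circ_lin_corr(x, phi):
    """Circular-linear correlation between linear x and circular phi.

    Returns (r, p) where r is the correlation coefficient of
    Kempter et al. (2012), eq. for r_cl based on the fitted circular
    variable, and p the large-sample normal test.  The caller supplies
    phi already reduced against the fitted slope when scoring a
    regression (see :func:`thetagamma.spatial.circular_linear_fit`).
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    phi_bar = circ_mean(phi)
    theta_bar = circ_mean(x)
    sin_p = np.sin(phi - phi_bar)
    sin_t = np.sin(x - theta_bar)
    denom = np.sqrt(np.sum(sin_p**2) * np.sum(sin_t**2))
    if denom == 0:
        return 0.0, 1.0
    r = float(np.sum(sin_p * sin_t) / denom)
    lam20 = np.mean(sin_t**2)
    lam02 = np.mean(sin_p**2)
    lam22 = np.mean(sin_t**2 * sin_p**2)
    if lam22 <= 0:
        return r, 1.0
    z = r * np.sqrt(n * lam20 * lam02 / lam22)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, p
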