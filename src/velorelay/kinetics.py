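"""First-order reaction kinetics of mRNA transcription, splicing and degradation.

A single gene's premature (unspliced, ``u``) and mature (spliced, ``s``)
mRNA abundances follow

.. math::

    du/dt = \\alpha - \\beta u, \\qquad
    ds/dt = \\beta u - \\gamma s,

with transcription rate :math:`\\alpha`, splicing rate :math:`\\beta` and
degradation rate :math:`\\gamma`.  Everything else in the package — the
kinetic simulator, the relay-loss trainer and the benchmark metrics — is
built on the three functions here: the instantaneous velocity, a single
forward-Euler extrapolation step, and the exact solution for constant
rates (used as an independent oracle for the numerical simulator).

All rates are unitless: absolute time scales are not identifiable from
spliced/unspliced snapshots alone, so only directions and rate ratios
carry meaning downstream.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "instantaneous_velocity",
    "extrapolate_state",
    "closed_form_constant_rates",
]


def _validate_finite(**kwargs: object) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite, got {value!r}")


def instantaneous_velocity(u, s, alpha, beta, gamma):
    """Time derivatives ``(du/dt, ds/dt)`` of the kinetic ODEs.

    Parameters are scalars or broadcastable arrays.  Returns the pair
    ``(alpha - beta*u, beta*u - gamma*s)``.
    """
    _validate_finite(u=u, s=s, alpha=alpha, beta=beta, gamma=gamma)
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    du = alpha - beta * u
    ds = beta * u - gamma * s
    if du.ndim == 0:
        return float(du), float(ds)
    return du, ds


def extrapolate_state(u, s, alpha, beta, gamma, dt: float):
    """One forward-Euler step of size ``dt``.

    Returns the raw extrapolated state ``(u + dt*(a - b*u), s + dt*(b*u - g*s))``
    without clipping at zero: the relay loss only uses the *direction* of the
    displacement, and clipping would bias the predicted vector's angle.
    """
    if not (np.isscalar(dt) and np.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be a positive finite scalar, got {dt!r}")
    du, ds = instantaneous_velocity(u, s, alpha, beta, gamma)
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    u_next = u + dt * np.asarray(du)
    s_next = s + dt * np.asarray(ds)
    if u_next.ndim == 0:
        return float(u_next), float(s_next)
    return u_next, s_next


def closed_form_constant_rates(u0, s0, alpha, beta, gamma, t):
    """Exact solution of the kinetic ODEs for constant rates.

    For ``beta != gamma``::

        u(t) = a/b + (u0 - a/b) e^{-b t}
        s(t) = a/g + (s0 - a/g) e^{-g t} + b (u0 - a/b) (e^{-b t} - e^{-g t})/(g - b)

    The degenerate ``beta == gamma`` case is handled analytically with the
    ``t e^{-b t}`` limit term rather than by perturbing the rates.  As
    ``t -> inf`` the solution converges to the fixed point ``(a/b, a/g)``.
    ``t`` may be an array.
    """
    _validate_finite(u0=u0, s0=s0, alpha=alpha, beta=beta, gamma=gamma, t=t)
    beta = float(beta)
    gamma = float(gamma)
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    u0 = float(u0)
    s0 = float(s0)
    alpha = float(alpha)
    t = np.asarray(t, dtype=float)

    u_ss = alpha / beta
    s_ss = alpha / gamma
    eb = np.exp(-beta * t)
    cu = u0 - u_ss
    u = u_ss + cu * eb
    if np.isclose(beta, gamma, rtol=1e-12, atol=1e-15):
        # lim_{g->b} (e^{-bt} - e^{-gt})/(g - b) = t e^{-bt}
        s = s_ss + (s0 - s_ss) * np.exp(-gamma * t) + beta * cu * t * eb
    else:
        eg = np.exp(-gamma * t)
        s = s_ss + (s0 - s_ss) * eg + beta * cu * (eb - eg) / (gamma - beta)
    if u.ndim == 0:
        return float(u), float(s)
    return u, s
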