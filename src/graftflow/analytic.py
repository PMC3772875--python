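"""Closed-form laminar pipe-flow solutions used as validation oracles.

These are independent of the finite-element path: steady Poiseuille flow and
pulsatile Womersley flow in a rigid circular tube, both driven by a
prescribed flow rate (the quantity the plug inlet imposes).
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv

__all__ = [
    "poiseuille_centerline",
    "poiseuille_wall_shear",
    "poiseuille_profile",
    "womersley_alpha",
    "womersley_profile",
]


def poiseuille_centerline(mean_velocity: float) -> float:
    """Fully developed centerline velocity = 2 V (cm/s)."""
    return 2.0 * mean_velocity


def poiseuille_wall_shear(mu: float, mean_velocity: float,
                          radius: float) -> float:
    """Developed wall shear 4 mu V / r (dyne/cm^2)."""
    return 4.0 * mu * mean_velocity / radius


def poiseuille_profile(r: np.ndarray, radius: float,
                       mean_velocity: float) -> np.ndarray:
    return 2.0 * mean_velocity * (1.0 - (np.asarray(r) / radius) ** 2)


def womersley_alpha(radius: float, period: float, nu: float,
                    harmonic: int = 1) -> float:
    return radius * np.sqrt(2.0 * np.pi * harmonic / (period * nu))


def womersley_profile(r, t, radius: float, period: float,
                      mean_velocity: float, amplitudes, phases,
                      nu: float) -> np.ndarray:
    """Axial velocity u(r, t) for flux-driven pulsatile tube flow.

    The cross-section-mean velocity is
    v(t) = V (1 + sum_k a_k cos(2 pi k t / T + phi_k)); the steady part is
    the Poiseuille profile, each harmonic the Womersley solution scaled to
    carry that harmonic's flux:

        u_k(r) = (V a_k) [1 - J0(beta_k r/R) / J0(beta_k)]
                 / [1 - 2 J1(beta_k) / (beta_k J0(beta_k))],

    beta_k = i^(3/2) alpha_k with alpha_k the k-th harmonic Womersley
    number, taking Re[u_k e^(i(k omega t + phi_k))].
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    t = np.asarray(t, dtype=float)
    u = poiseuille_profile(r, radius, mean_velocity)
    u = np.broadcast_to(u, np.broadcast_shapes(u.shape, np.shape(t))).copy() \
        if np.ndim(t) else u.copy()
    omega = 2.0 * np.pi / period
    i32 = np.exp(1j * 3.0 * np.pi / 4.0)  # i^(3/2)
    for k, (a_k, ph_k) in enumerate(zip(amplitudes, phases), start=1):
        alpha_k = womersley_alpha(radius, period, nu, harmonic=k)
        beta = i32 * alpha_k
        j0b = jv(0, beta)
        shape = 1.0 - jv(0, beta * r / radius) / j0b
        denom = 1.0 - 2.0 * jv(1, beta) / (beta * j0b)
        u_hat = mean_velocity * a_k * shape / denom
        u = u + np.real(u_hat * np.exp(1j * (k * omega * t + ph_k)))
    return u
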