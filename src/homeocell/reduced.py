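"""Reduced baseline models for mechanistic attribution.

Two deliberately restricted variants of the full framework:

* the *circular-cell* model holds the morphology fixed to a circle of
  radius ``R0`` and lets only the SF distribution respond to the cyclic
  strain — this reproduces what SF-remodeling-only models of strain
  avoidance compute, and quantifies how much alignment the cytoskeleton
  alone can produce;
* the *rod* model collapses the cell to one dimension (stretch ``lam`` and
  orientation ``theta``) and is used to predict cell-orientation modes
  under biaxial loading, which sit at the directions of vanishing cyclic
  strain-rate, ``theta = atan(1/sqrt(r))`` and its mirror.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from homeocell.ensemble import AngularDensity, circular_variance, equilibrium_weights, solve_beta
from homeocell.mechanics import CellParams, CyclicLoad, _cycle_times, substrate_strain
from homeocell.sf import SFParams, phi_grid

__all__ = [
    "RodMicrostate",
    "circular_cell_distribution",
    "rod_energy",
    "rod_orientation_density",
]


@dataclass(frozen=True)
class RodMicrostate:
    """1D cell microstate: rod stretch ``lam`` and orientation ``theta``."""

    lam: float
    theta: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("rod stretch must be positive")


def circular_cell_distribution(
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_time: int = 64,
):
    """SF distribution for a cell held circular at radius ``R0``.

    With the morphology frozen, the global and internal SF angles coincide
    (``delta = phi``) and the distribution is the cycle average of
    ``eta_hat * n_hat`` under the imposed strain-rate history.  Returns the
    normalized :class:`AngularDensity` ``xi_hat_circ`` and its circular
    variance ``CV_circ``.
    """
    from homeocell.sf import _eta_from_occupancy, solve_unbound_fraction

    delta = phi_grid(sfp.n_angular)
    times = _cycle_times(load, n_time)
    _, _, d1, _ = substrate_strain(times, load)
    geom = np.cos(delta) ** 2 - load.r * np.sin(delta) ** 2
    rate = d1[:, None] * geom[None, :]  # (T, n)
    fv = np.where(rate >= 0.0, 1.0, np.clip(1.0 + sfp.k_v * rate / sfp.eps_rate_0, 0.0, 1.0))
    n_hat = np.broadcast_to(1.0 / (1.0 + sfp.eps_ss), rate.shape)
    chi = n_hat * (sfp.alpha * fv + sfp.dmu)
    n_u = solve_unbound_fraction(n_hat, chi, sfp)  # (T,)
    y = (_eta_from_occupancy(n_hat, chi, n_u, sfp) * n_hat).mean(axis=0)
    dens = y / (y.sum() * np.pi / sfp.n_angular)
    d = AngularDensity(grid=delta, density=dens)
    return d, circular_variance(d)


def rod_energy(
    m: RodMicrostate,
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_time: int = 64,
    mu_rod: float = 3.0,
    normalize: bool = True,
) -> float:
    """Cycle-averaged free energy of a uniform rod-like cell.

    The SF population lives along the rod axis; its strain rate is the
    substrate rate resolved at angle ``theta``.  The passive part is a 1D
    convex stretch energy ``(mu_rod/2)(lam^2 + 2/lam - 3)`` with its well at
    ``lam = 1``.  Normalized by the rod's own suspension energy when
    ``normalize`` is true.
    """
    h = _rod_energy_batch(
        np.array([m.lam]), np.array([m.theta]), load, sfp, cp, n_time, mu_rod
    )[0]
    if normalize:
        h /= abs(_rod_suspension(sfp, cp, mu_rod))
    return float(h)


def _rod_energy_batch(lam, theta, load, sfp, cp, n_time, mu_rod):
    """All SF mass in one direction; same closure as the 2D model with the
    angular integral collapsed to a single bin of measure pi."""
    from homeocell.sf import _eta_from_occupancy, _xlogx, solve_unbound_fraction

    lam = np.asarray(lam, dtype=float)
    theta = np.asarray(theta, dtype=float)
    times = _cycle_times(load, n_time)
    _, _, d1, _ = substrate_strain(times, load)
    geom = np.cos(theta) ** 2 - load.r * np.sin(theta) ** 2  # (B,)
    rate = d1[None, :] * geom[:, None]  # (B, T)
    fv = np.where(rate >= 0.0, 1.0, np.clip(1.0 + sfp.k_v * rate / sfp.eps_rate_0, 0.0, 1.0))
    n_hat = lam[:, None] / (1.0 + sfp.eps_ss)
    chi = n_hat * (sfp.alpha * fv + sfp.dmu)
    m_b, m_u = sfp.mu_b0 / sfp.kT, sfp.mu_u0 / sfp.kT
    m_pack = sfp.mu_pack / sfp.kT
    nh = n_hat[..., None]
    n_u = solve_unbound_fraction(np.broadcast_to(nh, chi.shape + (1,)), chi[..., None], sfp)
    eta = _eta_from_occupancy(nh, chi[..., None], n_u, sfp)[..., 0]  # (B, T)
    y = eta * n_hat
    enth = m_pack + np.pi * y * n_hat * (m_b - sfp.alpha * fv) + m_u * n_u
    if sfp.eta_max is None or not np.isfinite(sfp.eta_max):
        mix_b = _xlogx(np.pi * y)
    else:
        thf = eta / sfp.eta_max
        mix_b = np.pi * sfp.eta_max * (_xlogx(thf) + _xlogx(1.0 - thf))
    h_cyto = sfp.n_total * sfp.kT * (enth + _xlogx(n_u) + mix_b).mean(axis=1)
    passive = 0.5 * mu_rod * (lam**2 + 2.0 / lam - 3.0)
    return h_cyto + passive


def _rod_suspension(sfp: SFParams, cp: CellParams, mu_rod: float) -> float:
    static = CyclicLoad(eps_amp=0.0, f=0.0)
    lam_s = cp.suspension_radius_factor
    return float(
        _rod_energy_batch(np.array([lam_s]), np.array([0.0]), static, sfp, cp, 8, mu_rod)[0]
    )


def rod_orientation_density(
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_lam: int = 96,
    n_theta: int = 180,
    lam_max: float = 3.0,
    n_time: int = 64,
    mu_rod: float = 3.0,
):
    """Homeostatic orientation distribution of the rod model.

    Applies the homeostatic-ensemble machinery on a uniform (lam, theta)
    grid: solve beta from ``<H_hat> = sign(H_s)`` and marginalize the
    Boltzmann weights over stretch.  Returns the :class:`AngularDensity`
    ``p(theta)`` on ``[0, pi)`` and the list of its mode angles.
    """
    lam = np.linspace(0.3, lam_max, n_lam)
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    ll, tt = np.meshgrid(lam, theta, indexing="ij")
    h_s = _rod_suspension(sfp, cp, mu_rod)
    h = _rod_energy_batch(ll.ravel(), tt.ravel(), load, sfp, cp, n_time, mu_rod)
    h = h.reshape(ll.shape) / abs(h_s)
    beta = solve_beta(h.ravel(), target=float(np.sign(h_s)))
    w = equilibrium_weights(h.ravel(), beta).reshape(ll.shape)
    p_theta = w.sum(axis=0)
    dens = p_theta / (p_theta.sum() * np.pi / n_theta)
    d = AngularDensity(grid=theta, density=dens)
    # modes: local maxima on the periodic grid
    up = dens >= np.roll(dens, 1)
    down = dens > np.roll(dens, -1)
    peak = up & down & (dens > dens.mean())
    modes = [float(a) for a in theta[peak]]
    return d, modes
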