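"""Steady-state thermodynamics of the stress-fiber (SF) cytoskeleton.

The contractile acto-myosin cytoskeleton is modeled as an angular
distribution of stress fibers.  At angle ``phi`` (measured from the major
axis of the cell) an SF packet contains ``n_hat(phi)`` functional units and
the packets have an angular concentration ``eta_hat(phi)``.  Because
intracellular remodeling is fast compared with both the strain cycle and the
evolution of cell shape, the cytoskeleton is always taken to be in its
steady state for the instantaneous strain and strain-rate of the cell:

* the number of functional units per fiber follows the fiber stretch,
  ``n_hat = (1 + eps_nom) / (1 + eps_ss)``, so that fibers at the intrinsic
  steady-state strain ``eps_ss`` carry exactly one unit;
* the fiber tension obeys a Hill-type relation: isometric or lengthening
  fibers carry the full stall stress ``sigma_max`` while shortening fibers
  lose tension linearly with contraction rate (clipped at zero);
* bound and unbound SF proteins exchange according to a saturating
  (Langmuir-type) binding isotherm with angular site capacity ``eta_max``:
  ``eta_hat = eta_max * g / (1 + g)`` with
  ``g = (N_u / (pi eta_max)) exp(chi)`` and
  ``chi = n_hat * (omega * sigma + mu_u0 - mu_b0) / kT``, subject to
  conservation of the total protein pool (``N_b + N_u = 1``).  In the
  dilute limit (``eta_max = None``) the isotherm reduces to the Boltzmann
  form ``eta_hat = (N_u / pi) exp(chi)``.

The resulting cytoskeletal free energy ``H_cyto`` combines the enthalpy of
the bound packets (chemical potential plus the stress work released by the
tension they carry) with the ideal mixing entropy of the bound and unbound
populations.  Polymerization (spreading, stretch) lowers ``H_cyto``;
contractile strain rates raise it by de-tensioning fibers through the Hill
relation.  These two features drive every prediction downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SFParams",
    "SFState",
    "phi_grid",
    "hill_factor",
    "steady_units",
    "sf_steady_state",
    "cyto_free_energy",
]


@dataclass
class SFParams:
    """Parameters of the stress-fiber model.

    Energies are measured in units of ``kT`` times the total protein count
    (reduced units, see ``docs/methods.md``); lengths in units of the
    reference cell radius ``R0``.

    Attributes
    ----------
    sigma_max : float
        Isometric (stall) SF stress scale; ``omega * sigma_max / kT`` is the
        dimensionless stress-work gain.
    eps_rate_0 : float
        Reference (unloaded-shortening) strain-rate scale of the Hill
        relation, 1/s.
    k_v : float
        Hill rate-sensitivity factor (dimensionless).
    eps_ss : float
        Intrinsic steady-state functional-unit strain.
    mu_b0, mu_u0 : float
        Reference chemical potentials of bound / unbound packets.
    omega : float
        Volume factor converting fiber stress to work per functional unit.
    kT : float
        Thermal energy scale (unit of energy in reduced units).
    n_angular : int
        Number of SF angular bins over ``(-pi/2, pi/2]``; must be even.
    n_total : float
        Total SF protein content setting the overall energy scale
        ``n_total * kT``.
    """

    sigma_max: float = 3.0
    eps_rate_0: float = 0.1
    k_v: float = 10.0
    eps_ss: float = 0.35
    mu_b0: float = -4.5
    mu_u0: float = -5.0
    omega: float = 1.0
    kT: float = 1.0
    n_angular: int = 36
    n_total: float = 1.0
    eta_max: float | None = 1.5  # angular site capacity; None = dilute (no cap)
    mu_pack: float = 4.758  # reference potential per packet, bound or unbound

    def __post_init__(self) -> None:
        if not (self.sigma_max > 0):
            raise ValueError("sigma_max must be > 0")
        if not (self.eps_rate_0 > 0):
            raise ValueError("eps_rate_0 must be > 0")
        if not (self.k_v > 0):
            raise ValueError("k_v must be > 0")
        if not (self.kT > 0):
            raise ValueError("kT must be > 0")
        if self.eps_ss <= -1:
            raise ValueError("eps_ss must be > -1")
        if self.n_angular < 8 or self.n_angular % 2:
            raise ValueError("n_angular must be >= 8 and even")

    @property
    def alpha(self) -> float:
        """Dimensionless stress-work gain ``omega * sigma_max / kT``."""
        return self.omega * self.sigma_max / self.kT

    @property
    def dmu(self) -> float:
        """Dimensionless binding-potential difference ``(mu_u0 - mu_b0)/kT``."""
        return (self.mu_u0 - self.mu_b0) / self.kT


@dataclass
class SFState:
    """Angular stress-fiber state at one instant.

    ``phi_grid`` holds angles in ``(-pi/2, pi/2]`` relative to the cell's
    major axis.  The invariant ``N_b + N_u = 1`` holds exactly, with
    ``N_b = ∫ eta_hat * n_hat dphi`` under the periodic trapezoid measure.
    """

    phi_grid: np.ndarray
    eta_hat: np.ndarray
    n_hat: np.ndarray
    N_b: float
    N_u: float
    sigma: np.ndarray = field(default=None, repr=False)  # fiber stress per bin

    def __post_init__(self) -> None:
        if not (0.0 <= self.N_u <= 1.0):
            raise ValueError("N_u must lie in [0, 1]")
        if np.any(self.eta_hat < 0):
            raise ValueError("eta_hat must be nonnegative")
        if np.any(self.n_hat <= 0):
            raise ValueError("n_hat must be positive")


def phi_grid(n: int) -> np.ndarray:
    """Uniform angular grid of ``n`` bins over ``(-pi/2, pi/2]``.

    The grid is periodic with period pi; sums over it implement the
    trapezoidal rule with periodic wrap, ``∫ f dphi ≈ (pi/n) * sum f``.
    """
    return -np.pi / 2 + np.arange(1, n + 1) * np.pi / n


def hill_factor(eps_rate_fiber, p: SFParams):
    """Hill-type stress ratio ``f_v = sigma / sigma_max`` in ``[0, 1]``.

    Lengthening or isometric fibers (rate >= 0) carry the full stall
    stress.  Shortening fibers lose tension linearly,
    ``f_v = max(0, 1 + k_v * rate / eps_rate_0)``.
    """
    rate = np.asarray(eps_rate_fiber, dtype=float)
    if not np.all(np.isfinite(rate)):
        raise ValueError("fiber strain rate must be finite")
    fv = np.clip(1.0 + p.k_v * rate / p.eps_rate_0, 0.0, 1.0)
    fv = np.where(rate >= 0.0, 1.0, fv)
    if fv.ndim == 0:
        return float(fv)
    return fv


def steady_units(eps_nom_fiber, p: SFParams):
    """Steady-state number of functional units per SF at nominal strain."""
    eps = np.asarray(eps_nom_fiber, dtype=float)
    if np.any(eps <= -1.0):
        raise ValueError("fiber nominal strain must exceed -1 (positive stretch)")
    n = (1.0 + eps) / (1.0 + p.eps_ss)
    if n.ndim == 0:
        return float(n)
    return n


def _chi(n_hat: np.ndarray, f_v: np.ndarray, p: SFParams) -> np.ndarray:
    """Dimensionless binding exponent.

    ``chi = n_hat*(omega*sigma + mu_u0 - mu_b0)/kT``; the per-packet
    reference potential ``mu_pack`` is carried by bound and unbound packets
    alike and therefore cancels from the binding equilibrium.
    """
    return n_hat * (p.alpha * f_v + p.dmu)


def _xlogx(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)


def solve_unbound_fraction(n_hat: np.ndarray, chi: np.ndarray, p: SFParams, tol: float = 1e-11):
    """Unbound fraction from protein conservation, vectorized.

    ``n_hat`` and ``chi`` have shape ``(..., n_angular)``; the conservation
    residual ``F(N_u) = N_u + eta_max ∫ n_hat g/(1+g) dphi - 1`` with
    ``g = (N_u / (pi eta_max)) exp(chi)`` is strictly increasing in ``N_u``
    with ``F(0) = -1``, so the root in ``(0, 1]`` is unique; it is found by
    a safeguarded Newton iteration (bracketed bisection fallback).  In the
    dilute limit the self-consistency is linear and solved in closed form.
    """
    e_chi = np.exp(chi)
    if p.eta_max is None or not np.isfinite(p.eta_max):
        big_i = (n_hat * e_chi).mean(axis=-1)
        return 1.0 / (1.0 + big_i)
    c = 1.0 / (np.pi * p.eta_max)
    cap = np.pi * p.eta_max  # eta_max * ∫dphi
    lo = np.zeros(chi.shape[:-1])
    hi = np.ones(chi.shape[:-1])
    u = np.full(chi.shape[:-1], 0.5)
    for _ in range(100):
        g = c * u[..., None] * e_chi
        t = g / (1.0 + g)
        f = u + cap * (n_hat * t).mean(axis=-1) - 1.0
        lo = np.where(f < 0, u, lo)
        hi = np.where(f > 0, u, hi)
        fp = 1.0 + cap * (n_hat * c * e_chi / (1.0 + g) ** 2).mean(axis=-1)
        u_new = u - f / fp
        u_new = np.where((u_new <= lo) | (u_new >= hi), 0.5 * (lo + hi), u_new)
        if np.max(np.abs(f)) < tol:
            u = u_new
            break
        u = u_new
    else:
        raise RuntimeError(
            f"unbound-fraction solve did not converge; max residual {np.max(np.abs(f)):.3e}"
        )
    return u


def _eta_from_occupancy(n_hat, chi, N_u, p: SFParams):
    e_chi = np.exp(chi)
    if p.eta_max is None or not np.isfinite(p.eta_max):
        return (np.asarray(N_u)[..., None] / np.pi) * e_chi
    g = (np.asarray(N_u)[..., None] / (np.pi * p.eta_max)) * e_chi
    return p.eta_max * g / (1.0 + g)


def sf_steady_state(strain_of_phi, rate_of_phi, p: SFParams) -> SFState:
    """Steady SF state for given angular strain and strain-rate maps.

    Parameters may be arrays over the angular grid ``phi_grid(p.n_angular)``
    or callables ``phi -> value``.  The unbound fraction solves the
    protein-conservation self-consistency (see
    :func:`solve_unbound_fraction`); the returned state satisfies
    ``N_b + N_u = 1`` to the 1e-10 solver tolerance.
    """
    phi = phi_grid(p.n_angular)
    eps = strain_of_phi(phi) if callable(strain_of_phi) else np.asarray(strain_of_phi, dtype=float)
    rate = rate_of_phi(phi) if callable(rate_of_phi) else np.asarray(rate_of_phi, dtype=float)
    if eps.shape != phi.shape or rate.shape != phi.shape:
        raise ValueError("strain/rate maps must cover the full angular grid")

    n_hat = steady_units(eps, p)
    f_v = hill_factor(rate, p)
    sigma = p.sigma_max * f_v
    chi = _chi(n_hat, f_v, p)
    N_u = float(solve_unbound_fraction(n_hat[None, :], chi[None, :], p)[0])
    eta = _eta_from_occupancy(n_hat[None, :], chi[None, :], np.array([N_u]), p)[0]
    return SFState(phi_grid=phi, eta_hat=eta, n_hat=n_hat, N_b=1.0 - N_u, N_u=N_u, sigma=sigma)


def cyto_free_energy(s: SFState, p: SFParams) -> float:
    """Cytoskeletal free energy ``H_cyto`` of a steady SF state.

    ``H_cyto = n_total * [ ∫ eta n mu_b dphi + N_u mu_u0 + kT S_mix ]``
    with the bound-packet chemical potential
    ``mu_b = mu_pack + n_hat (mu_b0 - omega sigma)`` and
    ``mu_u = mu_pack + mu_u0``: each packet carries the reference potential
    ``mu_pack`` in either phase (setting the zero of the protein free
    energy), and every bound functional unit contributes its own potential
    and the work done by the tension it carries.  ``S_mix`` combines the ideal entropy of the unbound pool with
    the site-occupancy entropy of the bound fibers
    (``eta_max ∫ [th ln th + (1-th) ln(1-th)] dphi`` with occupancy
    ``th = eta_hat / eta_max``); in the dilute limit the latter becomes the
    ideal angular mixing term ``∫ eta n ln(pi eta n) dphi``.
    """
    if s.sigma is None:
        raise ValueError("SFState.sigma required to evaluate the enthalpy")
    n = s.phi_grid.size
    dphi = np.pi / n
    y = s.eta_hat * s.n_hat  # bound packet density over phi
    mu_b = p.mu_pack + s.n_hat * (p.mu_b0 - p.omega * s.sigma)
    enthalpy = float(np.sum(y * mu_b) * dphi) + s.N_u * (p.mu_u0 + p.mu_pack)
    if p.eta_max is None or not np.isfinite(p.eta_max):
        mix_b = float(np.sum(_xlogx(np.pi * y)) * dphi / np.pi)
    else:
        th = s.eta_hat / p.eta_max
        mix_b = float(np.sum(_xlogx(th) + _xlogx(1.0 - th)) * dphi * p.eta_max)
    mix_u = s.N_u * math.log(s.N_u) if s.N_u > 0 else 0.0
    return p.n_total * (enthalpy + p.kT * (mix_u + mix_b))
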