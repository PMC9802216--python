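"""Elliptical cell microstates, cyclic substrate strain, and cell free energy.

A morphological microstate of the adherent cell is a spatially uniform
ellipse described either by the nondimensional quadratic-form coefficients
``(h, k, l)``, with the cell boundary satisfying
``h x1^2 + k x1 x2 + l x2^2 = R0^2``, or equivalently by the normalized
semi-axes ``(a1_hat, a2_hat)`` and the orientation ``theta`` of the major
axis.  The substrate is stiff, so the imposed cyclic strain (and
strain-rate) is transmitted directly to the adhered cell; the instantaneous
cell free energy is the sum of the steady-state cytoskeletal free energy
(``homeocell.sf``) and the passive elasticity of cytoplasm and nucleus, and
the quantity that enters the homeostatic ensemble is its time average over
one strain cycle, normalized by the magnitude of the suspended-cell free
energy ``|H_s|``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from homeocell.sf import SFParams, hill_factor, phi_grid, sf_steady_state, steady_units, cyto_free_energy

__all__ = [
    "CyclicLoad",
    "CellParams",
    "Microstate",
    "coeffs_from_geometry",
    "geometry_from_coeffs",
    "geometry_from_coeffs_batch",
    "area_aspect",
    "substrate_strain",
    "fiber_kinematics",
    "passive_energy",
    "cell_energy_instant",
    "cycle_averaged_energy",
    "suspension_energy",
    "hhat_batch",
]

_CIRCLE_TOL = 1e-12


@dataclass(frozen=True)
class CyclicLoad:
    """Imposed biaxial cyclic substrate strain.

    ``eps1(t) = eps_mean + (eps_amp/2) sin(2 pi f t)`` and
    ``eps2(t) = -r * eps1(t)``; ``r`` measures the biaxiality (``r = 0`` is
    uniaxial straining) and ``f = 0`` encodes a static substrate.
    """

    eps_amp: float = 0.1
    f: float = 1.0
    r: float = 0.0
    eps_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_amp < 0:
            raise ValueError("eps_amp must be >= 0")
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [0, 1]")

    @property
    def T_p(self) -> float:
        """Cycle period 1/f (inf for a static substrate)."""
        return 1.0 / self.f if self.f > 0 else math.inf

    @property
    def is_static(self) -> bool:
        return self.f == 0.0 or self.eps_amp == 0.0


@dataclass
class CellParams:
    """Cell geometry and passive-elasticity parameters (reduced units).

    Lengths are in units of ``R0``; the moduli are per unit reference area
    on the scale of the SF energy ``n_total * kT`` (see docs/methods.md).
    The shear modulus of the cell is below its bulk modulus, which is what
    makes elongated spread shapes elastically cheaper than isotropically
    spread ones.
    """

    R0: float = 1.0
    R_N: float = 0.5
    mu_cyto: float = 0.055
    kappa_cyto: float = 3.5
    mu_nuc: float = 0.11
    kappa_nuc: float = 7.0
    stiffening_exponent: float = 10.0
    volumetric_exponent: float = 4.0
    suspension_radius_factor: float = 0.96
    H_s: float | None = None  # cached suspension free energy

    def __post_init__(self) -> None:
        if not (0 < self.R_N < self.R0):
            raise ValueError("R_N must satisfy 0 < R_N < R0")
        if not (self.mu_cyto < self.kappa_cyto):
            raise ValueError("mu_cyto must be below kappa_cyto")
        if not (0 < self.suspension_radius_factor <= 1.0):
            raise ValueError("suspension_radius_factor must lie in (0, 1]")


def coeffs_from_geometry(a1_hat: float, a2_hat: float, theta: float):
    """Quadratic-form coefficients ``(h, k, l)`` of an ellipse.

    ``a1_hat >= a2_hat > 0`` are the normalized semi-major/minor axes and
    ``theta`` the major-axis orientation.
    """
    if not (a1_hat >= a2_hat > 0):
        raise ValueError("axes must satisfy a1_hat >= a2_hat > 0")
    c, s = math.cos(theta), math.sin(theta)
    inv1, inv2 = 1.0 / a1_hat**2, 1.0 / a2_hat**2
    h = c * c * inv1 + s * s * inv2
    k = (inv1 - inv2) * math.sin(2.0 * theta)
    l = c * c * inv2 + s * s * inv1
    return h, k, l


def _geometry_from_coeffs_arrays(h, k, l):
    """Vectorized closed-form eigen-decomposition of [[h, k/2], [k/2, l]]."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    l = np.asarray(l, dtype=float)
    mean = 0.5 * (h + l)
    diff = 0.5 * (h - l)
    s = np.sqrt(diff * diff + 0.25 * k * k)
    lam_min = mean - s
    lam_max = mean + s
    invalid = lam_min <= 0.0
    lam_min_safe = np.where(invalid, 1.0, lam_min)
    a1 = 1.0 / np.sqrt(lam_min_safe)
    a2 = 1.0 / np.sqrt(np.where(invalid, 1.0, lam_max))
    circular = s <= _CIRCLE_TOL * np.maximum(mean, 1.0)
    # the form h c^2 + k cs + l s^2 is minimal (major axis) along
    # theta = atan2(k, h - l)/2 + pi/2, exactly and stably for k -> 0
    theta = np.mod(0.5 * np.arctan2(k, h - l) + 0.5 * np.pi, np.pi)
    theta = np.where(circular, 0.0, theta)
    return a1, a2, theta, invalid, circular


def geometry_from_coeffs(h: float, k: float, l: float):
    """Inverse of :func:`coeffs_from_geometry`: ``(a1_hat, a2_hat, theta)``.

    ``theta`` is wrapped to ``[0, pi)``; a circle gets the tie-break
    ``theta = 0``.  Raises for a degenerate form (``4hl - k^2 <= 0``).
    """
    a1, a2, theta, invalid, _ = _geometry_from_coeffs_arrays(h, k, l)
    if invalid:
        raise ValueError(f"coefficients ({h}, {k}, {l}) do not describe an ellipse")
    return float(a1), float(a2), float(theta)


def geometry_from_coeffs_batch(hkl: np.ndarray):
    """Batched inverse mapping; returns ``(a1, a2, theta, valid)`` arrays."""
    a1, a2, theta, invalid, _ = _geometry_from_coeffs_arrays(hkl[..., 0], hkl[..., 1], hkl[..., 2])
    return a1, a2, theta, ~invalid


@dataclass(frozen=True)
class Microstate:
    """One elliptical cell morphology, stored as coefficients ``(h, k, l)``."""

    h: float
    k: float
    l: float
    a1_hat: float = field(init=False)
    a2_hat: float = field(init=False)
    theta: float = field(init=False)
    is_circular: bool = field(init=False)

    def __post_init__(self) -> None:
        if 4.0 * self.h * self.l - self.k**2 <= 0 or self.h <= 0 or self.l <= 0:
            raise ValueError("invalid ellipse: require h > 0, l > 0, 4hl - k^2 > 0")
        a1, a2, theta, _, circular = _geometry_from_coeffs_arrays(self.h, self.k, self.l)
        object.__setattr__(self, "a1_hat", float(a1))
        object.__setattr__(self, "a2_hat", float(a2))
        object.__setattr__(self, "theta", float(theta))
        object.__setattr__(self, "is_circular", bool(circular))

    @classmethod
    def from_geometry(cls, a1_hat: float, a2_hat: float, theta: float) -> "Microstate":
        return cls(*coeffs_from_geometry(a1_hat, a2_hat, theta))

    @property
    def A_hat(self) -> float:
        """Normalized area ``A / (pi R0^2) = a1_hat * a2_hat``."""
        return self.a1_hat * self.a2_hat

    @property
    def As(self) -> float:
        """Aspect ratio ``a1 / a2 >= 1``."""
        return self.a1_hat / self.a2_hat


def area_aspect(m: Microstate):
    """Normalized area and aspect ratio of a microstate."""
    return m.A_hat, m.As


def substrate_strain(t, load: CyclicLoad):
    """Principal substrate strains and strain rates at time ``t``."""
    t = np.asarray(t, dtype=float)
    if load.is_static:
        eps1 = np.broadcast_to(np.asarray(load.eps_mean), t.shape).astype(float)
        d1 = np.zeros_like(eps1)
    else:
        w = 2.0 * math.pi * load.f
        eps1 = load.eps_mean + 0.5 * load.eps_amp * np.sin(w * t)
        d1 = 0.5 * load.eps_amp * w * np.cos(w * t)
    return eps1, -load.r * eps1, d1, -load.r * d1


def _fiber_stretch(a1, a2, phi):
    """Fiber stretch at current angle phi from the homogeneous deformation.

    The reference direction phi_R maps onto the current direction phi through
    the principal stretches (a1, a2): tan(phi_R) = (a1/a2) tan(phi).
    """
    phi_r = np.arctan2(a1 * np.sin(phi), a2 * np.cos(phi))
    c, s = np.cos(phi_r), np.sin(phi_r)
    return np.sqrt((a1 * c) ** 2 + (a2 * s) ** 2)


def fiber_kinematics(m: Microstate, load: CyclicLoad, t: float, phi):
    """Nominal strain and strain rate of a fiber at angle ``phi``.

    ``phi`` is measured from the major axis.  The fiber strain follows from
    the finite homogeneous cell deformation; the fiber strain RATE is the
    substrate strain rate resolved onto the fiber's global direction
    ``delta = phi + theta`` (the cell stays adhered within the cycle).
    """
    phi = np.asarray(phi, dtype=float)
    lam = _fiber_stretch(m.a1_hat, m.a2_hat, phi)
    _, _, d1, d2 = substrate_strain(t, load)
    delta = phi + m.theta
    rate = d1 * np.cos(delta) ** 2 + d2 * np.sin(delta) ** 2
    return lam - 1.0, rate


def _ogden_w(lam1, lam2, mu, kappa, m, v):
    """2D compressible Ogden-type strain-energy density.

    Deviatoric part ``(2 mu / m^2)(lam1_dev^m + lam2_dev^m - 2)`` with
    ``lam_dev = lam / sqrt(J)`` (strain stiffening for m > 2; m = 2 is
    neo-Hookean), volumetric part ``(kappa/2)|J - 1|^v`` (v = 2 is the
    harmonic law; larger even v gives a flat-bottomed stiffening well).
    """
    j = lam1 * lam2
    x = np.sqrt(lam1 / lam2)
    return (2.0 * mu / m**2) * (x**m + x**-m - 2.0) + 0.5 * kappa * np.abs(j - 1.0) ** v


def _passive_from_axes(a1, a2, cp: CellParams):
    area_c = math.pi * (cp.R0**2 - cp.R_N**2)
    area_n = math.pi * cp.R_N**2
    m, v = cp.stiffening_exponent, cp.volumetric_exponent
    return area_c * _ogden_w(a1, a2, cp.mu_cyto, cp.kappa_cyto, m, v) + area_n * _ogden_w(
        a1, a2, cp.mu_nuc, cp.kappa_nuc, m, v
    )


def passive_energy(m: Microstate, cp: CellParams) -> float:
    """Passive elastic energy of cytoplasm and nucleus.

    Both regions deform affinely with the uniform cell stretches
    ``(lam1, lam2) = (a1_hat, a2_hat)``; zero iff undeformed.
    """
    return float(_passive_from_axes(m.a1_hat, m.a2_hat, cp))


def _cycle_times(load: CyclicLoad, n_time: int, t_I: float = 0.0) -> np.ndarray:
    """Quadrature nodes over one period (periodic trapezoid == uniform mean)."""
    if load.is_static:
        return np.array([t_I])
    return t_I + np.arange(n_time) * load.T_p / n_time


def cell_energy_instant(m: Microstate, load: CyclicLoad, t: float, sfp: SFParams, cp: CellParams) -> float:
    """Instantaneous cell free energy ``H_cell(t) = H_cyto(t) + H_passive``."""
    phi = phi_grid(sfp.n_angular)
    eps, rate = fiber_kinematics(m, load, t, phi)
    state = sf_steady_state(eps, rate, sfp)
    return cyto_free_energy(state, sfp) + passive_energy(m, cp)


def hhat_batch(
    a1,
    a2,
    theta,
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_time: int = 64,
    t_I: float = 0.0,
    normalize: bool = True,
    return_sf_profile: bool = False,
    chunk: int = 2048,
):
    """Cycle-averaged cell free energy for a batch of morphologies.

    Vectorized core used by the landscape, ensemble, and kinetics modules.
    ``a1``/``a2`` are the semi-axes along/perpendicular to direction
    ``theta`` (no ordering required).  Returns the normalized energy
    ``H_hat = H_cell / |H_s|`` when ``normalize`` is true, else raw energy.
    With ``return_sf_profile`` also returns the cycle-averaged bound-packet
    density ``<eta_hat * n_hat>(phi)`` per sample (the quantity entering the
    ensemble SF observables xi and rho).
    """
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    a2 = np.atleast_1d(np.asarray(a2, dtype=float))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), a1.shape).astype(float)
    if a1.shape != a2.shape:
        raise ValueError("a1 and a2 must have the same shape")

    phi = phi_grid(sfp.n_angular)
    times = _cycle_times(load, n_time, t_I)
    _, _, d1, _ = substrate_strain(times, load)  # (T,)

    out = np.empty(a1.shape, dtype=float)
    prof = np.empty(a1.shape + (sfp.n_angular,), dtype=float) if return_sf_profile else None

    from homeocell.sf import _eta_from_occupancy, _xlogx, solve_unbound_fraction

    alpha, dmu = sfp.alpha, sfp.dmu
    m_b, m_u = sfp.mu_b0 / sfp.kT, sfp.mu_u0 / sfp.kT
    m_pack = sfp.mu_pack / sfp.kT
    nphi = sfp.n_angular
    dphi = np.pi / nphi
    for start in range(0, a1.size, chunk):
        sl = slice(start, min(start + chunk, a1.size))
        p, q, th = a1[sl], a2[sl], theta[sl]
        lam = _fiber_stretch(p[:, None], q[:, None], phi[None, :])  # (B, n)
        n_hat = lam / (1.0 + sfp.eps_ss)
        delta = phi[None, :] + th[:, None]  # (B, n)
        geom = np.cos(delta) ** 2 - load.r * np.sin(delta) ** 2
        rate = d1[None, :, None] * geom[:, None, :]  # (B, T, n)
        fv = np.where(rate >= 0.0, 1.0, np.clip(1.0 + sfp.k_v * rate / sfp.eps_rate_0, 0.0, 1.0))
        nh = n_hat[:, None, :]
        chi = nh * (alpha * fv + dmu)
        n_u = solve_unbound_fraction(np.broadcast_to(nh, chi.shape), chi, sfp)  # (B, T)
        eta = _eta_from_occupancy(nh, chi, n_u, sfp)  # (B, T, n)
        y = eta * nh  # bound packet density
        enth = m_pack + dphi * (y * nh * (m_b - alpha * fv)).sum(axis=2) + m_u * n_u
        if sfp.eta_max is None or not np.isfinite(sfp.eta_max):
            mix_b = dphi * (_xlogx(np.pi * y) / np.pi).sum(axis=2)
        else:
            thf = eta / sfp.eta_max
            mix_b = sfp.eta_max * dphi * (_xlogx(thf) + _xlogx(1.0 - thf)).sum(axis=2)
        mix_u = _xlogx(n_u)
        h_cyto = sfp.n_total * sfp.kT * (enth + mix_u + mix_b).mean(axis=1)  # (B,)
        out[sl] = h_cyto + _passive_from_axes(p, q, cp)
        if return_sf_profile:
            prof[sl] = y.mean(axis=1)

    if normalize:
        out /= abs(suspension_energy(sfp, cp))
    if return_sf_profile:
        return out, prof
    return out


def cycle_averaged_energy(
    m: Microstate,
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_time: int = 64,
    t_I: float = 0.0,
    normalize: bool = True,
) -> float:
    """Cycle-averaged normalized free energy ``H_hat = H_cell^(c) / |H_s|``."""
    if n_time < 8:
        raise ValueError("n_time must be >= 8")
    val = hhat_batch(
        np.array([m.a1_hat]),
        np.array([m.a2_hat]),
        np.array([m.theta]),
        load,
        sfp,
        cp,
        n_time=n_time,
        t_I=t_I,
        normalize=normalize,
    )
    return float(val[0])


def suspension_energy(sfp: SFParams, cp: CellParams) -> float:
    """Free energy ``H_s`` of the unadhered (suspended) cell.

    The suspended cell is a circle of radius ``suspension_radius_factor * R0``
    with no imposed strain rate.  Cached on ``cp.H_s``.
    """
    if cp.H_s is not None:
        return cp.H_s
    a = cp.suspension_radius_factor
    static = CyclicLoad(eps_amp=0.0, f=0.0, r=0.0)
    val = float(
        hhat_batch(np.array([a]), np.array([a]), np.array([0.0]), static, sfp, cp, n_time=8, normalize=False)[0]
    )
    cp.H_s = val
    return val
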