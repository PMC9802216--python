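"""Overdamped Langevin kinetics of cell morphology.

Cell shape evolves much more slowly than both the strain cycle and the
intracellular remodeling, so the morphology coefficients ``r = (h, k, l)``
follow an overdamped Langevin equation driven by the gradient of the
cycle-averaged free energy, with noise amplitude set by the inverse
homeostatic temperature ``beta_hat``:

    dr_i/dt_hat = -dH_hat/dr_i + sqrt(2 / beta_hat) dW_i

in the nondimensional time ``t_hat = t |H_s| / gamma`` (``gamma`` is the
morphological damping coefficient).  The stationary law of this dynamics is
the homeostatic ensemble ``P_eq ∝ exp(-beta_hat H_hat)``, which is used as
a self-consistency check (:func:`stationarity_check`).

The integrator is Euler-Maruyama with reject-and-resample of noise for
proposals that leave the valid-ellipse region.  Rigid-body rotation is
tracked along each path by unwrapping the principal-axis angle with a
nearest-axis rule, which follows a material axis smoothly through aspect
ratio 1 crossings (where the major/minor labels swap without any physical
rotation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from homeocell.mechanics import (
    CellParams,
    CyclicLoad,
    _passive_from_axes,
    geometry_from_coeffs_batch,
    hhat_batch,
    suspension_energy,
)
from homeocell.sf import SFParams

__all__ = [
    "LangevinSettings",
    "Trajectory",
    "TrajectoryEnsemble",
    "AnalyticEnergy",
    "CellEnergyLandscape",
    "TabulatedEnergy",
    "drift",
    "langevin_step",
    "run_trajectory",
    "run_ensemble",
    "suspension_initial",
    "equilibrated_initial",
    "order_parameter",
    "mode_fraction",
    "stationarity_check",
]


@dataclass
class LangevinSettings:
    """Integrator settings for the nondimensional Langevin dynamics."""

    dt_hat: float = 1e-3
    t_end_hat: float = 100.0
    n_traj: int = 200
    seed: int = 0
    gamma_over_Hs: float = 500.0  # seconds; maps t_hat to wall-clock time
    fd_step: float = 1e-4
    record_stride: int = 50  # integration steps between recorded samples

    def __post_init__(self) -> None:
        if not self.dt_hat > 0:
            raise ValueError("dt_hat must be positive")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


# ---------------------------------------------------------------------------
# Energy models


class AnalyticEnergy:
    """Plug-in energy landscape from a callable ``r -> H_hat``.

    Used for fixtures with closed-form stationary laws (quadratic wells).
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], valid_fn=None):
        self._fn = fn
        self._valid = valid_fn

    def hhat(self, r: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(np.asarray(r, dtype=float)), dtype=float)

    def valid(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self._valid is None:
            return np.ones(r.shape[:-1], dtype=bool)
        return self._valid(r)


class CellEnergyLandscape:
    """Direct cycle-averaged cell energy as a function of ``(h, k, l)``."""

    def __init__(
        self,
        load: CyclicLoad,
        sfp: SFParams,
        cp: CellParams,
        n_time: int = 32,
        a_min: float = 0.3,
        a_max: float = 4.0,
    ):
        self.load, self.sfp, self.cp = load, sfp, cp
        self.n_time = n_time
        self.a_min, self.a_max = a_min, a_max

    def valid(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        a1, a2, _, ok = geometry_from_coeffs_batch(r)
        return ok & (a1 <= self.a_max) & (a2 >= self.a_min)

    def hhat(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        shape = r.shape[:-1]
        a1, a2, theta, ok = geometry_from_coeffs_batch(r.reshape(-1, 3))
        out = np.full(a1.shape, np.inf)
        if ok.any():
            out[ok] = hhat_batch(
                a1[ok], a2[ok], theta[ok], self.load, self.sfp, self.cp, n_time=self.n_time
            )
        return out.reshape(shape)


class TabulatedEnergy:
    """Interpolated cell energy on an (a1, a2, theta) grid.

    The Langevin runs take millions of energy evaluations.  Only the
    cycle-averaged cytoskeletal part is tabulated (it is smooth in the
    semi-axes and orientation, so trilinear interpolation reproduces it to
    well below the thermal scale ``1/beta_hat``); the passive part, whose
    stiffening walls interpolate poorly, is added analytically at query
    time.
    """

    def __init__(self, a_grid, theta_grid, cyto_values, sfp, cp, a_min, a_max):
        self.sfp, self.cp = sfp, cp
        self.a_min, self.a_max = a_min, a_max
        self._h_s = abs(suspension_energy(sfp, cp))
        self._interp = RegularGridInterpolator(
            (a_grid, a_grid, theta_grid), cyto_values, method="linear",
            bounds_error=False, fill_value=np.inf,
        )

    @classmethod
    def build(
        cls,
        load: CyclicLoad,
        sfp: SFParams,
        cp: CellParams,
        a_min: float = 0.3,
        a_max: float = 4.0,
        n_axis: int = 56,
        n_theta: int = 29,
        n_time: int = 24,
    ) -> "TabulatedEnergy":
        # pad the axis range slightly so states at the validity boundary
        # still interpolate rather than extrapolate
        pad = 0.02 * (a_max - a_min)
        a_grid = np.linspace(a_min - pad, a_max + pad, n_axis)
        theta_grid = np.linspace(0.0, np.pi, n_theta)  # inclusive; H(pi) = H(0)
        aa1, aa2, tt = np.meshgrid(a_grid, a_grid, theta_grid, indexing="ij")
        h_s = abs(suspension_energy(sfp, cp))
        vals = hhat_batch(
            aa1.ravel(), aa2.ravel(), tt.ravel(), load, sfp, cp, n_time=n_time
        ).reshape(aa1.shape)
        vals -= _passive_from_axes(aa1, aa2, cp) / h_s
        return cls(a_grid, theta_grid, vals, sfp, cp, a_min, a_max)

    def valid(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        a1, a2, _, ok = geometry_from_coeffs_batch(r)
        return ok & (a1 <= self.a_max) & (a2 >= self.a_min)

    def hhat(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        a1, a2, theta, ok = geometry_from_coeffs_batch(r)
        pts = np.stack([a1, a2, theta], axis=-1)
        cyto = self._interp(pts)
        passive = _passive_from_axes(a1, a2, self.cp) / self._h_s
        return np.where(ok, cyto + passive, np.inf)


# ---------------------------------------------------------------------------
# Dynamics


def drift(r, energy, fd_step: float = 1e-4, return_flags: bool = False):
    """Drift ``-dH_hat/dr`` by central finite differences.

    Where a stencil point leaves the valid region the difference falls back
    to one-sided (flagged in the optional second return value).
    """
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    r2 = np.atleast_2d(r)
    n = r2.shape[0]
    grad = np.empty_like(r2)
    flags = np.zeros((n, 3), dtype=bool)
    h0 = energy.hhat(r2)
    for i in range(3):
        e = np.zeros(3)
        e[i] = fd_step
        rp, rm = r2 + e, r2 - e
        okp, okm = energy.valid(rp), energy.valid(rm)
        hp = np.where(okp, energy.hhat(np.where(okp[:, None], rp, r2)), np.nan)
        hm = np.where(okm, energy.hhat(np.where(okm[:, None], rm, r2)), np.nan)
        central = (hp - hm) / (2.0 * fd_step)
        fwd = (hp - h0) / fd_step
        bwd = (h0 - hm) / fd_step
        g = np.where(okp & okm, central, np.where(okp, fwd, np.where(okm, bwd, 0.0)))
        flags[:, i] = ~(okp & okm)
        grad[:, i] = g
    d = -grad
    if single:
        d, flags = d[0], flags[0]
    return (d, flags) if return_flags else d


def langevin_step(
    r: np.ndarray,
    energy,
    beta_hat: float,
    dt_hat: float,
    rng: np.random.Generator,
    fd_step: float = 1e-4,
    max_reject: int = 100,
) -> np.ndarray:
    """One Euler-Maruyama step; invalid proposals reject-and-resample noise."""
    r = np.asarray(r, dtype=float)
    d = drift(r, energy, fd_step)
    amp = math.sqrt(2.0 * dt_hat / beta_hat) if np.isfinite(beta_hat) else 0.0
    for _ in range(max_reject):
        prop = r + dt_hat * d + amp * rng.standard_normal(3)
        if bool(energy.valid(prop[None, :])[0]):
            return prop
        if amp == 0.0:
            return r
    raise RuntimeError(f"step rejected {max_reject} times; reduce dt_hat")


def _theta_increment(theta_new: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Nearest-principal-axis angle increment, mapped to (-pi/4, pi/4].

    The principal directions form a frame with period pi/2; tracking the
    nearest member follows one material axis continuously through both
    label swaps at aspect ratio 1 and the theta wrap at pi.
    """
    d = np.mod(theta_new - psi + np.pi / 4.0, np.pi / 2.0) - np.pi / 4.0
    return np.where(d == -np.pi / 4.0, np.pi / 4.0, d)


@dataclass
class Trajectory:
    """One recorded Langevin path."""

    times: np.ndarray  # t_hat at the recorded samples
    states: np.ndarray  # (n_rec, 3) coefficients (h, k, l)
    theta_r: np.ndarray  # accumulated rigid rotation, unbounded

    @property
    def theta_r_aux(self) -> np.ndarray:
        """Auxiliary rotation folded to [0, pi)."""
        return np.mod(self.theta_r, np.pi)

    def geometry(self):
        a1, a2, theta, _ = geometry_from_coeffs_batch(self.states)
        return a1, a2, theta


@dataclass
class TrajectoryEnsemble:
    """Seeded ensemble of Langevin paths with per-slice observables."""

    times: np.ndarray  # (n_rec,)
    states: np.ndarray  # (n_traj, n_rec, 3)
    theta_r: np.ndarray  # (n_traj, n_rec)
    meta: dict = field(default_factory=dict)

    @property
    def n_traj(self) -> int:
        return self.states.shape[0]

    def slice_index(self, t_hat: float) -> int:
        return int(np.argmin(np.abs(self.times - t_hat)))

    def geometry_at(self, t_hat: float):
        idx = self.slice_index(t_hat)
        a1, a2, theta, _ = geometry_from_coeffs_batch(self.states[:, idx, :])
        return a1, a2, theta

    def theta_r_aux_at(self, t_hat: float) -> np.ndarray:
        return np.mod(self.theta_r[:, self.slice_index(t_hat)], np.pi)


def _substreams(seed: int, n: int):
    return [np.random.Generator(np.random.Philox(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_trajectory(
    initial,
    settings: LangevinSettings,
    energy,
    beta_hat: float,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Integrate one seeded path; wrapper over the vectorized ensemble driver."""
    if hasattr(initial, "h"):
        r0 = np.array([initial.h, initial.k, initial.l], dtype=float)
    else:
        r0 = np.asarray(initial, dtype=float)
    ens = run_ensemble(r0[None, :], settings, energy, beta_hat, n_traj=1)
    return Trajectory(times=ens.times, states=ens.states[0], theta_r=ens.theta_r[0])


def run_ensemble(
    initial_states: np.ndarray,
    settings: LangevinSettings,
    energy,
    beta_hat: float,
    n_traj: int | None = None,
    block: int = 1000,
) -> TrajectoryEnsemble:
    """Vectorized Euler-Maruyama integration of many trajectories.

    ``initial_states`` is an ``(n, 3)`` array of coefficients (a single row
    is broadcast to ``settings.n_traj`` paths).  Each trajectory consumes
    noise from its own counter-based (Philox) substream of the base seed, so
    results are reproducible and independent of the block size.
    """
    r = np.atleast_2d(np.asarray(initial_states, dtype=float)).copy()
    n = n_traj if n_traj is not None else settings.n_traj
    if r.shape[0] == 1 and n > 1:
        r = np.repeat(r, n, axis=0)
    if r.shape[0] != n:
        raise ValueError("initial_states rows must match n_traj")
    if not np.all(energy.valid(r)):
        raise ValueError("invalid initial state(s)")

    dt = settings.dt_hat
    n_steps = int(round(settings.t_end_hat / dt))
    stride = settings.record_stride
    n_rec = n_steps // stride + 1
    gens = _substreams(settings.seed, n)
    amp = math.sqrt(2.0 * dt / beta_hat) if np.isfinite(beta_hat) else 0.0

    states = np.empty((n, n_rec, 3))
    theta_r = np.empty((n, n_rec))
    _, _, th, _ = geometry_from_coeffs_batch(r)
    psi = th.copy()  # tracked material-axis angle, unbounded
    rot = np.zeros(n)
    states[:, 0, :] = r
    theta_r[:, 0] = 0.0

    step_idx = 0
    rec_idx = 1
    while step_idx < n_steps:
        nb = min(block, n_steps - step_idx)
        noise = np.empty((n, nb, 3))
        for j, g in enumerate(gens):
            noise[j] = g.standard_normal((nb, 3))
        for s in range(nb):
            d = drift(r, energy, settings.fd_step)
            prop = r + dt * d + amp * noise[:, s, :]
            bad = ~energy.valid(prop)
            tries = 0
            while bad.any():
                tries += 1
                if tries > 100:
                    raise RuntimeError("step rejected 100 times; reduce dt_hat")
                for j in np.nonzero(bad)[0]:
                    prop[j] = r[j] + dt * d[j] + amp * gens[j].standard_normal(3)
                bad = ~energy.valid(prop)
            r = prop
            _, _, th, _ = geometry_from_coeffs_batch(r)
            inc = _theta_increment(th, psi)
            psi = psi + inc
            rot += inc
            step_idx += 1
            if step_idx % stride == 0:
                states[:, rec_idx, :] = r
                theta_r[:, rec_idx] = rot
                rec_idx += 1

    times = np.arange(n_rec) * stride * dt
    return TrajectoryEnsemble(
        times=times,
        states=states,
        theta_r=theta_r,
        meta={"seed": settings.seed, "dt_hat": dt, "beta_hat": beta_hat, "n_traj": n},
    )


# ---------------------------------------------------------------------------
# Initial conditions


def suspension_initial(cp: CellParams) -> np.ndarray:
    """Coefficients of the deterministic suspended state (circle, 0.96 R0)."""
    a = cp.suspension_radius_factor
    return np.array([1.0 / a**2, 0.0, 1.0 / a**2])


def equilibrated_initial(
    static_result,
    theta0: float,
    n_morph: int = 50,
    n_rep: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Initial states equilibrated without load, all oriented at ``theta0``.

    Draws ``n_morph`` morphology couplets ``(A_hat, As)`` from a solved
    static (f = 0) ensemble's equilibrium weights, sets every orientation to
    ``theta0``, and repeats each morphology ``n_rep`` times.
    """
    from homeocell.mechanics import coeffs_from_geometry

    rng = np.random.default_rng(seed)
    s = static_result.samples
    idx = rng.choice(len(s), size=n_morph, p=static_result.weights)
    rows = []
    for i in idx:
        hkl = coeffs_from_geometry(s.a1[i], s.a2[i], theta0)
        rows.extend([hkl] * n_rep)
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Observables


def order_parameter(ens: TrajectoryEnsemble, t_hat: float) -> float:
    """Orientational order parameter ``S = <cos 2 theta>`` at time ``t_hat``."""
    _, _, theta = ens.geometry_at(t_hat)
    return float(np.mean(np.cos(2.0 * theta)))


def mode_fraction(
    ens: TrajectoryEnsemble,
    t_hat: float,
    window=(np.deg2rad(40.0), np.deg2rad(140.0)),
):
    """Strain-mode vs rotation-mode attribution of cyclic strain avoidance.

    For an ensemble started at ``theta0 = 0``, reorientation by rigid
    rotation moves the auxiliary rotation ``theta_r_aux`` into the window
    around 90 deg, while reorientation by pure straining (axis swap) leaves
    it near 0/180 deg.  Returns ``(P_theta, P_aux, strain_mode_fraction)``:
    the fraction of cell orientations in the window, the fraction of
    auxiliary rotations in the window, and their difference.
    """
    lo, hi = window
    _, _, theta = ens.geometry_at(t_hat)
    aux = ens.theta_r_aux_at(t_hat)
    p_theta = float(np.mean((theta >= lo) & (theta <= hi)))
    p_aux = float(np.mean((aux >= lo) & (aux <= hi)))
    return p_theta, p_aux, p_theta - p_aux


def stationarity_check(
    ens: TrajectoryEnsemble,
    energy,
    beta_hat: float,
    edges: Sequence[np.ndarray],
    burn_in: float = 0.0,
    threshold: float = 0.05,
) -> dict:
    """Compare long-run Langevin occupancy with ``exp(-beta_hat H_hat)``.

    Histograms all recorded states with ``t_hat >= burn_in`` on the given
    per-coordinate bin ``edges`` and compares against the Boltzmann
    reference evaluated at the bin centers (restricted to valid bins).
    Reports the KL divergence (empirical || reference) and a chi-square
    statistic per occupied bin, with pass/fail at ``threshold`` on the KL.
    """
    keep = ens.times >= burn_in
    pts = ens.states[:, keep, :].reshape(-1, 3)
    hist, _ = np.histogramdd(pts, bins=edges)
    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    cc = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1)
    flat = cc.reshape(-1, 3)
    valid = energy.valid(flat)
    h = np.where(valid, energy.hhat(flat), np.inf)
    logw = -beta_hat * h
    logw -= logw[valid].max()
    ref = np.where(valid, np.exp(logw), 0.0)
    ref /= ref.sum()
    emp = hist.reshape(-1)
    n_tot = emp.sum()
    emp = emp / n_tot
    occ = emp > 0
    kl = float(np.sum(emp[occ] * np.log(emp[occ] / np.maximum(ref[occ], 1e-300))))
    exp_counts = ref * n_tot
    mask = exp_counts > 5
    chi2 = float(np.sum((emp[mask] * n_tot - exp_counts[mask]) ** 2 / exp_counts[mask]))
    return {
        "kl": kl,
        "chi2": chi2,
        "n_bins_occupied": int(occ.sum()),
        "n_samples": int(n_tot),
        "passed": bool(kl < threshold),
        "threshold": threshold,
    }
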