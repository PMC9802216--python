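"""The cyclic homeostatic ensemble over elliptical cell morphologies.

Adherent cells exchange high-energy nutrients with the surrounding bath,
which drives fluctuations of cell shape far larger than thermal ones.  The
homeostatic ensemble is the maximum-entropy distribution over morphological
microstates subject to the constraint that the ensemble-averaged cell free
energy equals the suspended-cell free energy ``H_s`` (the cell's fixed
energetic budget).  The result is a Boltzmann-like distribution
``P_eq ∝ exp(-beta_hat * H_hat)`` where ``H_hat = H_cell / |H_s|`` is the
cycle-averaged normalized free energy and the "inverse homeostatic
temperature" ``beta_hat = beta |H_s|`` is the Lagrange multiplier solved
from the constraint ``<H_hat> = sign(H_s)``.

Phase space is sampled uniformly in the ellipse coefficients ``(h, k, l)``
with rejection of invalid or out-of-range shapes; reported densities over
``(theta, A_hat, As)`` therefore carry the induced Jacobian implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from homeocell.mechanics import (
    CellParams,
    CyclicLoad,
    geometry_from_coeffs_batch,
    hhat_batch,
    suspension_energy,
)
from homeocell.sf import SFParams, phi_grid

__all__ = [
    "PhaseSpaceBounds",
    "AngularDensity",
    "EnsembleResult",
    "sample_phase_space",
    "equilibrium_weights",
    "solve_beta",
    "solve_ensemble",
    "morphology_densities",
    "sf_global_distribution",
    "circular_variance",
    "free_energy_landscape",
]


@dataclass(frozen=True)
class PhaseSpaceBounds:
    """Axis bounds defining the sampled region of morphological phase space."""

    a_min: float = 0.3
    a_max: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.a_min < self.a_max):
            raise ValueError("require 0 < a_min < a_max")

    @property
    def box(self):
        """The (h, k, l) box guaranteed to contain all admissible ellipses."""
        lam_lo = 1.0 / self.a_max**2
        lam_hi = 1.0 / self.a_min**2
        span = lam_hi - lam_lo
        return (lam_lo, lam_hi), (-span, span), (lam_lo, lam_hi)


@dataclass
class PhaseSample:
    """Accepted morphological microstates from uniform (h, k, l) sampling."""

    hkl: np.ndarray  # (n, 3)
    a1: np.ndarray
    a2: np.ndarray
    theta: np.ndarray
    n_proposed: int
    n_accepted: int  # before truncation to the requested sample count
    seed: int
    bounds: PhaseSpaceBounds

    def __len__(self) -> int:
        return self.hkl.shape[0]


@dataclass
class AngularDensity:
    """Normalized angular density on a uniform periodic grid.

    ``grid`` holds bin-center angles (period pi) and ``density`` nonnegative
    values with unit integral under the periodic trapezoid measure.
    """

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.density < -1e-12):
            raise ValueError("density must be nonnegative")

    @property
    def spacing(self) -> float:
        return float(np.pi / self.grid.size)

    def integral(self) -> float:
        return float(np.sum(self.density) * self.spacing)


@dataclass
class EnsembleResult:
    """Solved cyclic homeostatic ensemble."""

    samples: PhaseSample
    energies: np.ndarray  # H_hat per sample
    beta_hat: float
    weights: np.ndarray
    sf_profiles: np.ndarray | None = None  # cycle-averaged eta*n per (sample, phi)
    meta: dict = field(default_factory=dict)

    def homeostatic_residual(self, target: float = -1.0) -> float:
        return float(np.sum(self.weights * self.energies) - target)


def sample_phase_space(
    bounds: PhaseSpaceBounds,
    n_samples: int,
    seed: int,
    max_batches: int = 1000,
) -> PhaseSample:
    """Uniform rejection sampling of valid ellipses in (h, k, l).

    Draws uniformly in the bounding box, rejecting degenerate forms
    (``4hl - k^2 <= 0``) and shapes whose axes fall outside
    ``[a_min, a_max]``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    (h_lo, h_hi), (k_lo, k_hi), (l_lo, l_hi) = bounds.box
    kept = []
    n_prop = 0
    n_kept = 0
    for _ in range(max_batches):
        m = max(4 * n_samples, 1000)
        draw = rng.uniform(
            low=[h_lo, k_lo, l_lo], high=[h_hi, k_hi, l_hi], size=(m, 3)
        )
        n_prop += m
        a1, a2, _, valid = geometry_from_coeffs_batch(draw)
        ok = valid & (a1 <= bounds.a_max) & (a2 >= bounds.a_min)
        kept.append(draw[ok])
        n_kept += int(ok.sum())
        if n_kept >= n_samples:
            break
    if n_kept < n_samples:
        raise ValueError(
            f"bounds error: only {n_kept} valid samples in {n_prop} proposals"
        )
    hkl = np.concatenate(kept, axis=0)[:n_samples]
    a1, a2, theta, _ = geometry_from_coeffs_batch(hkl)
    return PhaseSample(
        hkl=hkl, a1=a1, a2=a2, theta=theta, n_proposed=n_prop, n_accepted=n_kept,
        seed=seed, bounds=bounds,
    )


def equilibrium_weights(energies: np.ndarray, beta_hat: float) -> np.ndarray:
    """Normalized Boltzmann weights ``w ∝ exp(-beta_hat * H_hat)``.

    Computed with a max-shift so arbitrarily deep landscapes cannot
    overflow.
    """
    e = np.asarray(energies, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    x = -beta_hat * e
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def _mean_energy(energies: np.ndarray, beta_hat: float) -> float:
    x = -beta_hat * energies
    lz = logsumexp(x)
    return float(np.exp(logsumexp(x, b=energies - energies.min()) - lz)) + energies.min()


def solve_beta(
    energies: np.ndarray,
    target: float = -1.0,
    beta_max: float = 1e6,
    tol: float = 1e-12,
) -> float:
    """Solve the homeostatic constraint ``<H_hat>_beta = target`` for beta_hat.

    ``<H_hat>_beta`` is strictly decreasing in beta (it is minus the
    variance times d/dbeta), so the root is unique; it exists iff
    ``min(H_hat) < target < mean(H_hat)`` for nonnegative beta.
    """
    e = np.asarray(energies, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    e_min, e_max = float(e.min()), float(e.max())
    if e_min == e_max:
        raise ValueError(
            f"degenerate constraint: all energies equal {e_min}; any beta satisfies it"
        )
    if not (e_min < target < e_max):
        raise ValueError(
            f"infeasible constraint: target {target} outside attainable "
            f"range ({e_min}, {e_max})"
        )

    def g(b: float) -> float:
        return _mean_energy(e, b) - target

    lo, hi = 0.0, 1.0
    g_lo = g(lo)
    if g_lo <= 0.0:
        # mean already below target: beta < 0 branch (possible for targets
        # above the uniform mean); bracket downward.
        lo, hi = -1.0, 0.0
        while g(lo) < 0.0:
            lo *= 2.0
            if lo < -beta_max:
                raise ValueError("failed to bracket beta root")
    else:
        while g(hi) > 0.0:
            hi *= 2.0
            if hi > beta_max:
                raise ValueError("failed to bracket beta root")
    beta = brentq(g, lo, hi, xtol=tol, rtol=8.9e-16)
    resid = g(beta)
    if abs(resid) > 1e-10:
        raise RuntimeError(f"beta solve residual {resid:.2e} exceeds tolerance")
    return float(beta)


def solve_ensemble(
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_samples: int = 20000,
    seed: int = 0,
    bounds: PhaseSpaceBounds | None = None,
    n_time: int = 64,
    keep_sf_profiles: bool = True,
) -> EnsembleResult:
    """Sample phase space, evaluate cycle-averaged energies, solve beta.

    The homeostatic target is ``sign(H_s)`` on the normalized energy scale
    (``-1`` for the calibrated defaults, where the suspended cell has
    negative free energy).
    """
    bounds = bounds or PhaseSpaceBounds()
    sample = sample_phase_space(bounds, n_samples, seed)
    h_s = suspension_energy(sfp, cp)
    target = float(np.sign(h_s))
    res = hhat_batch(
        sample.a1,
        sample.a2,
        sample.theta,
        load,
        sfp,
        cp,
        n_time=n_time,
        return_sf_profile=keep_sf_profiles,
    )
    energies, profiles = res if keep_sf_profiles else (res, None)
    beta_hat = solve_beta(energies, target=target)
    weights = equilibrium_weights(energies, beta_hat)
    return EnsembleResult(
        samples=sample,
        energies=energies,
        beta_hat=beta_hat,
        weights=weights,
        sf_profiles=profiles,
        meta={
            "n_samples": n_samples,
            "seed": seed,
            "n_time": n_time,
            "target": target,
            "H_s": h_s,
            "load": {"eps_amp": load.eps_amp, "f": load.f, "r": load.r},
        },
    )


def _weighted_density(values: np.ndarray, weights: np.ndarray, edges: np.ndarray):
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    width = np.diff(edges)
    dens = hist / (hist * width).sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def morphology_densities(
    res: EnsembleResult,
    theta_bins: int = 36,
    scalar_bins: int = 40,
):
    """Weighted probability densities of theta, A_hat, and As.

    Returns a dict with keys ``"theta"`` (an :class:`AngularDensity` on
    ``[0, pi)``), ``"A_hat"``, and ``"As"`` (tuples of bin centers and
    density values).
    """
    s = res.samples
    w = res.weights
    edges_t = np.linspace(0.0, np.pi, theta_bins + 1)
    centers_t, dens_t = _weighted_density(s.theta, w, edges_t)
    a_hat = s.a1 * s.a2
    asp = s.a1 / s.a2
    out = {"theta": AngularDensity(grid=centers_t, density=dens_t)}
    for name, vals in (("A_hat", a_hat), ("As", asp)):
        edges = np.linspace(vals.min(), vals.max(), scalar_bins + 1)
        out[name] = _weighted_density(vals, w, edges)
    return out


def _periodic_shift(profiles: np.ndarray, shifts: np.ndarray, n: int) -> np.ndarray:
    """Resample per-sample angular profiles y(phi) onto the global grid.

    ``xi(delta) = y(phi = delta - theta)``: linear interpolation on the
    periodic grid, vectorized over samples.
    """
    # fractional bin offset of each sample's theta
    pos = shifts / (np.pi / n)
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    idx = (np.arange(n)[None, :] - i0[:, None]) % n
    idx_m1 = (idx - 1) % n
    return (1.0 - frac[:, None]) * profiles[np.arange(len(shifts))[:, None], idx] + frac[
        :, None
    ] * profiles[np.arange(len(shifts))[:, None], idx_m1]


def sf_global_distribution(res: EnsembleResult):
    """Ensemble-averaged SF angular distributions ``xi_hat`` and ``rho_hat``.

    ``rho(phi)`` averages the cycle-averaged bound-packet density at angle
    ``phi`` relative to each cell's major axis; ``xi(delta)`` first rotates
    each cell's profile to the global angle ``delta = phi + theta``.  Both
    are returned normalized to unit integral.
    """
    if res.sf_profiles is None:
        raise ValueError("ensemble was solved without SF profiles")
    prof = res.sf_profiles
    n = prof.shape[1]
    w = res.weights
    rho = w @ prof
    xi = w @ _periodic_shift(prof, res.samples.theta, n)
    grid = phi_grid(n)
    dphi = np.pi / n
    return (
        AngularDensity(grid=grid, density=xi / (xi.sum() * dphi)),
        AngularDensity(grid=grid, density=rho / (rho.sum() * dphi)),
    )


def circular_variance(d: AngularDensity) -> float:
    """Circular variance ``CV = 1 - |first even circular moment|``.

    1 for an isotropic density, 0 for a perfectly aligned one.  The input
    must be normalized to unit integral.
    """
    if abs(d.integral() - 1.0) > 1e-6:
        raise ValueError(f"density not normalized: integral = {d.integral():.6f}")
    c = float(np.sum(d.density * np.cos(2.0 * d.grid)) * d.spacing)
    s = float(np.sum(d.density * np.sin(2.0 * d.grid)) * d.spacing)
    return 1.0 - float(np.hypot(c, s))


def free_energy_landscape(
    theta: float,
    a1_grid: np.ndarray,
    a2_grid: np.ndarray,
    load: CyclicLoad,
    sfp: SFParams,
    cp: CellParams,
    n_time: int = 64,
):
    """Normalized free-energy landscape over the (a1_hat, a2_hat) grid.

    Evaluates the cycle-averaged ``H_hat`` at fixed orientation ``theta`` on
    the tensor grid and returns ``(H_hat, (a1*, a2*))`` where the argmin is
    restricted to ``a1 >= a2`` (the major axis is the one at ``theta``).
    """
    aa1, aa2 = np.meshgrid(a1_grid, a2_grid, indexing="ij")
    h = hhat_batch(
        aa1.ravel(), aa2.ravel(), np.full(aa1.size, theta), load, sfp, cp, n_time=n_time
    ).reshape(aa1.shape)
    masked = np.where(aa1 >= aa2, h, np.inf)
    i, j = np.unravel_index(np.argmin(masked), masked.shape)
    return h, (float(a1_grid[i]), float(a2_grid[j]))
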