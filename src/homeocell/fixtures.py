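"""Deterministic toy objects used by the test suite and demos.

Each fixture is a small, analytically tractable object with a closed-form
property that the corresponding module must reproduce:

* ``two_state_ensemble`` — energies (-1, -0.5) whose homeostatic constraint
  at target -0.8 has the exact solution ``beta_hat = 2 ln(1.5)``;
* ``quadratic_landscape`` — a separable quadratic energy over (h, k, l)
  whose Langevin stationary law is Gaussian with variance
  ``1 / (2 beta_hat a_i)`` per coordinate (Ornstein-Uhlenbeck);
* ``synthetic_rotation_paths`` — scripted trajectories with known rigid
  rotation, exercising the axis-tracking rules (pure rotation vs pure
  shape-swap reorientation);
* ``isotropic_sf_state`` — an angularly uniform stress-fiber state with the
  unbound fraction known in closed form in the dilute limit.
"""

from __future__ import annotations

import math

import numpy as np

from homeocell.kinetics import AnalyticEnergy
from homeocell.mechanics import coeffs_from_geometry
from homeocell.sf import SFParams, phi_grid, sf_steady_state

__all__ = ["make_fixtures"]


def _two_state_ensemble(seed: int) -> dict:
    return {
        "energies": np.array([-1.0, -0.5]),
        "target": -0.8,
        "beta_exact": 2.0 * math.log(1.5),
        "weights_exact": np.array([0.6, 0.4]),
    }


def _quadratic_landscape(seed: int, a=(1.0, 1.0, 1.0), center=(1.0, 0.0, 1.0)) -> dict:
    a = np.asarray(a, dtype=float)
    center = np.asarray(center, dtype=float)

    def hhat(r):
        return np.sum(a * (r - center) ** 2, axis=-1)

    def grad(r):
        return 2.0 * a * (r - center)

    return {
        "energy": AnalyticEnergy(hhat),
        "grad_exact": grad,
        "coeffs": a,
        "center": center,
        "stationary_var": lambda beta_hat: 1.0 / (2.0 * beta_hat * a),
    }


def _synthetic_rotation_paths(seed: int, n_steps: int = 200) -> dict:
    """Scripted (a1, a2, theta) paths with known accumulated rotation."""
    t = np.linspace(0.0, 1.0, n_steps)
    # pure rigid rotation 0 -> 90 deg at fixed shape: theta_r ends at pi/2
    rot = np.array([coeffs_from_geometry(2.0, 1.0, th) for th in t * np.pi / 2])
    # pure strain-mode swap: axes exchange through As = 1, no rotation
    a1 = 2.0 - t * 1.0  # 2 -> 1
    a2 = 1.0 + t * 1.0  # 1 -> 2
    swap = np.array(
        [
            coeffs_from_geometry(max(x, y), min(x, y), 0.0 if x >= y else np.pi / 2)
            for x, y in zip(a1, a2)
        ]
    )
    return {
        "rotation_states": rot,
        "rotation_theta_r_final": np.pi / 2,
        "swap_states": swap,
        "swap_theta_r_final": 0.0,
        "times": t,
    }


def _isotropic_sf_state(seed: int) -> dict:
    """Uniform state in the dilute limit: chi == 0 gives N_u = 1/2 exactly."""
    # alpha = 1, dmu = (mu_u0 - mu_b0)/kT = -1, n_hat = 1 at eps = eps_ss,
    # so chi = n_hat * (alpha + dmu) = 0 on every bin
    p = SFParams(sigma_max=1.0, mu_b0=1.0, mu_u0=0.0, omega=1.0, kT=1.0, eta_max=None)
    phi = phi_grid(p.n_angular)
    state = sf_steady_state(np.full_like(phi, p.eps_ss), np.zeros_like(phi), p)
    return {"params": p, "state": state, "N_u_exact": 0.5, "eta_exact": 1.0 / (2 * np.pi)}


_KINDS = {
    "two_state_ensemble": _two_state_ensemble,
    "quadratic_landscape": _quadratic_landscape,
    "synthetic_rotation_paths": _synthetic_rotation_paths,
    "isotropic_sf_state": _isotropic_sf_state,
}


def make_fixtures(kind: str, seed: int = 0) -> dict:
    """Build the named fixture bundle (deterministic for a given seed)."""
    try:
        builder = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    return builder(seed)
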