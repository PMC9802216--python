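# Model and methods

## The physical picture

Adherent cells on stretched elastic substrates reorganize dramatically:
under uniaxial cyclic strain at physiological frequencies (~1 Hz) both the
acto-myosin stress fibers (SFs) and the cell bodies orient away from the
straining direction ("cyclic strain avoidance"), and the distributions of
cell area and aspect ratio narrow.  `homeocell` implements a statistical
mechanics treatment of this phenomenon: the cell is an open system driven by
nutrient exchange, whose shape fluctuations are far larger than thermal, and
whose stationary statistics follow from maximizing morphological entropy
subject to a *homeostatic constraint* — the ensemble-averaged free energy of
the adhered cell equals that of the cell in suspension,

    sum_c P_eq(c) H_cell(c) = H_s,     P_eq(c) ∝ exp(-beta * H_cell(c)).

`beta` is the Lagrange multiplier of the constraint (an inverse
"homeostatic temperature"); we report the nondimensional
`beta_hat = beta * |H_s|`.  Working on a stiff substrate means the imposed
strain history transmits directly to the adhered cell and the substrate
elastic energy is the same constant for every morphology, so it cancels
from the ensemble.

A morphological microstate is a spatially uniform ellipse with normalized
semi-axes `(a1_hat, a2_hat) = (a1, a2)/R0` and orientation `theta`,
parameterized internally by the quadratic-form coefficients `(h, k, l)`
(`h x1^2 + k x1 x2 + l x2^2 = R0^2`), which span comparable ranges and are
the coordinates in which phase space is sampled and in which the Langevin
dynamics runs.

## Separation of timescales

Three timescales order the problem: intracellular remodeling (seconds), the
strain cycle (~1 s), and morphological evolution (minutes).  Hence (i) the
SF cytoskeleton is always in its *steady state* for the instantaneous
strain/strain-rate, (ii) the cell shape is effectively frozen over one
strain cycle, so the energy entering the ensemble is the *cycle average*
`H_cell^(c) = (1/T_p) ∫ H_cell(t) dt`, and (iii) morphology evolves on the
slow timescale, which is where the Langevin description lives.

## Free energy of a microstate

`H_cell(t) = H_cyto(t) + H_passive`.

### Stress-fiber free energy

SFs at angle `phi` from the major axis carry `n_hat(phi)` functional units
per packet, with the steady-state unit count following the fiber stretch,
`n_hat = lambda_f / (1 + eps_ss)`.  Fiber stretch uses the finite
homogeneous deformation of the ellipse (the reference direction is the
inverse image of `phi`); the fiber strain *rate* is the substrate rate
resolved onto the fiber's global direction `delta = phi + theta` — the cell
stays adhered within a cycle, so fibers co-cycle with the substrate.

Tension follows a Hill-type relation: lengthening or isometric fibers carry
the stall stress `sigma_max`; shortening fibers lose tension linearly with
rate, `f_v = max(0, 1 + k_v * rate / eps_rate_0)`, clipped to `[0, 1]`.

Bound and unbound SF protein packets exchange through a saturating
(Langmuir-type) isotherm with angular site capacity `eta_max`:

    eta_hat = eta_max * g / (1 + g),
    g = (N_u / (pi eta_max)) * exp(chi),
    chi = n_hat * (omega sigma + mu_u0 - mu_b0) / kT,

with the unbound fraction `N_u` solved from protein conservation
`N_u + ∫ eta_hat n_hat dphi = 1` (unique root in (0, 1]; safeguarded Newton,
residual < 1e-10; in the dilute limit `eta_max = None` the equation is
linear and solved in closed form).  The capacity matters: it produces the
flat-topped angular SF distributions seen in cells (circular variance ~0.6
rather than the sharply peaked Boltzmann profiles of an uncapped model).

The free energy combines enthalpy and ideal mixing entropy:

    H_cyto = n_total * [ ∫ eta n mu_b dphi + N_u mu_u
                         + kT ( N_u ln N_u + S_sites ) ],
    mu_b = mu_pack + n_hat (mu_b0 - omega sigma),
    mu_u = mu_pack + mu_u0,

where each *functional unit* contributes its reference potential and the
work of the tension it carries (hence the factor `n_hat` in `mu_b`), and
`mu_pack` is a reference potential per packet carried by both phases — it
cancels from the binding equilibrium and acts as the zero of the protein
free energy.  Because `beta_hat = beta |H_s|` is reported on the scale of
the suspension energy, this reference is *not* arbitrary: it is the single
parameter controlling the overall magnitude of `|H_s|` relative to the
landscape relief, and it is calibrated (once) against the reference
`beta_hat` values.  `S_sites` is the site-occupancy entropy
`eta_max ∫ [th ln th + (1 - th) ln(1 - th)] dphi`, `th = eta_hat/eta_max`.

Two features of this closure drive all predictions: polymerization
(spreading, elongation) lowers `H_cyto`, and contractile strain rates raise
it by de-tensioning fibers through the Hill relation.

### Passive elasticity

Cytoplasm (annulus out to `R0`) and nucleus (disc of radius `R_N`) deform
affinely with the cell.  Each region carries a 2D compressible Ogden-type
energy

    W = (2 mu / m^2) (x^m + x^-m - 2) + (kappa/2) |J - 1|^v,
    x = sqrt(lam1/lam2),  J = lam1 lam2,

with stiffening exponents `m = 10` (deviatoric) and `v = 4` (volumetric).
The strain stiffening is essential, not cosmetic: with a neo-Hookean law
(`m = 2`, `v = 2`) the SF polymerization gain and the shear cost are both
asymptotically linear in aspect ratio, the landscape has no robust interior
minimum, and the preferred shape runs away to the phase-space boundary.
Strong stiffening gives a flat-bottomed basin with steep walls, an interior
minimum at moderate elongation, and less stored elastic energy at the
minimum.  The nucleus is taken twice as stiff as the cytoplasm.

### Suspension state

The suspended cell is a circle of radius `0.96 R0` (slight contraction of
the stress-free state, area `A_hat = 0.9216`) with no imposed strain rate;
its free energy `H_s < 0` normalizes everything (`H_hat = H / |H_s|`,
target `<H_hat> = -1`).

## The cyclic ensemble pipeline

1. Sample `(h, k, l)` uniformly in the box guaranteed to contain all
   ellipses with axes in `[a_min, a_max] = [0.3, 4]`, rejecting degenerate
   forms and out-of-range shapes.  Reported densities over
   `(theta, A_hat, As)` therefore carry the induced Jacobian implicitly.
2. Evaluate the cycle-averaged normalized energy of every sample
   (trapezoid over one period; 64 nodes for cyclic runs — the Hill clip
   makes the integrand piecewise smooth, so the quadrature is second-order,
   not spectral; 8 nodes suffice for static runs).
3. Solve the homeostatic constraint for `beta_hat` by bracketed Brent
   iteration on the strictly decreasing map `beta -> <H_hat>_beta`
   (residual < 1e-10) and form overflow-safe Boltzmann weights.
4. Ensemble observables: weighted densities of `theta`, `A_hat`, `As`; the
   global SF distribution `xi_hat(delta)` (each cell's cycle-averaged
   bound-packet profile rotated to the lab frame) and the cell-frame
   distribution `rho_hat(phi)`; circular variances
   `CV = 1 - |first even circular moment|`.

Sample-size note: the reported observables use importance ratios whose
effective sample size collapses as the ensemble concentrates (at
`beta_hat ~ 15-25` under 1 Hz load, roughly 1 in 2000 uniform samples
carries weight).  The acceptance pipeline therefore uses 1e5 accepted
samples; at 2e4 the cyclic `beta_hat` estimate can wander by +-40% between
seeds.  All estimates remain unbiased; only their variance is at stake.

## Langevin kinetics

Morphology evolves by overdamped Langevin dynamics in `r = (h, k, l)`,

    dr_i/dt_hat = -dH_hat/dr_i + sqrt(2/beta_hat) dW_i,

in nondimensional time `t_hat = t |H_s| / gamma`; `gamma/|H_s| = 500 s`
maps simulations to wall-clock time.  The stationary law is exactly the
homeostatic ensemble (checked against closed-form Gaussian stationary
states on quadratic plug-in landscapes, and self-consistently on the cell
landscape).  Euler-Maruyama with `dt_hat = 1e-3`; proposals leaving the
valid-ellipse region reject and resample the noise (the boundary is rarely
visited at the calibrated `beta_hat`).  Each trajectory draws from its own
counter-based (Philox) substream, so ensembles are reproducible and
independent of vectorization blocking.

Long ensembles use a precomputed trilinear table over
`(a1_hat, a2_hat, theta)` (56 x 56 x 29 nodes, 24 cycle nodes) of the
*cytoskeletal* part only — the passive part, whose stiffening walls
interpolate poorly, is added analytically at query time.  The combined
error (max ~0.017, rms ~0.002 in `H_hat` units) is well below the thermal
scale `1/beta_hat ~ 0.06`; the direct evaluator remains available and is
used in the unit tests.

Rigid rotation `theta_r` is tracked by unwrapping the principal-axis frame:
at each step the increment is the nearest member of the frame orbit
`{theta + j pi/2}` relative to the tracked axis, mapped to
`(-pi/4, pi/4]`.  This follows one material axis smoothly through aspect
ratio 1 crossings, where the major/minor labels swap without physical
rotation (the swap is how "strain-mode" reorientation shows up: `theta`
changes by 90 deg while `theta_r` stays near 0).  The auxiliary angle
`theta_r_aux = theta_r mod pi` makes rotation- and strain-mode
reorientation directly comparable with the orientation density: the mass of
`p(theta_r_aux)` in a window around 90 deg measures the rotation-mode
share.

Initial conditions: "suspension" is the deterministic `0.96 R0` circle
(orientation undefined; reported as uniform); "equilibrated at theta0"
draws `(A_hat, As)` couplets from the solved static ensemble and sets every
orientation to `theta0` (50 morphologies, replicated).

## Reduced models

*Circular cell*: morphology frozen to a circle of radius `R0`; only the SF
distribution responds to the strain history.  This reproduces what
SF-remodeling-only models compute and quantifies how much of strain
avoidance survives without shape change (its `CV_circ ~ 0.9` at 1 Hz shows
SF remodeling alone produces far less alignment than observed).

*Rod*: one-dimensional cell with stretch `lam` and orientation `theta`,
same SF closure collapsed to a single direction plus a convex 1D stretch
energy `(mu_rod/2)(lam^2 + 2/lam - 3)` (stiffness calibrated so the static rod prefers a stretch comparable to the 2D model).  The homeostatic machinery on a
uniform `(lam, theta)` grid yields `p(theta)` whose modes sit at the
directions of vanishing cyclic strain rate, `theta = atan(1/sqrt(r))` and
its mirror — a geometric prediction insensitive to the energy details,
which is the point of the baseline.

## Parameters (reduced units)

Lengths are in units of `R0`, energies in units of `n_total * kT` (the
thermal scale of the total SF protein pool).  The defaults were calibrated
once, jointly, against the reference steady-state targets (landscape minima,
`beta_hat` pair, circular variances) and then frozen:

| parameter | default | meaning |
|---|---|---|
| `sigma_max * omega / kT` | 3.0 | stress-work gain per functional unit |
| `eps_rate_0` | 0.1 /s | Hill reference rate (transition ~0.03 Hz at 10% amplitude) |
| `k_v` | 10 | Hill rate sensitivity |
| `eps_ss` | 0.35 | intrinsic functional-unit strain |
| `mu_b0/kT` | -4.5 | per-unit bound reference potential |
| `mu_u0/kT` | -5.0 | unbound reference potential |
| `mu_pack/kT` | 4.758 | per-packet reference (sets the `|H_s|` scale) |
| `eta_max` | 1.5 | angular site capacity |
| `n_angular` | 36 | SF angular bins over (-pi/2, pi/2] |
| `mu_cyto, kappa_cyto` | 0.055, 3.5 | cytoplasm moduli (per unit reference area) |
| `mu_nuc, kappa_nuc` | 0.11, 7.0 | nucleus moduli |
| `m, v` | 10, 4 | stiffening exponents |
| `R_N` | 0.5 | nucleus radius |

## What the synthetic conditions do and do not show

All inputs are synthetic: the strain protocol is the ideal sinusoid
`eps1 = eps_mean + (eps_amp/2) sin(2 pi f t)`, `eps2 = -r eps1`, and cells
are ideal uniform ellipses.  Real data differ in ways the model ignores:
cells are not elliptical, SFs bundle discretely rather than forming smooth
angular densities, focal adhesions and substrate compliance are absent
(stiff limit), and intracellular kinetics are assumed instantaneously
equilibrated within each strain cycle.  Passing tests therefore validate
the statistical-mechanical machinery and its calibrated steady state, not
cell biology per se.

## Known limitations

* The constitutive closures above are calibrated stand-ins built around
  the two qualitative drivers (polymerization gain, rate de-tensioning);
  they reproduce most of the reference steady-state values but not all.  Within this closure family the within-cell SF distribution
  sharpens only moderately under load (the instantaneous-steady-state
  assumption restores transverse fibers during every tensile half-cycle),
  so the predicted cyclic `CV(rho_hat)` and `CV(xi_hat)` sit ~0.05-0.15
  above the reference values, and the 0.5 Hz and 1 Hz within-cell
  distributions nearly coincide (both frequencies are deep in the
  rate-saturated regime of the clipped Hill branch).
* The homeostatic `beta_hat` under cyclic load is an importance-sampling
  estimate with small effective sample size; quoted values need ~1e5
  uniform samples for stability.
* `f = 0.01-0.1 Hz` protocols sit near the Hill transition where the
  quadrature of the clipped integrand converges only at second order; use
  more cycle nodes there.
* Cycle-period ~ morphology-evolution timescale regimes are outside the
  model's assumptions.
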