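"""Bayesian inference of per-pixel polarimetric parameters.

The sample at each pixel is modelled as an elliptical retarder followed by a
partial linear polariser:

    J = A_pol(D, theta_D) . A_ret(phi, theta_phi, delta)

with diattenuation ``D`` and axis ``theta_D``, retardance ``phi`` and axis
``theta_phi``, and circularity ``delta``.  Measured output Jones vectors
``v_k = J u_k`` (k = 1..n illumination states) are assumed corrupted by
isotropic complex Gaussian noise of standard deviation ``sigma``; a single
unknown global phase per pixel (the piston between calibration and sample
acquisitions) is profiled out analytically, so the posterior is invariant
under ``v -> e^{i a} v``.

The decomposition carries an exact 8-fold degeneracy: eight parameter tuples
map to the identical Jones matrix.  ``canonicalise`` picks the class member
closest to a fixed reference point so that parameter images are smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import i0

__all__ = [
    "PolarimetricParams",
    "PriorSpec",
    "jones_forward",
    "equivalence_class",
    "canonicalise",
    "log_posterior",
    "infer_pixel",
    "infer_joint",
    "infer_map",
    "CANONICAL_REFERENCE",
]


def _wrap_half_pi(a: float) -> float:
    """Wrap an axis angle into (-pi/2, pi/2] (period pi)."""
    a = (a + np.pi / 2) % np.pi - np.pi / 2
    return np.pi / 2 if np.isclose(a, -np.pi / 2) else a


def _wrap_pi(a: float) -> float:
    """Wrap a phase into (-pi, pi] (period 2*pi)."""
    a = (a + np.pi) % (2 * np.pi) - np.pi
    return np.pi if np.isclose(a, -np.pi) else a


@dataclass(frozen=True)
class PolarimetricParams:
    """The five-parameter Jones decomposition (angles in rad).

    ``theta_phi`` and ``theta_D`` are axis orientations in (-pi/2, pi/2];
    ``phi`` (retardance) and ``delta`` (circularity) lie in (-pi, pi];
    diattenuation ``D`` in [-1, 1].
    """

    theta_phi: float
    phi: float
    delta: float
    D: float
    theta_D: float

    def validate(self) -> None:
        if not (-np.pi / 2 < self.theta_phi <= np.pi / 2 + 1e-12):
            raise ValueError(f"theta_phi={self.theta_phi} outside (-pi/2, pi/2]")
        if not (-np.pi / 2 < self.theta_D <= np.pi / 2 + 1e-12):
            raise ValueError(f"theta_D={self.theta_D} outside (-pi/2, pi/2]")
        if not (-np.pi < self.phi <= np.pi + 1e-12):
            raise ValueError(f"phi={self.phi} outside (-pi, pi]")
        if not (-np.pi < self.delta <= np.pi + 1e-12):
            raise ValueError(f"delta={self.delta} outside (-pi, pi]")
        if not (-1 <= self.D <= 1):
            raise ValueError(f"D={self.D} outside [-1, 1]")

    def wrapped(self) -> "PolarimetricParams":
        return PolarimetricParams(
            _wrap_half_pi(self.theta_phi), _wrap_pi(self.phi),
            _wrap_pi(self.delta), float(np.clip(self.D, -1, 1)),
            _wrap_half_pi(self.theta_D))

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_phi, self.phi, self.delta, self.D,
                         self.theta_D])


#: Reference point used to pick a unique representative of each degeneracy
#: class: (theta_phi, phi, delta, D, theta_D) = (pi/4, pi, 0, 1, pi/4).
CANONICAL_REFERENCE = PolarimetricParams(np.pi / 4, np.pi, 0.0, 1.0, np.pi / 4)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def jones_forward(p: PolarimetricParams, validate: bool = True) -> np.ndarray:
    """Jones matrix of the elliptical-retarder + partial-polariser model."""
    if validate:
        p.validate()
    a_pol = _rot(p.theta_D) @ np.diag([1 + p.D, 1 - p.D]) @ _rot(-p.theta_D)
    e_d = np.diag([1.0, np.exp(1j * p.delta)])
    e_dm = np.diag([1.0, np.exp(-1j * p.delta)])
    d_phi = np.diag([np.exp(1j * p.phi / 2), np.exp(-1j * p.phi / 2)])
    a_ret = e_d @ _rot(p.theta_phi) @ d_phi @ _rot(-p.theta_phi) @ e_dm
    return a_pol.astype(complex) @ a_ret


def equivalence_class(p: PolarimetricParams) -> list[PolarimetricParams]:
    """The eight parameter tuples producing the identical Jones matrix.

    Members are ``(theta_phi [+pi/2 | sign-flip], +/-phi, delta [+pi],
    +/-D, theta_D [+pi/2])`` in the four compatible combinations, wrapped
    back into range.
    """
    t, f, d, D, tD = p.theta_phi, p.phi, p.delta, p.D, p.theta_D
    raw = [
        (t, f, d, D, tD),
        (t + np.pi / 2, -f, d, D, tD),
        (-t, f, d + np.pi, D, tD),
        (-t + np.pi / 2, -f, d + np.pi, D, tD),
        (t, f, d, -D, tD + np.pi / 2),
        (t + np.pi / 2, -f, d, -D, tD + np.pi / 2),
        (-t, f, d + np.pi, -D, tD + np.pi / 2),
        (-t + np.pi / 2, -f, d + np.pi, -D, tD + np.pi / 2),
    ]
    return [PolarimetricParams(*m).wrapped() for m in raw]


def _circ_dist(a: float, b: float, period: float) -> float:
    d = (a - b) % period
    return min(d, period - d)


def canonicalise(p: PolarimetricParams,
                 reference: PolarimetricParams = CANONICAL_REFERENCE
                 ) -> PolarimetricParams:
    """Return the degeneracy-class member closest to ``reference``.

    Distance is Euclidean over circular differences for the angles (period pi
    for the axis angles, 2*pi for phi and delta) and absolute difference for
    D.  Idempotent, and leaves the forward Jones matrix unchanged.
    """
    members = equivalence_class(p)

    def dist(m: PolarimetricParams) -> float:
        return (
            _circ_dist(m.theta_phi, reference.theta_phi, np.pi) ** 2
            + _circ_dist(m.phi, reference.phi, 2 * np.pi) ** 2
            + _circ_dist(m.delta, reference.delta, 2 * np.pi) ** 2
            + (m.D - reference.D) ** 2
            + _circ_dist(m.theta_D, reference.theta_D, np.pi) ** 2
        )

    return min(members, key=dist)


# ---------------------------------------------------------------------------
# Priors and posterior
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Priors and noise model for the Bayesian fit.

    ``sigma`` is the complex-Gaussian noise standard deviation, fixed during
    inference and expressed relative to unit-mean illumination amplitude.
    Circular parameters carry von Mises priors (kappa = 0 is the flat limit,
    used for theta_D, theta_phi and phi); delta uses kappa = 1 to damp
    over-fitting of circularity.  D has a truncated-Gaussian prior on [-1, 1]
    with mean 0 and broad variance.  ``R`` is the neighbourhood size for the
    joint misalignment-robust inference.
    """

    sigma: float = 0.4
    kappa_delta: float = 1.0
    kappa_axes: float = 0.0          # flat limit for theta_D, theta_phi, phi
    D_variance: float = 5.0
    R: int = 15

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.D_variance <= 0 or self.R < 1:
            raise ValueError("sigma and D_variance must be > 0 and R >= 1")
        if self.kappa_delta < 0 or self.kappa_axes < 0:
            raise ValueError("kappa must be >= 0")


def _check_states(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    U = np.atleast_2d(np.asarray(U, dtype=np.complex128))
    V = np.atleast_2d(np.asarray(V, dtype=np.complex128))
    if U.shape != V.shape or U.ndim != 2 or U.shape[1] != 2:
        raise ValueError("U and V must both have shape (n_states, 2)")
    if U.shape[0] < 2:
        raise ValueError("at least two polarisation states are required "
                         f"(got {U.shape[0]})")
    return U, V


def _aligned_residual_sq(J: np.ndarray, U: np.ndarray, V: np.ndarray) -> float:
    """Sum of squared residuals after profiling out one global phase.

    min_a sum_k ||v_k - e^{ia} J u_k||^2
      = sum ||v||^2 + sum ||Ju||^2 - 2 |sum <Ju, v>|.
    """
    JU = U @ J.T
    cross = np.vdot(JU, V)          # sum conj(Ju).v
    return float(max(
        np.sum(np.abs(V) ** 2) + np.sum(np.abs(JU) ** 2) - 2 * np.abs(cross),
        0.0))


def _log_prior(p: PolarimetricParams, prior: PriorSpec) -> float:
    lp = 0.0
    # von Mises on circular parameters (axis angles live on a period-pi
    # circle, so the doubled angle is used); kappa = 0 gives the flat limit.
    if prior.kappa_axes > 0:
        k = prior.kappa_axes
        lp += k * np.cos(2 * p.theta_D) - np.log(2 * np.pi * i0(k))
        lp += k * np.cos(2 * p.theta_phi) - np.log(2 * np.pi * i0(k))
        lp += k * np.cos(p.phi) - np.log(2 * np.pi * i0(k))
    else:
        lp += 2 * -np.log(np.pi) - np.log(2 * np.pi)
    k = prior.kappa_delta
    lp += k * np.cos(p.delta) - np.log(2 * np.pi * i0(k))
    # truncated Gaussian on D over [-1, 1], mean 0; the truncation constant
    # does not depend on D so it is folded into the additive constant.
    lp += -p.D ** 2 / (2 * prior.D_variance)
    return lp


def log_posterior(p: PolarimetricParams, U: np.ndarray, V: np.ndarray,
                  prior: PriorSpec) -> float:
    """Unnormalised log posterior of the 5 parameters given state pairs.

    The likelihood is the product over states of 2-D complex Gaussians
    ``v_k ~ CN(J u_k, sigma^2 I)`` with one shared global phase profiled out.
    """
    U, V = _check_states(U, V)
    J = jones_forward(p, validate=False)
    r2 = _aligned_residual_sq(J, U, V)
    n = U.shape[0]
    ll = -r2 / prior.sigma ** 2 - 2 * n * np.log(np.pi * prior.sigma ** 2)
    return ll + _log_prior(p, prior)


# ---------------------------------------------------------------------------
# Per-pixel MAP inference
# ---------------------------------------------------------------------------

def _params_from_vector(x: np.ndarray) -> PolarimetricParams:
    return PolarimetricParams(x[0], x[1], x[2], x[3], x[4])

_BOUNDS = [(-np.pi / 2, np.pi / 2), (-np.pi, np.pi), (-np.pi, np.pi),
           (-1.0, 1.0), (-np.pi / 2, np.pi / 2)]


def _polar_init(U: np.ndarray, V: np.ndarray) -> PolarimetricParams | None:
    """Closed-form initialiser via least squares + polar decomposition.

    Solves V ~ J U for J, factorises J = P W (P Hermitian PSD, W unitary) and
    reads the five parameters off the A_pol / A_ret structure.  Exact for
    noiseless in-class data; a starting point otherwise.
    """
    try:
        J, *_ = np.linalg.lstsq(U, V, rcond=None)
        J = J.T
        # polar decomposition J = P W
        u_svd, s, vh = np.linalg.svd(J)
        P = (u_svd * s) @ u_svd.conj().T
        W = u_svd @ vh
        # A_pol = R(tD) diag(1+D, 1-D) R(-tD): eigvals of P
        evals, evecs = np.linalg.eigh(P)
        # eigh sorts ascending -> evals[1] = 1+D direction
        D = float(np.clip((evals[1] - evals[0]) / 2, -1, 1))
        scale = (evals[1] + evals[0]) / 2
        if scale > 1e-12:
            pass  # overall transmittance is assumed normalised out by caller
        v1 = evecs[:, 1]
        theta_D = _wrap_half_pi(float(np.arctan2(-np.real(v1[1] * np.conj(v1[0])),
                                                 np.abs(v1[0]) ** 2 - 0.5 + 0.5)))
        # R(tD) column for eigenvalue 1+D is (cos tD, -sin tD)
        theta_D = _wrap_half_pi(float(-np.arctan2(np.real(v1[1]), np.real(v1[0]))))
        # retarder part: remove residual det phase, match A_ret structure
        detW = np.linalg.det(W)
        W = W * np.exp(-0.5j * np.angle(detW))
        cos_half = np.clip(np.real(W[0, 0] + W[1, 1]) / 2, -1, 1)
        phi = 2 * np.arccos(cos_half)
        sin_half = np.sin(phi / 2)
        if sin_half < 1e-9:
            theta_phi, delta = 0.0, 0.0
        else:
            z = np.imag(W[0, 0] - W[1, 1]) / 2 / sin_half     # cos 2 theta
            off = 1j * W[1, 0] / sin_half                      # sin2t e^{i delta}
            theta_phi = 0.5 * np.arctan2(np.abs(off), np.clip(z, -1, 1))
            delta = float(np.angle(off)) if np.abs(off) > 1e-9 else 0.0
        return PolarimetricParams(_wrap_half_pi(theta_phi), _wrap_pi(phi),
                                  _wrap_pi(delta), D, theta_D).wrapped()
    except np.linalg.LinAlgError:
        return None


def infer_pixel(U: np.ndarray, V: np.ndarray, prior: PriorSpec | None = None,
                extra_starts: int = 0, seed: int = 0) -> dict:
    """MAP estimate of the five parameters for one pixel.

    Deterministic multi-start bounded optimisation: one start per degeneracy
    class member of the closed-form (polar decomposition) initialiser, plus
    optional seeded random restarts.  Returns a dict with keys ``params``
    (canonicalised), ``params_raw``, ``log_posterior``, ``residual_rms``,
    ``converged``.
    """
    prior = prior or PriorSpec()
    U, V = _check_states(U, V)

    def neg_lp(x: np.ndarray) -> float:
        return -log_posterior(_params_from_vector(x).wrapped(), U, V, prior)

    starts: list[PolarimetricParams] = []
    init = _polar_init(U, V)
    if init is None:
        init = PolarimetricParams(0.3, 1.0, 0.2, 0.3, 0.3)
    starts.extend(equivalence_class(init))
    if extra_starts:
        rng = np.random.default_rng(seed)
        for _ in range(extra_starts):
            starts.append(PolarimetricParams(
                rng.uniform(-np.pi / 2, np.pi / 2), rng.uniform(-np.pi, np.pi),
                rng.uniform(-np.pi, np.pi), rng.uniform(-1, 1),
                rng.uniform(-np.pi / 2, np.pi / 2)))

    best, best_val, any_ok = None, np.inf, False
    for s in starts:
        res = minimize(neg_lp, s.as_array(), method="L-BFGS-B", bounds=_BOUNDS)
        any_ok = any_ok or res.success
        if res.fun < best_val:
            best_val, best = res.fun, res.x
    p_raw = _params_from_vector(best).wrapped()
    J = jones_forward(p_raw, validate=False)
    rms = np.sqrt(_aligned_residual_sq(J, U, V) / U.size)
    return {
        "params": canonicalise(p_raw),
        "params_raw": p_raw,
        "log_posterior": -best_val,
        "residual_rms": float(rms),
        "converged": bool(any_ok),
    }


# ---------------------------------------------------------------------------
# Joint neighbourhood inference (misalignment-artefact correction)
# ---------------------------------------------------------------------------
#
# Misaligned illumination/detection arms imprint a linear phase ramp on one
# polarisation component.  For a birefringent sample whose axes are not
# aligned with the arms this masquerades as a spatially varying retardance.
# The joint model for a small neighbourhood therefore shares two quantities
# across its R pixels: the retardance-axis angle ``theta_hat`` (the rotated
# linear-polarisation basis in which the sample retarder is diagonal, taking
# the place of theta_phi) and the common inter-arm ramp slope (gx, gy).
# Expressed in that basis the retarder is diagonal and the circularity
# degree of freedom drops out, so each pixel retains (D, theta_D, phi).

_GAMMA_GRID = np.linspace(-np.pi, np.pi, 48, endpoint=False)
_PHI_GRID = np.linspace(-np.pi, np.pi, 48, endpoint=False)


def _fit_diag_retarder(J_t: np.ndarray) -> tuple[float, float, float]:
    """Best (phi, D, theta_D_tilde) with J_t ~ e^{i g} A_pol . diag(e^{±i phi/2}).

    Closed-form least squares on the matrix entries over a (phi, gamma) grid
    with two zoom levels; the polariser part [[1+e, b], [b, 1-e]] is linear
    given (phi, gamma).  Exact for in-class noiseless input.
    """
    phis, gammas = _PHI_GRID, _GAMMA_GRID
    span = phis[1] - phis[0]
    best = (np.inf, 0.0, 0.0, 0.0, 0.0)
    for _ in range(3):
        P, G = np.meshgrid(phis, gammas, indexing="ij")
        p = np.exp(1j * P / 2)             # e^{i phi/2}
        w00 = J_t[0, 0] * np.exp(-1j * G)
        w01 = J_t[0, 1] * np.exp(-1j * G)
        w10 = J_t[1, 0] * np.exp(-1j * G)
        w11 = J_t[1, 1] * np.exp(-1j * G)
        e = (np.real(w00 * np.conj(p)) - np.real(w11 * p)) / 2
        b = (np.real(w01 * p) + np.real(w10 * np.conj(p))) / 2
        r = (np.abs(w00 - (1 + e) * p) ** 2 + np.abs(w11 - (1 - e) / p) ** 2
             + np.abs(w01 - b / p) ** 2 + np.abs(w10 - b * p) ** 2)
        idx = np.unravel_index(np.argmin(r), r.shape)
        if r[idx] < best[0]:
            best = (float(r[idx]), float(P[idx]), float(G[idx]),
                    float(e[idx]), float(b[idx]))
        phis = best[1] + np.linspace(-span, span, 9)
        gammas = best[2] + np.linspace(-span, span, 9)
        span = phis[1] - phis[0]
    _, phi, _, e, b = best
    D = float(np.clip(np.hypot(e, b), 0.0, 1.0))
    theta_Dt = 0.5 * np.arctan2(-b, e) if D > 1e-12 else 0.0
    return _wrap_pi(phi), D, float(theta_Dt)


def _deramp(V: np.ndarray, beta: float) -> np.ndarray:
    out = V.copy()
    out[:, 1] *= np.exp(-1j * beta)
    return out


def _joint_objective(theta_hat: float, g: np.ndarray, U_list, V_list,
                     coords, prior: PriorSpec, polish: bool = False):
    """Joint log posterior for shared (theta_hat, ramp slope g).

    Per pixel: de-ramp the V component, rotate into the theta_hat basis, fit
    the diagonal-retarder + polariser model in closed form, optionally polish
    against the full posterior.  Returns (sum of log posteriors, fits) where
    each fit is the 5-parameter tuple with theta_phi = theta_hat, delta = 0.
    """
    Rm = _rot(-theta_hat)
    centre = coords.mean(axis=0)
    total, fits = 0.0, []
    for (Uk, Vk), xy in zip(zip(U_list, V_list), coords):
        beta = float(g @ (xy - centre))
        Vd = _deramp(Vk, beta)
        Ut = Uk @ Rm.T
        Vt = Vd @ Rm.T
        J_t, *_ = np.linalg.lstsq(Ut, Vt, rcond=None)
        phi, D, tDt = _fit_diag_retarder(J_t.T)
        p = PolarimetricParams(theta_hat, phi, 0.0, D,
                               _wrap_half_pi(tDt + theta_hat)).wrapped()
        if polish:
            def neg_lp(x):
                q = PolarimetricParams(theta_hat, _wrap_pi(x[0]), 0.0,
                                       float(np.clip(x[1], -1, 1)),
                                       _wrap_half_pi(x[2]))
                return -log_posterior(q, Uk, Vd, prior)
            r = minimize(neg_lp, np.array([p.phi, p.D, p.theta_D]),
                         method="L-BFGS-B",
                         bounds=[(-np.pi, np.pi), (-1, 1),
                                 (-np.pi / 2, np.pi / 2)])
            p = PolarimetricParams(theta_hat, _wrap_pi(r.x[0]), 0.0,
                                   float(np.clip(r.x[1], -1, 1)),
                                   _wrap_half_pi(r.x[2])).wrapped()
        total += log_posterior(p, Uk, Vd, prior)
        fits.append(p)
    return total, fits


def _phi_tilt(fits, coords) -> float:
    """RMS slope (rad/µm) of a linear fit to retardance across a neighbourhood."""
    phis = np.unwrap([f.phi for f in fits])
    A = np.column_stack([coords[:, 0], coords[:, 1], np.ones(len(coords))])
    sol, *_ = np.linalg.lstsq(A, phis, rcond=None)
    return float(np.hypot(sol[0], sol[1]))


def infer_joint(U_list, V_list, coords, prior: PriorSpec | None = None,
                n_theta_grid: int = 19, lp_window: float = 2.0,
                fit_ramp: bool = True) -> dict:
    """Joint MAP inference over a neighbourhood of R pixels.

    The rotated retardance-axis angle ``theta_hat`` and the inter-arm phase
    ramp slope are shared across the neighbourhood; the remaining parameters
    (D, theta_D, phi) are optimised per pixel and the per-pixel log
    posteriors summed (the factorised approximation of the neighbourhood
    posterior).  Among candidates whose joint posterior lies within
    ``lp_window`` of the maximum, the one minimising the spatial tilt of the
    retardance is selected, which suppresses the misalignment artefact while
    leaving tilt-free data untouched.  For phi -> 0 the retarder is nearly
    isotropic and ``theta_hat`` is only weakly constrained, mirroring the
    behaviour of theta_phi in the per-pixel model.

    Returns dict with ``params`` (canonicalised per-pixel parameters, all
    sharing theta_phi = theta_hat and delta = 0), ``theta_hat``, ``ramp``
    (gx, gy in rad/µm), ``log_posterior`` and ``tilt`` (rad/µm).
    """
    prior = prior or PriorSpec()
    coords = np.asarray(coords, dtype=float)
    U_list = [_check_states(u, v)[0] for u, v in zip(U_list, V_list)]
    V_list = [np.atleast_2d(np.asarray(v, dtype=complex)) for v in V_list]
    if not (len(U_list) == len(V_list) == len(coords)):
        raise ValueError("U_list, V_list and coords must have equal length")

    g0 = np.zeros(2)
    thetas = np.linspace(-np.pi / 2, np.pi / 2, n_theta_grid, endpoint=False)
    grid = [( _joint_objective(t, g0, U_list, V_list, coords, prior)[0], t)
            for t in thetas]
    grid.sort(key=lambda e: -e[0])
    step = np.pi / n_theta_grid

    candidates = []  # (lp, theta, g)
    for lp, th in grid[:2]:
        g_best = g0
        if fit_ramp:
            from scipy.optimize import minimize as _min
            res = _min(lambda g: -_joint_objective(th, g, U_list, V_list,
                                                   coords, prior)[0],
                       g0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-3, "maxfev": 120,
                                "initial_simplex": [[0, 0], [0.02, 0],
                                                    [0, 0.02]]})
            g_best = res.x
        r = minimize_scalar(
            lambda t: -_joint_objective(t, g_best, U_list, V_list, coords,
                                        prior)[0],
            bounds=(th - step, th + step), method="bounded",
            options={"xatol": 1e-3})
        th_ref = _wrap_half_pi(float(r.x))
        lp_ref, _ = _joint_objective(th_ref, g_best, U_list, V_list, coords,
                                     prior)
        candidates.append((lp_ref, th_ref, g_best))
        candidates.append((lp, th, g0))

    lp_max = max(c[0] for c in candidates)
    finalists = []
    for lp, th, g in candidates:
        if lp >= lp_max - lp_window:
            lp_p, fits = _joint_objective(th, g, U_list, V_list, coords,
                                          prior, polish=True)
            finalists.append((lp_p, th, g, fits, _phi_tilt(fits, coords)))
    best = min(finalists, key=lambda c: c[4])
    lp_best, theta_hat, g, fits, tilt = best
    return {
        "params": [canonicalise(p) for p in fits],
        "params_raw": fits,
        "theta_hat": float(theta_hat),
        "ramp": np.asarray(g, dtype=float),
        "log_posterior": float(lp_best),
        "tilt": float(tilt),
    }


def parameter_deviation(p_est: PolarimetricParams,
                        p_true: PolarimetricParams) -> np.ndarray:
    """Per-parameter deviations minimised over the degeneracy class.

    Returns [d_theta_phi, d_phi, d_delta, d_D, d_theta_D] using circular
    distances (period pi for the axis angles, 2*pi for phi and delta) for
    the class member of ``p_est`` closest to ``p_true`` overall.
    """
    best, best_d = np.inf, None
    for m in equivalence_class(p_est):
        d = np.array([
            _circ_dist(m.theta_phi, p_true.theta_phi, np.pi),
            _circ_dist(m.phi, p_true.phi, 2 * np.pi),
            _circ_dist(m.delta, p_true.delta, 2 * np.pi),
            abs(m.D - p_true.D),
            _circ_dist(m.theta_D, p_true.theta_D, np.pi)])
        if d.sum() < best:
            best, best_d = d.sum(), d
    return best_d


def sample_synthetic_pixels(n: int, rng: np.random.Generator,
                            d_max: float = 0.7,
                            phi_range: tuple[float, float] = (0.4, 2.7),
                            axis_margin: float = 0.2) -> list[PolarimetricParams]:
    """Draw ground-truth parameter tuples for recovery experiments.

    Draws follow the inference priors but are restricted to the identifiable
    regime: |D| <= ``d_max`` (a near-complete polariser extinguishes one axis
    and hides the retarder parameters behind it), |phi| inside ``phi_range``
    (a vanishing retarder leaves its axis undefined; phi ~ pi sits on the
    wrap-around boundary) and axis angles ``axis_margin`` away from the range
    edges.  delta follows its von Mises(kappa=1) prior.
    """
    out = []
    while len(out) < n:
        D = np.clip(rng.normal(0.0, np.sqrt(5.0)), -1, 1)
        if abs(D) > d_max:
            continue
        out.append(PolarimetricParams(
            rng.uniform(-np.pi / 2 + axis_margin, np.pi / 2 - axis_margin),
            rng.uniform(*phi_range) * rng.choice([-1.0, 1.0]),
            float(rng.vonmises(0.0, 1.0)), float(D),
            rng.uniform(-np.pi / 2 + axis_margin, np.pi / 2 - axis_margin)))
    return out


def axis_posterior_spread(U: np.ndarray, V: np.ndarray, prior: PriorSpec,
                          params: PolarimetricParams, n_grid: int = 90) -> float:
    """Circular spread (rad) of the conditional posterior of theta_phi.

    Profiles the posterior over a grid of the retardance-axis angle with the
    other four parameters held at ``params``; returns the circular standard
    deviation of the doubled angle mapped back to axis units.  A vanishing
    retarder (phi -> 0) leaves the axis unconstrained and the spread large.
    """
    thetas = np.linspace(-np.pi / 2, np.pi / 2, n_grid, endpoint=False)
    lps = np.array([
        log_posterior(replace(params, theta_phi=t), U, V, prior)
        for t in thetas])
    w = np.exp(lps - lps.max())
    w /= w.sum()
    z = np.sum(w * np.exp(2j * thetas))
    rbar = min(np.abs(z), 1 - 1e-12)
    return float(np.sqrt(-2 * np.log(rbar)) / 2)


def infer_map(U_img: np.ndarray, V_img: np.ndarray, prior: PriorSpec | None = None,
              pixel_pitch: float = 1.0, low_D_threshold: float = 0.1) -> dict:
    """Run joint inference over tiled neighbourhoods of a full image.

    ``U_img`` and ``V_img`` have shape (ny, nx, n_states, 2).  The image is
    tiled into 5x3 blocks (15 pixels, the default neighbourhood size R); each
    block is inferred jointly and the canonicalised parameters assembled into
    five maps.  Pixels whose diattenuation magnitude falls below
    ``low_D_threshold`` have the diattenuation axis flagged low-confidence
    (the axis of a vanishing diattenuation vector is undefined).

    Returns dict of 2-D arrays: ``D``, ``theta_D``, ``phi``, ``theta_phi``,
    ``delta``, plus boolean ``theta_D_low_confidence``.
    """
    prior = prior or PriorSpec()
    U_img = np.asarray(U_img, dtype=complex)
    V_img = np.asarray(V_img, dtype=complex)
    if U_img.shape != V_img.shape or U_img.ndim != 4:
        raise ValueError("U_img/V_img must have shape (ny, nx, n_states, 2)")
    ny, nx = U_img.shape[:2]
    # tile shape chosen so a full tile holds exactly R pixels (5x3 for R=15)
    ty = max(int(np.round(np.sqrt(prior.R * 5 / 3))), 1)
    tx = max(prior.R // ty, 1)
    maps = {k: np.zeros((ny, nx)) for k in
            ("D", "theta_D", "phi", "theta_phi", "delta")}
    for y0 in range(0, ny, ty):
        for x0 in range(0, nx, tx):
            ys = slice(y0, min(y0 + ty, ny))
            xs = slice(x0, min(x0 + tx, nx))
            yy, xx = np.mgrid[ys, xs]
            coords = np.column_stack([xx.ravel() * pixel_pitch,
                                      yy.ravel() * pixel_pitch])
            Us = U_img[ys, xs].reshape(-1, *U_img.shape[2:])
            Vs = V_img[ys, xs].reshape(-1, *V_img.shape[2:])
            out = infer_joint(list(Us), list(Vs), coords, prior)
            for p, iy, ix in zip(out["params"], yy.ravel(), xx.ravel()):
                maps["D"][iy, ix] = p.D
                maps["theta_D"][iy, ix] = p.theta_D
                maps["phi"][iy, ix] = p.phi
                maps["theta_phi"][iy, ix] = p.theta_phi
                maps["delta"][iy, ix] = p.delta
    maps["theta_D_low_confidence"] = np.abs(maps["D"]) < low_D_threshold
    return maps
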