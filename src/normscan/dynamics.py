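"""Mean-field reputation dynamics with implementation and assignment errors.

The population state is the vector ``h`` of reputation shares.  In each time
unit a random donor meets a random recipient; the donor's next reputation is
drawn from the error kernel of the resident norm, giving the flow

    dh_Z/dt = sum_{X,Y} h_X h_Y K(X, Y -> Z) - h_Z,

which preserves ``sum(h) = 1``.  Errors enter the kernel in two ways: an
implementation error (probability ``mu_e``) makes a donor defect when
cooperation is prescribed (never the reverse), and an assignment error
(probability ``mu_a``) replaces the prescribed new reputation by one of the
k-1 wrong labels, chosen uniformly (each with mass ``mu_a / (k-1)``, i.e.
``mu_a / 2`` in the ternary model).

The stationary state is obtained by fourth-order Runge-Kutta integration
from the uniform initial condition, renormalising every step; a guarded
Newton polish accelerates the final approach for norms whose slow relaxation
rate is O(mu) (see docs/methods.md for the acceptance safeguards).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .norms import Norm

__all__ = [
    "ErrorModel",
    "StationaryResult",
    "NonConvergenceError",
    "transition_kernel",
    "flow",
    "stationary",
    "cooperation_level",
    "scaling_exponent",
    "extrapolate_mu_zero",
    "picard_fixed_points",
    "DEFAULT_MU_GRID",
]

#: Error-rate grid used for scaling fits: three decades below the working mu.
DEFAULT_MU_GRID = (1e-3, 1e-4, 1e-5, 1e-6)


@dataclass(frozen=True)
class ErrorModel:
    """Implementation error ``mu_e`` (C -> D only) and assignment error ``mu_a``."""

    mu_e: float = 1e-3
    mu_a: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_e < 1.0):
            raise ValueError("mu_e must lie in [0, 1)")
        if not (0.0 <= self.mu_a < 1.0):
            raise ValueError("mu_a must lie in [0, 1)")

    @classmethod
    def tied(cls, mu: float) -> "ErrorModel":
        """The common single-noise setting mu_e = mu_a = mu."""
        return cls(mu, mu)


class NonConvergenceError(RuntimeError):
    """The dynamics did not reach the residual tolerance; carries the last state."""

    def __init__(self, message: str, h_last: np.ndarray, residual: float, steps: int):
        super().__init__(message)
        self.h_last = h_last
        self.residual = residual
        self.steps = steps


@dataclass(frozen=True)
class StationaryResult:
    """Stationary reputation shares and the cooperation level of a norm."""

    h_star: np.ndarray = field(compare=False)
    p_c: float
    residual: float
    steps: int
    initial_condition: np.ndarray = field(compare=False)

    @property
    def p_d(self) -> float:
        """Defection level 1 - p_c."""
        return 1.0 - self.p_c

    @property
    def h_B(self) -> float:
        return float(self.h_star[0])

    @property
    def h_N(self) -> float:
        # meaningful for k=3 (index 1 is N); for k=2 index 1 is G
        return float(self.h_star[1])

    @property
    def h_G(self) -> float:
        return float(self.h_star[-1])


# ---------------------------------------------------------------------------
# Kernel and flow
# ---------------------------------------------------------------------------


def _action_kernels(norm: Norm, err: ErrorModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-context kernels if the donor *intends* C resp. D.

    ``K_C[x, y, z]`` is the probability of next reputation z when cooperation
    is prescribed at (x, y) (implementation error may flip it to defection);
    ``K_D`` is the same for prescribed defection (no error applies).  Both
    include the assignment-error smearing.  Rows sum to one.
    """
    k = norm.k
    wrong = err.mu_a / (k - 1)
    keep = 1.0 - k * wrong  # = 1 - mu_a - mu_a/(k-1) + ... == (1 - k/(k-1) mu_a)
    eye = np.eye(k)
    on_c = eye[norm.assignment[:, :, 0]]  # delta_{R(x,y,C), z}
    on_d = eye[norm.assignment[:, :, 1]]
    K_C = keep * ((1.0 - err.mu_e) * on_c + err.mu_e * on_d) + wrong
    K_D = keep * on_d + wrong
    return K_C, K_D


def transition_kernel(norm: Norm, err: ErrorModel) -> np.ndarray:
    """Probability ``K[x, y, z]`` that a donor with reputation x facing a
    recipient with reputation y ends up with reputation z under the resident
    norm, including both error types.  Each (x, y) row sums to 1."""
    K_C, K_D = _action_kernels(norm, err)
    coop = (norm.action == 0)[:, :, None]
    return np.where(coop, K_C, K_D)


def flow(h: np.ndarray, norm: Norm, err: ErrorModel) -> np.ndarray:
    """Rate of change of the reputation shares; components sum to zero."""
    K = transition_kernel(norm, err)
    return _flow_mat(np.asarray(h, dtype=float), K.reshape(norm.k * norm.k, norm.k), norm.k)


def _flow_mat(h: np.ndarray, K2: np.ndarray, k: int) -> np.ndarray:
    pair = np.outer(h, h).reshape(k * k)
    return pair @ K2 - h


def _flow_jacobian(h: np.ndarray, K3: np.ndarray, k: int) -> np.ndarray:
    """d flow_z / d h_w for the unconstrained flow."""
    # inflow term: sum_y h_y K[w,y,z] + sum_x h_x K[x,w,z]
    J = np.einsum("y,wyz->zw", h, K3) + np.einsum("x,xwz->zw", h, K3)
    return J - np.eye(k)


def _newton_polish(
    h: np.ndarray, K3: np.ndarray, k: int, tol: float
) -> tuple[np.ndarray, bool]:
    """Newton iteration on the simplex-reduced flow.

    Returns (root, ok); ok is False if the iteration leaves the simplex,
    fails to converge, or lands on a dynamically unstable root.
    """
    K2 = K3.reshape(k * k, k)
    u = h.copy()
    for _ in range(40):
        f = _flow_mat(u, K2, k)
        r = float(np.abs(f).max())
        if r < tol:
            break
        Jfull = _flow_jacobian(u, K3, k)
        # reduce to the simplex: eliminate the last coordinate
        Jr = (Jfull[:-1, :-1] - Jfull[:-1, -1:])
        try:
            du = np.linalg.solve(Jr, -f[:-1])
        except np.linalg.LinAlgError:
            return h, False
        if not np.all(np.isfinite(du)) or np.abs(du).max() > 0.5:
            return h, False
        u = u.copy()
        u[:-1] += du
        u[-1] = 1.0 - u[:-1].sum()
        if u.min() < -1e-12:
            return h, False
    else:
        return h, False
    u = np.clip(u, 0.0, None)
    u /= u.sum()
    # accept only roots that are attracting within the simplex
    Jfull = _flow_jacobian(u, K3, k)
    Jr = Jfull[:-1, :-1] - Jfull[:-1, -1:]
    if np.linalg.eigvals(Jr).real.max() > 1e-9:
        return h, False
    return u, True


def stationary(
    norm: Norm,
    err: ErrorModel,
    init: np.ndarray | None = None,
    dt: float = 0.1,
    tol: float = 1e-10,
    max_steps: int = 1_000_000,
    polish: bool = True,
) -> StationaryResult:
    """Integrate the share dynamics to the stationary state.

    RK4 with renormalisation each step from the uniform initial condition
    (the representative state when several attractors coexist).  The step
    size is raised fivefold once the residual drops below 1e-2 (fixed points
    of the flow are exact fixed points of an RK4 step of any stable size, so
    this changes speed, not the limit), and a guarded Newton polish finishes
    the approach once the trajectory is close to the slow manifold.

    Raises
    ------
    NonConvergenceError
        If ``max_steps`` RK4 steps do not bring ``max |dh/dt|`` below ``tol``
        (possible cycles or extremely slow relaxation).
    """
    k = norm.k
    h = np.full(k, 1.0 / k) if init is None else np.asarray(init, dtype=float).copy()
    if h.shape != (k,) or h.min() < 0:
        raise ValueError("init must be a length-k distribution")
    h /= h.sum()
    h0 = h.copy()
    K3 = transition_kernel(norm, err)
    K2 = K3.reshape(k * k, k)

    step = dt
    steps = 0
    check_every = 25
    polish_gate = 1e-5  # try Newton only near the slow manifold
    residual = float(np.abs(_flow_mat(h, K2, k)).max())
    while steps < max_steps:
        for _ in range(check_every):
            k1 = _flow_mat(h, K2, k)
            k2_ = _flow_mat(h + 0.5 * step * k1, K2, k)
            k3 = _flow_mat(h + 0.5 * step * k2_, K2, k)
            k4 = _flow_mat(h + step * k3, K2, k)
            h = h + (step / 6.0) * (k1 + 2.0 * k2_ + 2.0 * k3 + k4)
            h = np.clip(h, 0.0, None)
            h /= h.sum()
            steps += 1
        residual = float(np.abs(_flow_mat(h, K2, k)).max())
        if residual < 1e-2 and step == dt:
            # fast modes have relaxed; a larger step stays inside the RK4
            # stability region (flow eigenvalues are bounded by ~3 in modulus)
            step = dt * 5.0
        if polish and residual < polish_gate:
            # polish before the tolerance break: a residual below tol still
            # leaves an O(residual / slow-rate) solution error that Newton
            # removes in a few iterations
            root, ok = _newton_polish(h, K3, k, tol=1e-13)
            if ok and np.abs(root - h).max() < 0.5:
                h = root
                residual = float(np.abs(_flow_mat(h, K2, k)).max())
                break
        if residual < tol:
            break
    if residual >= tol:
        raise NonConvergenceError(
            f"no stationary state within {max_steps} steps (residual {residual:.2e})",
            h_last=h,
            residual=residual,
            steps=steps,
        )
    return StationaryResult(
        h_star=h,
        p_c=cooperation_level(h, norm),
        residual=residual,
        steps=steps,
        initial_condition=h0,
    )


def cooperation_level(h: np.ndarray, norm: Norm) -> float:
    """Prescribed cooperation probability ``sum_{X,Y} h_X h_Y [P(X,Y) = C]``.

    Implementation error does not enter here; it discounts payoffs instead.
    """
    h = np.asarray(h, dtype=float)
    coop = (norm.action == 0).astype(float)
    return float(h @ coop @ h)


# ---------------------------------------------------------------------------
# Scaling with the error rate
# ---------------------------------------------------------------------------

_QUANTITIES = {
    "h_N_star": lambda res: res.h_N,
    "h_B_star": lambda res: res.h_B,
    "p_d": lambda res: res.p_d,
}


def scaling_exponent(
    norm: Norm,
    quantity: str = "h_N_star",
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID,
    **kwargs,
) -> tuple[float, float, dict]:
    """Least-squares slope of ``log(quantity)`` against ``log(mu)``.

    Both error rates are tied (mu_e = mu_a = mu) across the grid.  Quantities
    that vanish exactly at some mu are excluded from the fit and flagged in
    the diagnostics.  A slope near 1 (1/2, 0) signals an O(mu) (O(sqrt mu),
    O(1)) quantity.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; choose from {sorted(_QUANTITIES)}")
    getter = _QUANTITIES[quantity]
    mus, values, excluded = [], [], []
    for mu in sorted(mu_grid, reverse=True):
        res = stationary(norm, ErrorModel.tied(mu), **kwargs)
        v = getter(res)
        if v <= 0.0:
            excluded.append(mu)
            continue
        mus.append(mu)
        values.append(v)
    if len(mus) < 2:
        raise ValueError("fewer than two usable grid points for the scaling fit")
    slope, intercept = np.polyfit(np.log10(mus), np.log10(values), 1)
    fitted = slope * np.log10(mus) + intercept
    diagnostics = {
        "mu": list(mus),
        "values": list(values),
        "excluded": excluded,
        "max_fit_residual": float(np.abs(fitted - np.log10(values)).max()),
    }
    return float(slope), float(intercept), diagnostics


def extrapolate_mu_zero(
    norm: Norm,
    quantity: str = "h_N_star",
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID,
    **kwargs,
) -> float:
    """Richardson extrapolation of a stationary quantity to mu -> 0.

    Quantities that converge to a finite limit approach it linearly in mu,
    so the limit is read off from the two smallest grid values.
    """
    getter = _QUANTITIES[quantity]
    mus = sorted(mu_grid)
    v = [getter(stationary(norm, ErrorModel.tied(mu), **kwargs)) for mu in mus[:2]]
    mu1, mu2 = mus[:2]
    return float((v[0] * mu2 - v[1] * mu1) / (mu2 - mu1))


# ---------------------------------------------------------------------------
# Independent fixed-point oracle (used by the test suite)
# ---------------------------------------------------------------------------


def picard_fixed_points(
    norm: Norm,
    err: ErrorModel,
    n_starts: int = 20,
    damping: float = 0.5,
    tol: float = 1e-14,
    max_iter: int = 400_000,
    seed: int = 0,
) -> list[np.ndarray]:
    """All distinct fixed points of ``h = sum h_X h_Y K(X,Y,.)`` found by
    damped Picard iteration from random simplex starts.

    This solves the stationarity condition directly, without integrating the
    flow, and serves as an independent cross-check of :func:`stationary`.
    The iteration stops on the fixed-point residual ``max |T(h) - h|``
    (not the step size): slowly contracting modes amplify a residual of
    eps into a solution error of order eps divided by the contraction rate,
    so a deep residual is what certifies the returned point.
    """
    k = norm.k
    K2 = transition_kernel(norm, err).reshape(k * k, k)
    rng = np.random.default_rng(seed)
    found: list[np.ndarray] = []
    for _ in range(n_starts):
        h = rng.dirichlet(np.ones(k))
        residual = np.inf
        for _ in range(max_iter):
            t = np.outer(h, h).reshape(k * k) @ K2
            t /= t.sum()
            residual = float(np.abs(t - h).max())
            if residual < tol:
                break
            h = (1.0 - damping) * h + damping * t
        if residual < 1e-12:
            if not any(np.abs(h - g).max() < 1e-7 for g in found):
                found.append(h)
    return found
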