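"""Cooperative-ESS tests: strict Nash stability against all action-rule mutants.

A resident norm is a *cooperative ESS* (CESS) when (i) its stationary
cooperation level clears a threshold (0.99 at the working error rate 1e-3,
chosen between mu and sqrt(mu)) and (ii) the resident payoff strictly exceeds
the payoff of a rare mutant adopting any of the ``2**(k*k) - 1`` alternative
action rules.  Reputations are public and assigned by the population's shared
assignment rule, so mutants differ in behaviour only: a mutant's next
reputation follows the *resident* assignment applied to the mutant's chosen
action.

Payoffs come from the one-shot donation game (cost ``c`` to the donor,
benefit ``b > c`` to the recipient):

    pi_res = p_c (1 - mu_e) (b - c)
    pi_mut = p_c(res->mut) (1 - mu_e) b - p_c(mut->res) (1 - mu_e) c

where the mutant's conditional reputation distribution ``H*`` solves a
linear k-state chain driven by the resident's stationary shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ErrorModel, StationaryResult, _action_kernels, stationary
from .norms import Norm

__all__ = [
    "GameParams",
    "MutantResult",
    "EssReport",
    "DEFAULT_BC_GRID",
    "DEFAULT_PC_THRESHOLD",
    "STRICTNESS_RTOL",
    "resident_payoff",
    "mutant_stationary",
    "mutant_payoff",
    "is_cess",
    "core_set_filter",
]

#: Benefit-to-cost ratios spanning the "reasonable" range [1.1, 10].
DEFAULT_BC_GRID = (1.1, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)

#: Cooperation-level gate at the working error rate.
DEFAULT_PC_THRESHOLD = 0.99

#: Relative tolerance for the strict payoff comparison; ties are invadable.
STRICTNESS_RTOL = 1e-9


@dataclass(frozen=True)
class GameParams:
    """Donation-game parameters: benefit b and cost c with b > c > 0."""

    b: float
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.b > self.c > 0):
            raise ValueError("donation game requires b > c > 0")

    @property
    def ratio(self) -> float:
        return self.b / self.c


@dataclass(frozen=True)
class MutantResult:
    """Best-responding mutant found during a CESS test."""

    action_int: int
    H_star: np.ndarray = field(compare=False)
    payoff: float
    p_c_mut_to_res: float
    p_c_res_to_mut: float


@dataclass(frozen=True)
class EssReport:
    """Outcome of a CESS test at one parameter point."""

    verdict: str  # "CESS" | "fails_cooperation_threshold" | "invadable"
    resident_payoff: float
    p_c: float
    stationary: StationaryResult
    best_mutant: MutantResult | None
    params: GameParams
    err: ErrorModel
    threshold: float

    @property
    def is_cess(self) -> bool:
        return self.verdict == "CESS"


def resident_payoff(p_c: float, params: GameParams, err: ErrorModel) -> float:
    """Per-round resident payoff ``p_c (1 - mu_e) (b - c)``."""
    return p_c * (1.0 - err.mu_e) * (params.b - params.c)


# ---------------------------------------------------------------------------
# Mutant reputation chain
# ---------------------------------------------------------------------------


def _all_action_tables(k: int) -> np.ndarray:
    """All 2**(k*k) action tables, indexed by their action integer."""
    n = k * k
    ints = np.arange(2**n, dtype=np.int64)
    bits = (ints[:, None] >> np.arange(n - 1, -1, -1)) & 1
    return bits.reshape(-1, k, k)


def _mutant_chains(
    resident: Norm, h_star: np.ndarray, err: ErrorModel, actions: np.ndarray
) -> np.ndarray:
    """Row-stochastic chains ``M[m, x, z]`` for a batch of mutant action tables.

    ``M`` averages the mutant kernel over the resident recipient pool:
    ``M[x, z] = sum_y h*_y Khat(x, y, z)`` where the mutant's on-path
    assignment is R(x, y, Phat(x, y)) and error terms use R(x, y, D).
    """
    K_C, K_D = _action_kernels(resident, err)
    coop = (actions == 0)[..., None]
    Khat = np.where(coop, K_C, K_D)  # (m, k, k, k)
    return np.einsum("y,mxyz->mxz", h_star, Khat)


def _chain_stationary(M: np.ndarray) -> np.ndarray:
    """Stationary distributions of a batch of row-stochastic k-state chains.

    Solved as the linear system ``H (M - I) = 0`` with the normalisation
    ``sum H = 1``; the rare non-irreducible cases fall back to iterating the
    chain from the uniform distribution.
    """
    m, k, _ = M.shape
    A = np.transpose(M, (0, 2, 1)) - np.eye(k)
    A[:, -1, :] = 1.0
    rhs = np.zeros((m, k))
    rhs[:, -1] = 1.0
    try:
        H = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # a singular member poisons the batched solve; redo chain by chain
        H = np.empty((m, k))
        for i in range(m):
            try:
                H[i] = np.linalg.solve(A[i], rhs[i])
            except np.linalg.LinAlgError:
                H[i] = np.nan
    bad = ~np.all(np.isfinite(H), axis=1) | (H.min(axis=1) < -1e-9)
    if np.any(bad):
        # reducible chain (possible only at mu_a = 0): iterate from uniform
        for i in np.flatnonzero(bad):
            h = np.full(k, 1.0 / k)
            for _ in range(100_000):
                new = h @ M[i]
                new /= new.sum()
                if np.abs(new - h).max() < 1e-14:
                    h = new
                    break
                h = new
            H[i] = h
    H = np.clip(H, 0.0, None)
    H /= H.sum(axis=1, keepdims=True)
    return H


def mutant_stationary(
    resident: Norm,
    mutant_action: np.ndarray | int,
    h_star: np.ndarray,
    err: ErrorModel,
) -> np.ndarray:
    """Stationary reputation distribution of a rare mutant with the given
    action rule, embedded in a resident population at ``h_star``."""
    if isinstance(mutant_action, (int, np.integer)):
        mutant_action = Norm.from_ints(resident.k, 0, int(mutant_action)).action
    actions = np.asarray(mutant_action, dtype=np.int64)[None]
    M = _mutant_chains(resident, np.asarray(h_star, float), err, actions)
    return _chain_stationary(M)[0]


def _mutant_coop_rates(
    resident: Norm, actions: np.ndarray, H: np.ndarray, h_star: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(p_c mut->res, p_c res->mut) for a batch of mutants."""
    coop_mut = (actions == 0).astype(float)
    coop_res = (resident.action == 0).astype(float)
    p_mr = np.einsum("mx,mxy,y->m", H, coop_mut, h_star)
    p_rm = np.einsum("x,xy,my->m", h_star, coop_res, H)
    return p_mr, p_rm


def mutant_payoff(
    resident: Norm,
    mutant_action: np.ndarray | int,
    h_star: np.ndarray,
    H_star: np.ndarray,
    params: GameParams,
    err: ErrorModel,
) -> float:
    """Rare-mutant payoff ``p_c(res->mut)(1-mu_e) b - p_c(mut->res)(1-mu_e) c``."""
    if isinstance(mutant_action, (int, np.integer)):
        mutant_action = Norm.from_ints(resident.k, 0, int(mutant_action)).action
    actions = np.asarray(mutant_action, dtype=np.int64)[None]
    p_mr, p_rm = _mutant_coop_rates(
        resident, actions, np.asarray(H_star, float)[None], np.asarray(h_star, float)
    )
    return float(p_rm[0] * (1.0 - err.mu_e) * params.b - p_mr[0] * (1.0 - err.mu_e) * params.c)


# ---------------------------------------------------------------------------
# CESS verdicts
# ---------------------------------------------------------------------------


def _mutant_statistics(
    resident: Norm, h_star: np.ndarray, err: ErrorModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """H*, cooperation rates and action tables for every action rule."""
    actions = _all_action_tables(resident.k)
    M = _mutant_chains(resident, h_star, err, actions)
    H = _chain_stationary(M)
    p_mr, p_rm = _mutant_coop_rates(resident, actions, H, h_star)
    return actions, H, p_mr, p_rm


def _verdict_from_payoffs(
    resident: Norm,
    stat: StationaryResult,
    actions: np.ndarray,
    H: np.ndarray,
    p_mr: np.ndarray,
    p_rm: np.ndarray,
    params: GameParams,
    err: ErrorModel,
    threshold: float,
) -> EssReport:
    pi_res = resident_payoff(stat.p_c, params, err)
    pi_mut = p_rm * (1.0 - err.mu_e) * params.b - p_mr * (1.0 - err.mu_e) * params.c
    own = resident.action_int
    mask = np.ones(len(pi_mut), dtype=bool)
    mask[own] = False
    margin = pi_res - pi_mut
    slack = STRICTNESS_RTOL * max(1.0, abs(pi_res))
    invaders = np.flatnonzero(mask & (margin <= slack))
    best_idx = int(np.flatnonzero(mask)[np.argmax(pi_mut[mask])])
    best = MutantResult(
        action_int=best_idx,
        H_star=H[best_idx],
        payoff=float(pi_mut[best_idx]),
        p_c_mut_to_res=float(p_mr[best_idx]),
        p_c_res_to_mut=float(p_rm[best_idx]),
    )
    verdict = "invadable" if len(invaders) else "CESS"
    return EssReport(
        verdict=verdict,
        resident_payoff=pi_res,
        p_c=stat.p_c,
        stationary=stat,
        best_mutant=best,
        params=params,
        err=err,
        threshold=threshold,
    )


def is_cess(
    norm: Norm,
    params: GameParams,
    err: ErrorModel | None = None,
    p_c_threshold: float = DEFAULT_PC_THRESHOLD,
    stat: StationaryResult | None = None,
) -> EssReport:
    """Full CESS test of a resident norm at one (b, c) point.

    Computes the resident stationary state, gates on the cooperation level,
    and compares the resident payoff against every alternative action rule.
    A precomputed ``stat`` may be supplied to avoid re-integration.
    """
    err = err or ErrorModel()
    if stat is None:
        stat = stationary(norm, err)
    if stat.p_c < p_c_threshold:
        return EssReport(
            verdict="fails_cooperation_threshold",
            resident_payoff=resident_payoff(stat.p_c, params, err),
            p_c=stat.p_c,
            stationary=stat,
            best_mutant=None,
            params=params,
            err=err,
            threshold=p_c_threshold,
        )
    actions, H, p_mr, p_rm = _mutant_statistics(norm, stat.h_star, err)
    return _verdict_from_payoffs(
        norm, stat, actions, H, p_mr, p_rm, params, err, p_c_threshold
    )


def core_set_filter(
    norm: Norm,
    bc_grid: tuple[float, ...] = DEFAULT_BC_GRID,
    err: ErrorModel | None = None,
    p_c_threshold: float = DEFAULT_PC_THRESHOLD,
    c: float = 1.0,
    stat: StationaryResult | None = None,
) -> tuple[bool, dict[float, EssReport]]:
    """CESS at *every* benefit-to-cost ratio of the grid (intersection).

    The stationary state and the mutant reputation chains do not depend on
    (b, c), so they are computed once and only the payoff comparison is
    re-evaluated per ratio.
    """
    if not bc_grid:
        raise ValueError("bc_grid must be non-empty")
    err = err or ErrorModel()
    if stat is None:
        stat = stationary(norm, err)
    reports: dict[float, EssReport] = {}
    if stat.p_c < p_c_threshold:
        for ratio in bc_grid:
            reports[ratio] = is_cess(
                norm, GameParams(b=ratio * c, c=c), err, p_c_threshold, stat=stat
            )
        return False, reports
    mutstats = _mutant_statistics(norm, stat.h_star, err)
    ok = True
    for ratio in bc_grid:
        report = _verdict_from_payoffs(
            norm, stat, *mutstats, GameParams(b=ratio * c, c=c), err, p_c_threshold
        )
        reports[ratio] = report
        ok = ok and report.is_cess
    return ok, reports
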