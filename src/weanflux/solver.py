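"""Steady-state community FBA with a cooperative growth trade-off.

The model is the usual constrained linear program: find fluxes ``v`` with
``S v = 0`` inside the flux bounds, maximizing community growth
``mu_c = sum_i a_i mu_i`` (the abundance-weighted sum of taxon growth rates).

Because the community optimum is typically achieved by letting the best
competitors grow alone, growth is redistributed with a cooperative trade-off
computed in two steps:

1. maximize ``mu_c`` to obtain ``mu_c_max``;
2. among all flux states that still achieve at least ``alpha * mu_c_max``
   community growth (``alpha`` in (0, 1]), pick the one minimizing
   ``sum_i mu_i**2``.

Step 2 is a convex QP whose unconstrained-in-the-polytope solution is the
closed form ``mu_i = alpha * mu_c_max * a_i / (a^T a)`` — growth proportional
to relative abundance. It is solved exactly with Wolfe's minimum-norm-point
algorithm on the projection of the flux polytope onto the growth-rate
coordinates, using the LP solver as linear-minimization oracle; this needs no
dedicated QP backend and terminates finitely. Remaining flux degeneracy (the
growth rates pin only part of the flux vector) is resolved by a minimal-total-
flux (L1) polish LP, which makes reported fluxes deterministic.

All linear programs go through scipy's HiGHS interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .community import CommunityModel

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNSTABLE = "numerically-unstable"


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs for the LP/QP pipeline.

    ``negligible_growth`` is the threshold (1/h) below which a taxon is
    counted as not growing; ``alpha_grid`` is the descending grid scanned by
    :func:`find_optimal_alpha`; ``step2_norm`` selects the allocation
    objective (``"l2"`` is the cooperative trade-off; ``"l1"`` is exposed for
    sensitivity analyses only).
    """

    feasibility_tol: float = 1e-8
    optimality_tol: float = 1e-8
    negligible_growth: float = 1e-6
    alpha_grid: Tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
    step2_norm: str = "l2"
    early_exit: bool = True

    def __post_init__(self):
        if self.feasibility_tol <= 0 or self.optimality_tol <= 0:
            raise ValueError("tolerances must be positive")
        if list(self.alpha_grid) != sorted(self.alpha_grid, reverse=True):
            raise ValueError("alpha_grid must be strictly descending")
        if len(set(self.alpha_grid)) != len(self.alpha_grid):
            raise ValueError("alpha_grid must be strictly descending")


@dataclass
class TradeoffSolution:
    """Result of a community FBA / cooperative trade-off solve."""

    mu_c: float
    mu_c_max: float
    mu_i: Dict[str, float]
    alpha: float
    fluxes: Dict[str, float]
    status: str
    x: Optional[np.ndarray] = None
    exchanges: Dict[Tuple[str, str], float] = field(default_factory=dict)
    alpha_trace: List[Tuple[float, int, str]] = field(default_factory=list)

    def growing_taxa(self, threshold: float = 1e-6) -> List[str]:
        return [t for t, mu in self.mu_i.items() if mu > threshold]


@dataclass
class ValidationReport:
    max_residual: float
    mu_identity_residual: float
    negligible_taxa: List[str]
    tradeoff_respected: bool


def _medium_dict(medium) -> Mapping[str, float]:
    fluxes = getattr(medium, "fluxes", None)
    if fluxes is not None:
        unit_state = getattr(medium, "unit_state", "per-hour")
        if unit_state != "per-hour":
            raise ValueError("medium must be converted to per-hour before solving")
        return fluxes
    return medium


def _solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[sparse.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res


def _solution_from_x(
    model: CommunityModel, x: np.ndarray, alpha: float, mu_c_max: float, status: str
) -> TradeoffSolution:
    mu_i = {t: float(x[j]) for t, j in model.biomass_cols.items()}
    return TradeoffSolution(
        mu_c=model.community_growth(mu_i),
        mu_c_max=mu_c_max,
        mu_i=mu_i,
        alpha=alpha,
        fluxes={name: float(v) for name, v in zip(model.col_names, x)},
        status=status,
        x=x,
        exchanges={
            key: float(x[j]) for key, j in model.exchange_cols.items()
        },
    )


def maximize_community_growth(
    model: CommunityModel, medium, config: SolverConfig = SolverConfig()
) -> TradeoffSolution:
    """Step 1: maximize ``mu_c`` on the given medium (plain community FBA).

    Returns a solution with ``alpha`` recorded as 1 and no allocation step;
    the supporting flux vector satisfies ``S v = 0`` to solver tolerance but
    its growth split across taxa may be degenerate.
    """
    lb, ub = model.bounds_with_medium(_medium_dict(medium))
    c = np.zeros(len(model.col_names))
    for taxon, j in model.biomass_cols.items():
        c[j] = -model.abundances[taxon]
    res = _solve_lp(c, model.S, lb, ub)
    if res.status == 2:
        return TradeoffSolution(
            mu_c=float("nan"),
            mu_c_max=float("nan"),
            mu_i={},
            alpha=1.0,
            fluxes={},
            status=STATUS_INFEASIBLE,
        )
    if res.status != 0:
        return TradeoffSolution(
            mu_c=float("nan"),
            mu_c_max=float("nan"),
            mu_i={},
            alpha=1.0,
            fluxes={},
            status=STATUS_UNSTABLE,
        )
    sol = _solution_from_x(model, res.x, 1.0, -float(res.fun), STATUS_OPTIMAL)
    return sol


def closed_form_allocation(
    abundances: np.ndarray, alpha: float, mu_c_max: float
) -> np.ndarray:
    """Unconstrained cooperative-trade-off optimum: ``alpha*mu_c_max*a/(a^T a)``."""
    a = np.asarray(abundances, dtype=float)
    return alpha * mu_c_max * a / float(a @ a)


def _min_norm_point(
    oracle: Callable[[np.ndarray], Optional[np.ndarray]],
    dim: int,
    tol: float = 1e-10,
    max_iter: int = 300,
) -> Tuple[Optional[np.ndarray], bool]:
    """Wolfe's minimum-norm-point algorithm over a polytope given by an LP oracle.

    ``oracle(d)`` returns a point of the polytope minimizing ``d @ p`` (or
    ``None`` if the underlying LP fails). Returns ``(point, converged)``.
    """
    p = oracle(np.ones(dim))
    if p is None:
        return None, False
    pts: List[np.ndarray] = [p]
    lams = np.array([1.0])
    x = p.copy()
    for _ in range(max_iter):
        p = oracle(x)
        if p is None:
            return x, False
        gap = float(x @ x - x @ p)
        if gap <= tol * max(1.0, float(x @ x)):
            return x, True
        pts.append(p)
        lams = np.append(lams, 0.0)
        # minor cycle: project the origin onto aff(pts), trimming the corral
        while True:
            P = np.column_stack(pts)
            m = P.shape[1]
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = 2.0 * (P.T @ P)
            A[:m, m] = 1.0
            A[m, :m] = 1.0
            rhs = np.zeros(m + 1)
            rhs[m] = 1.0
            w = np.linalg.lstsq(A, rhs, rcond=None)[0][:m]
            if np.all(w > -1e-12):
                x = P @ w
                lams = np.clip(w, 0.0, None)
                break
            neg = w < 0
            theta = float(np.min(lams[neg] / (lams[neg] - w[neg])))
            lams = (1.0 - theta) * lams + theta * w
            keep = lams > 1e-12
            if not np.any(keep):
                keep[int(np.argmax(lams))] = True
            pts = [pts[i] for i in np.flatnonzero(keep)]
            lams = lams[keep]
            lams = lams / lams.sum()
            x = np.column_stack(pts) @ lams
    return x, False


def _polish_fluxes(
    model: CommunityModel,
    lb: np.ndarray,
    ub: np.ndarray,
    mu: np.ndarray,
    clamp: float = 1e-7,
):
    """Fix growth rates (within ``clamp``) and minimize total |flux| (L1)."""
    n = len(model.col_names)
    lb2 = lb.copy()
    ub2 = ub.copy()
    for i, (taxon, _, _) in enumerate(model.taxa):
        j = model.biomass_cols[taxon]
        target = max(mu[i], lb[j])
        lb2[j] = max(lb[j], target - clamp)
        ub2[j] = min(ub[j], target + clamp)
        if lb2[j] > ub2[j]:
            lb2[j] = ub2[j]
    # L1 via auxiliary variables: min sum t, with  x - t <= 0 and -x - t <= 0
    eye = sparse.identity(n, format="csr")
    A_eq = sparse.hstack([model.S, sparse.csr_matrix(model.S.shape)], format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])], format="csr"
    )
    b_ub = np.zeros(2 * n)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    big = float(np.max(np.abs(np.concatenate([lb2, ub2])))) + 1.0
    lb_full = np.concatenate([lb2, np.zeros(n)])
    ub_full = np.concatenate([ub2, np.full(n, big)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lb_full, ub_full]),
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


def cooperative_tradeoff(
    model: CommunityModel,
    medium,
    alpha: float,
    config: SolverConfig = SolverConfig(),
    mu_c_max: Optional[float] = None,
) -> TradeoffSolution:
    """Two-step cooperative trade-off at a fixed ``alpha`` in (0, 1].

    Step 1 computes ``mu_c_max`` (unless supplied); step 2 minimizes
    ``sum_i mu_i**2`` subject to all FBA constraints plus
    ``sum_i a_i mu_i >= alpha * mu_c_max``. If the allocation cannot be
    solved to optimality the partial solution is returned with status
    ``"numerically-unstable"``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    medium_map = _medium_dict(medium)
    if mu_c_max is None:
        step1 = maximize_community_growth(model, medium_map, config)
        if step1.status != STATUS_OPTIMAL:
            return step1
        mu_c_max = step1.mu_c_max

    lb, ub = model.bounds_with_medium(medium_map)
    a = model.abundance_vector()
    bm_cols = np.array([model.biomass_cols[t] for t, _, _ in model.taxa])
    n = len(model.col_names)

    # tiny relative slack so step 2 stays feasible at alpha=1 despite the
    # finite precision of the step-1 optimum
    slack = min(9e-7, 1e-9 * (1.0 + abs(mu_c_max)))
    target = alpha * mu_c_max - slack

    if target <= 0:
        mu = np.zeros(len(a))
        converged = True
    elif config.step2_norm == "l1":
        c = np.zeros(n)
        c[bm_cols] = 1.0
        row = sparse.csr_matrix(
            (-a, (np.zeros(len(a), dtype=int), bm_cols)), shape=(1, n)
        )
        res = _solve_lp(c, model.S, lb, ub, A_ub=row, b_ub=np.array([-target]))
        if res.status != 0:
            return TradeoffSolution(
                mu_c=float("nan"),
                mu_c_max=mu_c_max,
                mu_i={},
                alpha=alpha,
                fluxes={},
                status=STATUS_INFEASIBLE if res.status == 2 else STATUS_UNSTABLE,
            )
        mu = res.x[bm_cols]
        converged = True
    else:
        row = sparse.csr_matrix(
            (-a, (np.zeros(len(a), dtype=int), bm_cols)), shape=(1, n)
        )

        def oracle(direction: np.ndarray) -> Optional[np.ndarray]:
            c = np.zeros(n)
            c[bm_cols] = direction
            res = _solve_lp(c, model.S, lb, ub, A_ub=row, b_ub=np.array([-target]))
            if res.status != 0:
                return None
            return res.x[bm_cols]

        mu, converged = _min_norm_point(oracle, len(a))
        if mu is None:
            return TradeoffSolution(
                mu_c=float("nan"),
                mu_c_max=mu_c_max,
                mu_i={},
                alpha=alpha,
                fluxes={},
                status=STATUS_INFEASIBLE,
            )

    x = _polish_fluxes(model, lb, ub, np.asarray(mu))
    if x is None:
        # keep the allocation but flag that no supporting flux vector was pinned
        mu_map = {t: float(m) for (t, _, _), m in zip(model.taxa, mu)}
        return TradeoffSolution(
            mu_c=model.community_growth(mu_map),
            mu_c_max=mu_c_max,
            mu_i=mu_map,
            alpha=alpha,
            fluxes={},
            status=STATUS_UNSTABLE,
        )
    status = STATUS_OPTIMAL if converged else STATUS_UNSTABLE
    sol = _solution_from_x(model, x, alpha, mu_c_max, status)
    return sol


def find_optimal_alpha(
    model: CommunityModel, medium, config: SolverConfig = SolverConfig()
) -> TradeoffSolution:
    """Scan the descending ``alpha_grid`` and keep the most cooperative solution.

    Returns the solution at the largest alpha maximizing the number of taxa
    growing above ``negligible_growth``; the scan stops early once every
    taxon grows (no lower alpha can do better). The full scan trace
    ``(alpha, growing count, status)`` is recorded on the solution.
    """
    if not config.alpha_grid:
        raise ValueError("alpha_grid must be nonempty")
    medium_map = _medium_dict(medium)
    step1 = maximize_community_growth(model, medium_map, config)
    if step1.status != STATUS_OPTIMAL:
        step1.alpha_trace = [(a, 0, step1.status) for a in config.alpha_grid]
        return step1

    best: Optional[TradeoffSolution] = None
    best_count = -1
    trace: List[Tuple[float, int, str]] = []
    for alpha in config.alpha_grid:
        sol = cooperative_tradeoff(
            model, medium_map, alpha, config, mu_c_max=step1.mu_c_max
        )
        count = (
            len(sol.growing_taxa(config.negligible_growth))
            if sol.status != STATUS_INFEASIBLE
            else 0
        )
        trace.append((alpha, count, sol.status))
        if sol.status != STATUS_INFEASIBLE and count > best_count:
            best, best_count = sol, count
        if config.early_exit and count == model.n_taxa:
            break
    if best is None:
        step1_fail = TradeoffSolution(
            mu_c=float("nan"),
            mu_c_max=step1.mu_c_max,
            mu_i={},
            alpha=config.alpha_grid[-1],
            fluxes={},
            status=STATUS_INFEASIBLE,
        )
        step1_fail.alpha_trace = trace
        return step1_fail
    best.alpha_trace = trace
    return best


def check_solution(
    model: CommunityModel, sol: TradeoffSolution, config: SolverConfig = SolverConfig()
) -> ValidationReport:
    """Validate a solution: mass-balance residual, growth identity, trade-off."""
    if sol.x is not None:
        residual = float(np.max(np.abs(model.S @ sol.x))) if model.S.shape[0] else 0.0
    else:
        residual = float("nan")
    mu_c_from_parts = model.community_growth(sol.mu_i)
    negligible = [
        t for t, mu in sol.mu_i.items() if mu <= config.negligible_growth
    ]
    return ValidationReport(
        max_residual=residual,
        mu_identity_residual=abs(sol.mu_c - mu_c_from_parts),
        negligible_taxa=negligible,
        tradeoff_respected=(len(negligible) == 0 and bool(sol.mu_i)),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def solution_to_json(sol: TradeoffSolution, model: CommunityModel, path: str) -> None:
    report = check_solution(model, sol)
    payload = {
        "mu_c": sol.mu_c,
        "mu_c_max": sol.mu_c_max,
        "mu_i": sol.mu_i,
        "alpha": sol.alpha,
        "status": sol.status,
        "max_residual": report.max_residual,
        "mu_identity_residual": report.mu_identity_residual,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def fluxes_to_tsv(sol: TradeoffSolution, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction\ttaxon\tflux\n")
        for name in sorted(sol.fluxes):
            if "::" in name:
                left, right = name.split("::", 1)
                taxon, rxn = ("", right) if left == "EX" else (left, right)
                if left == "EX":
                    rxn = f"EX_{right}"
            else:  # pragma: no cover - names always carry the :: separator
                taxon, rxn = "", name
            fh.write(f"{rxn}\t{taxon}\t{sol.fluxes[name]!r}\n")
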