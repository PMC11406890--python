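"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP/QP code paths: linear programs are
solved by vertex enumeration in the null space of the equality constraints,
and the quadratic allocation by exhaustive active-set enumeration on a dense
KKT system. They are only tractable for toy communities (a handful of
degrees of freedom), which is exactly how they are used.
"""

from __future__ import annotations

from itertools import combinations as _combinations

import numpy as np
from scipy.linalg import null_space

from weanflux.community import AbundanceProfile, CommunityModel, assemble_community
from weanflux.synth import ArchetypeSpec, gen_taxon


def _z_polytope(model: CommunityModel, medium, extra_row=None, extra_rhs=None):
    """Reduce {S x = 0, lb <= x <= ub (+ optional a.x <= b)} to G z <= h with
    x = N z."""
    A = model.S.toarray()
    N = null_space(A)
    lb, ub = model.bounds_with_medium(medium)
    G = np.vstack([N, -N])
    h = np.concatenate([ub, -lb])
    if extra_row is not None:
        G = np.vstack([G, extra_row @ N])
        h = np.append(h, extra_rhs)
    return N, G, h


def lp_max_by_vertex_enumeration(model: CommunityModel, medium, c) -> float:
    """Maximize ``c @ x`` over the flux polytope by enumerating vertices."""
    N, G, h = _z_polytope(model, medium)
    d = N.shape[1]
    cN = np.asarray(c) @ N
    best = 0.0  # z = 0 is always feasible (all bound intervals contain 0)
    if d == 0:
        return best
    m = len(h)
    for idx in _combinations(range(m), d):
        Gs = G[list(idx)]
        try:
            z = np.linalg.solve(Gs, h[list(idx)])
        except np.linalg.LinAlgError:
            continue
        if np.all(G @ z <= h + 1e-8):
            best = max(best, float(cN @ z))
    return best


def qp_min_growth_norm(model: CommunityModel, medium, target: float):
    """Minimize ``sum_i mu_i**2`` subject to the flux polytope and
    ``sum_i a_i mu_i >= target`` by exhaustive active-set enumeration.

    Returns the optimal growth-rate vector (taxon order as ``model.taxa``).
    """
    a = model.abundance_vector()
    bm = np.array([model.biomass_cols[t] for t, _, _ in model.taxa])
    n = len(model.col_names)
    row = np.zeros(n)
    row[bm] = -a
    N, G, h = _z_polytope(model, medium, extra_row=row, extra_rhs=-target)
    d = N.shape[1]
    M = N[bm, :]  # mu = M z
    H = 2.0 * (M.T @ M) + 1e-12 * np.eye(d)
    best_obj = np.inf
    best_mu = None
    m = len(h)
    for r in range(0, d + 1):
        for idx in _combinations(range(m), r):
            Gs = G[list(idx)]
            kkt = np.zeros((d + r, d + r))
            kkt[:d, :d] = H
            if r:
                kkt[:d, d:] = Gs.T
                kkt[d:, :d] = Gs
            rhs = np.concatenate([np.zeros(d), h[list(idx)]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            z = sol[:d]
            if np.all(G @ z <= h + 1e-8):
                mu = M @ z
                obj = float(mu @ mu)
                if obj < best_obj - 1e-15:
                    best_obj = obj
                    best_mu = mu
    return best_mu


def random_toy_community(rng: np.random.Generator):
    """A random 1–3 taxon community (each taxon <= 6 reactions) with medium."""
    k = int(rng.integers(1, 4))
    n_sub = int(rng.integers(1, k + 1))
    substrates = [f"S{i}" for i in range(n_sub)]
    models = []
    specs = {}
    for i in range(k):
        sub = substrates[int(rng.integers(0, n_sub))]
        yield_gdw = float(rng.uniform(0.2, 1.0))
        prods = {}
        if rng.random() < 0.7:
            prods[f"P{i}"] = float(rng.uniform(0.5, 2.0))
        spec = ArchetypeSpec("generalist", {sub: (yield_gdw, prods)})
        specs[f"T{i}"] = spec
        models.append(gen_taxon(spec, f"T{i}"))
    raw = rng.dirichlet(np.ones(k))
    profile = AbundanceProfile({f"T{i}": float(raw[i]) for i in range(k)})
    community = assemble_community(models, profile)
    medium = {s: float(rng.uniform(1.0, 20.0)) for s in substrates}
    return community, profile, medium
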