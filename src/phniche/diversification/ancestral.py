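"""Marginal ancestral-state reconstruction under a fitted SSE model.

Uses the standard two-pass conditional-combination scheme: a rootward
(post-order) pass stores the branch-bottom and branch-top partial
likelihood vectors D and the extinction trajectories E along every branch;
a tipward (pre-order) pass propagates the "rest of tree" vector F through
each branch with the transposed flow operator (the D equation is linear in
D given E, so its adjoint is integrated with the time-mirrored transposed
coefficient matrix).  The marginal probability of state i at an internal
node is proportional to F_i x D_i at that node; hidden states are summed
out per examined state.  This is one of several internally consistent SSE
reconstruction conventions; at lambda = mu = 0 it reduces exactly to the
classical Mk marginal reconstruction.

This pass runs once per fitted model, so it uses scipy's integrator rather
than the jitted pruning kernel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .fit import SSEFit
from .likelihood import LabeledPhylogeny
from .models import STATES

__all__ = ["ancestral_states"]


def _forward_pass(phylo, spec, params, rtol, atol, include_merge=True):
    lam, mu, Q = spec.rates(params)
    qsum = Q.sum(axis=1)
    n = spec.n_states

    def rhs(_t, y):
        E, D = y[:n], y[n:]
        tot = lam + mu + qsum
        return np.concatenate(
            [
                mu - tot * E + lam * E**2 + Q @ E,
                -tot * D + 2 * lam * E * D + Q @ D,
            ]
        )

    tipD = phylo.tip_D_init(spec)
    tipE = np.tile(1.0 - spec.rho, spec.n_hidden)
    nn = phylo.n_nodes
    D_bottom = np.zeros((nn, n))  # normalised, at node (tip init or merged)
    E_bottom = np.zeros((nn, n))
    D_top = np.zeros((nn, n))
    E_top = np.zeros((nn, n))
    sols = [None] * nn
    for idx in range(nn):
        l = phylo.post_left[idx]
        if l < 0:
            D0, E0 = tipD[idx].copy(), tipE.copy()
        else:
            r = phylo.post_right[idx]
            D0 = D_top[l] * D_top[r]
            if include_merge:
                D0 = D0 * lam
            E0 = E_top[l]
        s = D0.sum()
        if s <= 0:
            raise ValueError("zero partial likelihood during forward pass")
        D0 = D0 / s
        D_bottom[idx], E_bottom[idx] = D0, E0
        t = phylo.blen[idx]
        if t > 0:
            sol = solve_ivp(
                rhs,
                (0.0, t),
                np.concatenate([E0, D0]),
                rtol=rtol,
                atol=atol,
                dense_output=True,
            )
            if not sol.success:
                raise RuntimeError(f"branch integration failed at node {idx}")
            sols[idx] = sol
            E_top[idx], D_top[idx] = sol.y[:n, -1], sol.y[n:, -1]
        else:
            E_top[idx], D_top[idx] = E0, D0
    return lam, mu, Q, qsum, D_bottom, E_bottom, D_top, E_top, sols


def ancestral_states(
    phylo: LabeledPhylogeny,
    fit: SSEFit,
    root_mode: str = "obs",
    condition_on_survival: bool = True,
    include_speciation_merge: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Per-internal-node marginal probabilities of the four examined states.

    Rows are indexed by the node's post-order position in the flattened
    tree (the root is the last row); columns are the examined states; rows
    sum to 1.  Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("ancestral reconstruction requires a converged fit")
    spec = fit.spec
    n = spec.n_states
    lam, mu, Q, qsum, D_bottom, E_bottom, D_top, E_top, sols = _forward_pass(
        phylo, spec, fit.params, rtol, atol, include_merge=include_speciation_merge
    )

    def adjoint(idx, u):
        """F_bottom = Phi^T u for the branch above node idx."""
        T = phylo.blen[idx]
        if T <= 0 or sols[idx] is None:
            return u
        sol = sols[idx]

        def rhs(s, z):
            E = sol.sol(T - s)[:n]
            tot = lam + mu + qsum
            A = np.diag(-tot + 2.0 * lam * E) + Q
            return A.T @ z

        res = solve_ivp(rhs, (0.0, T), u, rtol=rtol, atol=atol)
        if not res.success:
            raise RuntimeError(f"adjoint integration failed at node {idx}")
        return res.y[:, -1]

    nn = phylo.n_nodes
    root = nn - 1
    F = np.zeros((nn, n))
    cond = 1.0 / (lam * (1.0 - E_top[root]) ** 2) if condition_on_survival else np.ones(n)
    D_adj = D_top[root] * cond
    if root_mode == "obs":
        w = D_adj / D_adj.sum()
    elif root_mode == "flat":
        w = np.full(n, 1.0 / n)
    else:
        raise ValueError(f"unknown root_mode {root_mode!r}")
    F[root] = w * cond
    # pre-order = reverse post-order
    for idx in range(nn - 1, -1, -1):
        l = phylo.post_left[idx]
        if l < 0:
            continue
        r = phylo.post_right[idx]
        for child, sib in ((l, r), (r, l)):
            u = F[idx] * D_top[sib]
            if include_speciation_merge:
                u = u * lam
            s = u.sum()
            if s > 0:
                u = u / s
            F[child] = adjoint(child, u)

    rows = {}
    for idx in range(nn):
        if phylo.post_left[idx] < 0:
            continue
        m = F[idx] * D_bottom[idx]
        tot = m.sum()
        if tot <= 0:
            raise ValueError(f"degenerate marginal at node {idx}")
        m = m / tot
        examined = m.reshape(spec.n_hidden, 4).sum(axis=0)
        rows[idx] = examined
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(STATES))
    out.index.name = "postorder_node"
    return out
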