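"""SSE likelihood: pruning along the tree with per-branch ODE integration.

For each joint state *i*, two quantities are propagated rootward along every
branch: ``E_i(t)``, the probability that a lineage alive at time *t* before
the present in state *i* leaves no sampled descendants, and ``D_i(t)``, the
density of the observed subtree conditional on the branch being in state
*i* at time *t*:

    dE_i/dt = mu_i - (lambda_i + mu_i + sum_j q_ij) E_i
              + lambda_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + sum_j q_ij) D_i
              + 2 lambda_i E_i D_i + sum_j q_ij D_j

Tips are initialised with D_i = rho_i for states compatible with the
observed character (all hidden layers are compatible) and E_i = 1 - rho_i;
at internal nodes D_i <- D_i^left * D_i^right * lambda_i.  D is renormalised
at every node with a log accumulator to avoid underflow.  At the root the
states are combined either with weights proportional to D (the observed-
state weighting) or flat weights, optionally conditioning on survival of
both crown lineages.

The per-branch integrator is an adaptive Cash-Karp Runge-Kutta 4(5)
compiled with numba; the whole post-order pass runs inside one jitted
kernel, which is what makes multi-start maximum likelihood on
several-hundred-tip trees tractable.  ``scipy.integrate.solve_ivp`` is used
as an independent cross-check in the test suite, not in this path.
"""

from __future__ import annotations

import hashlib
from typing import Dict, Iterable, Mapping, Optional, Set, Union

import dendropy
import numpy as np
from numba import njit

from .models import N_EXAMINED, STATES, SSEModelSpec

__all__ = ["LabeledPhylogeny", "sse_loglik", "extinction_prob"]

_ULTRAMETRIC_RTOL = 1e-6


class LabeledPhylogeny:
    """Rooted, bifurcating, ultrametric tree plus tip -> state assignments.

    ``tip_states`` maps each tip label to a state code in ``STATES`` or to
    an iterable of codes for ambiguous tips.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tip_states: Mapping[str, Union[str, Iterable[str]]],
    ) -> None:
        self.tree = tree
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        missing = [t for t in labels if t not in tip_states]
        if missing:
            raise ValueError(f"tips without a state entry: {missing[:5]}...")
        self.tip_states: Dict[str, Set[str]] = {}
        for t in labels:
            s = tip_states[t]
            codes = {s} if isinstance(s, str) else set(s)
            bad = codes - set(STATES)
            if bad or not codes:
                raise ValueError(f"tip {t!r}: invalid state(s) {sorted(bad)}")
            self.tip_states[t] = codes
        for node in tree.preorder_internal_node_iter():
            nch = len(node.child_nodes())
            if nch != 2:
                raise ValueError(
                    f"tree must be bifurcating; node with {nch} children found"
                )
        # ultrametricity: relative spread of tip depths
        depths = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
            depths[node] = d
        tipd = np.array([depths[lf] for lf in leaves])
        self.depth = float(tipd.max())
        if self.depth <= 0:
            raise ValueError("tree has zero depth")
        if (tipd.max() - tipd.min()) / self.depth > _ULTRAMETRIC_RTOL:
            raise ValueError(
                f"tree is not ultrametric (tip depth spread "
                f"{(tipd.max() - tipd.min()) / self.depth:.2e} relative)"
            )
        self._flatten()

    def _flatten(self) -> None:
        """Post-order arrays for the pruning kernel."""
        nodes = list(self.tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.post_left = -np.ones(n, dtype=np.int64)
        self.post_right = -np.ones(n, dtype=np.int64)
        self.blen = np.zeros(n)
        self.tip_label = [None] * n
        for i, node in enumerate(nodes):
            self.blen[i] = node.edge.length or 0.0
            ch = node.child_nodes()
            if ch:
                self.post_left[i] = index[id(ch[0])]
                self.post_right[i] = index[id(ch[1])]
            else:
                self.tip_label[i] = node.taxon.label
        self.n_nodes = n
        self.n_tips = sum(1 for lbl in self.tip_label if lbl is not None)

    @property
    def data_hash(self) -> str:
        s = self.tree.as_string(schema="newick")
        st = ";".join(f"{k}={','.join(sorted(v))}" for k, v in sorted(self.tip_states.items()))
        return hashlib.sha256((s + "|" + st).encode()).hexdigest()[:16]

    def tip_D_init(self, spec: SSEModelSpec) -> np.ndarray:
        """(n_nodes, n_states) initial D: rho for compatible states, else 0."""
        ns = spec.n_states
        out = np.zeros((self.n_nodes, ns))
        for i, lbl in enumerate(self.tip_label):
            if lbl is None:
                continue
            for code in self.tip_states[lbl]:
                e = STATES.index(code)
                for h in range(spec.n_hidden):
                    out[i, 4 * h + e] = spec.rho[e]
        return out


# ---------------------------------------------------------------------------
# numba kernel: Cash-Karp RK45 with step control + post-order pruning pass

@njit(cache=True)
def _rhs(y, lam, mu, Q, qsum, n):
    out = np.empty(2 * n)
    E = y[:n]
    D = y[n:]
    QE = Q.dot(E)
    QD = Q.dot(D)
    for i in range(n):
        tot = lam[i] + mu[i] + qsum[i]
        out[i] = mu[i] - tot * E[i] + lam[i] * E[i] * E[i] + QE[i]
        out[n + i] = -tot * D[i] + 2.0 * lam[i] * E[i] * D[i] + QD[i]
    return out


@njit(cache=True)
def _integrate_branch(y0, t_total, lam, mu, Q, qsum, rtol, atol):
    """Adaptive Cash-Karp RK45 from 0 to t_total; returns the end state."""
    n = lam.shape[0]
    y = y0.copy()
    t = 0.0
    h = t_total
    k = np.empty((6, 2 * n))
    for _ in range(100000):
        if t >= t_total:
            break
        if t + h > t_total:
            h = t_total - t
        k[0] = _rhs(y, lam, mu, Q, qsum, n)
        yt = y + h * (0.2 * k[0])
        k[1] = _rhs(yt, lam, mu, Q, qsum, n)
        yt = y + h * (0.075 * k[0] + 0.225 * k[1])
        k[2] = _rhs(yt, lam, mu, Q, qsum, n)
        yt = y + h * (0.3 * k[0] - 0.9 * k[1] + 1.2 * k[2])
        k[3] = _rhs(yt, lam, mu, Q, qsum, n)
        yt = y + h * (
            -11.0 / 54.0 * k[0] + 2.5 * k[1] - 70.0 / 27.0 * k[2] + 35.0 / 27.0 * k[3]
        )
        k[4] = _rhs(yt, lam, mu, Q, qsum, n)
        yt = y + h * (
            1631.0 / 55296.0 * k[0]
            + 175.0 / 512.0 * k[1]
            + 575.0 / 13824.0 * k[2]
            + 44275.0 / 110592.0 * k[3]
            + 253.0 / 4096.0 * k[4]
        )
        k[5] = _rhs(yt, lam, mu, Q, qsum, n)
        y5 = y + h * (
            37.0 / 378.0 * k[0]
            + 250.0 / 621.0 * k[2]
            + 125.0 / 594.0 * k[3]
            + 512.0 / 1771.0 * k[5]
        )
        y4 = y + h * (
            2825.0 / 27648.0 * k[0]
            + 18575.0 / 48384.0 * k[2]
            + 13525.0 / 55296.0 * k[3]
            + 277.0 / 14336.0 * k[4]
            + 0.25 * k[5]
        )
        # component-wise error against mixed tolerance
        errmax = 0.0
        for i in range(2 * n):
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(y5[i] - y4[i]) / sc
            if e > errmax:
                errmax = e
        if errmax <= 1.0:
            t += h
            y = y5
            fac = 5.0 if errmax == 0.0 else min(5.0, 0.9 * errmax ** (-0.2))
            h *= fac
        else:
            h *= max(0.1, 0.9 * errmax ** (-0.25))
        if not np.isfinite(errmax):
            return y * np.nan
    return y


@njit(cache=True)
def _pruning_pass(
    post_left,
    post_right,
    blen,
    tipD,
    tipE,
    lam,
    mu,
    Q,
    qsum,
    rtol,
    atol,
    include_merge,
):
    """Post-order pruning.  Returns (log_scale, E_root, D_root_normalised,
    E_top, D_top) where the *_top arrays hold branch-end vectors per node."""
    n_nodes = post_left.shape[0]
    n = lam.shape[0]
    E_top = np.zeros((n_nodes, n))
    D_top = np.zeros((n_nodes, n))
    logcum = 0.0
    for idx in range(n_nodes):
        l = post_left[idx]
        y0 = np.empty(2 * n)
        if l < 0:
            y0[:n] = tipE
            y0[n:] = tipD[idx]
        else:
            r = post_right[idx]
            for i in range(n):
                d = D_top[l, i] * D_top[r, i]
                if include_merge:
                    d *= lam[i]
                y0[n + i] = d
            y0[:n] = E_top[l]
        s = 0.0
        for i in range(n):
            s += y0[n + i]
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf, E_top, D_top
        for i in range(n):
            y0[n + i] /= s
        logcum += np.log(s)
        if blen[idx] > 0.0:
            y1 = _integrate_branch(y0, blen[idx], lam, mu, Q, qsum, rtol, atol)
        else:
            y1 = y0
        ok = True
        for i in range(2 * n):
            if not np.isfinite(y1[i]):
                ok = False
        if not ok:
            return -np.inf, E_top, D_top
        E_top[idx] = y1[:n]
        D_top[idx] = np.maximum(y1[n:], 0.0)
    return logcum, E_top, D_top


def extinction_prob(lam: float, mu: float, t, rho: float = 1.0):
    """Closed-form single-state extinction probability E(t).

    For a birth-death process with speciation ``lam``, extinction ``mu`` and
    sampling fraction ``rho``:  with rho = 1,
    E(t) = mu (1 - exp(-(lam-mu) t)) / (lam - mu exp(-(lam-mu) t)),
    degenerating to mu t / (1 + mu t) when lam == mu.
    """
    t = np.asarray(t, dtype=float)
    if rho != 1.0:
        raise NotImplementedError("closed form implemented for rho = 1 only")
    if np.isclose(lam, mu):
        out = mu * t / (1.0 + mu * t)
    else:
        ert = np.exp(-(lam - mu) * t)
        out = mu * (1.0 - ert) / (lam - mu * ert)
    return float(out) if out.ndim == 0 else out


def sse_loglik(
    phylo: LabeledPhylogeny,
    spec: SSEModelSpec,
    params,
    root_mode: str = "obs",
    condition_on_survival: bool = True,
    include_speciation_merge: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    return_partials: bool = False,
):
    """Log likelihood (nats) of the labelled tree under an SSE model.

    ``root_mode`` is ``"obs"`` (root weights proportional to the root D
    values) or ``"flat"`` (uniform weights).  ``condition_on_survival``
    divides per-state root partials by lambda_i (1 - E_i)^2 before
    weighting.  ``include_speciation_merge=False`` drops the lambda factor
    at node merges; combined with lambda = mu = 0, a flat root and no
    conditioning, the likelihood reduces exactly to the Mk character
    likelihood (used for validation).
    """
    lam, mu, Q = spec.rates(params)
    qsum = Q.sum(axis=1)
    tipD = phylo.tip_D_init(spec)
    tipE = np.tile(1.0 - spec.rho, spec.n_hidden)
    logcum, E_top, D_top = _pruning_pass(
        phylo.post_left,
        phylo.post_right,
        phylo.blen,
        tipD,
        tipE,
        lam,
        mu,
        Q,
        qsum,
        rtol,
        atol,
        include_speciation_merge,
    )
    if not np.isfinite(logcum):
        return (-np.inf, None, None) if return_partials else -np.inf
    root = phylo.n_nodes - 1
    D_root = D_top[root].copy()
    E_root = E_top[root]
    if condition_on_survival:
        denom = lam * (1.0 - E_root) ** 2
        if np.any(denom <= 0):
            return (-np.inf, None, None) if return_partials else -np.inf
        D_root = D_root / denom
    if root_mode == "obs":
        tot = D_root.sum()
        if tot <= 0:
            return (-np.inf, None, None) if return_partials else -np.inf
        w = D_root / tot
    elif root_mode == "flat":
        w = np.full(spec.n_states, 1.0 / spec.n_states)
    else:
        raise ValueError(f"unknown root_mode {root_mode!r}")
    L = float(np.dot(w, D_root))
    if L <= 0 or not np.isfinite(L):
        return (-np.inf, None, None) if return_partials else -np.inf
    ll = logcum + np.log(L)
    if return_partials:
        return ll, E_top, D_top
    return float(ll)
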