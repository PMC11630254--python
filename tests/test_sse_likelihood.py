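"""SSE likelihood engine against independent oracles and its invariants."""

import dendropy
import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from phniche.diversification import (
    LabeledPhylogeny,
    extinction_prob,
    make_spec,
    simulate_sse,
    sse_loglik,
)


def _mk_loglik_expm(phylo, Q, n=4):
    """Matrix-exponential pruning for the pure character (Mk) model."""
    Qg = Q - np.diag(Q.sum(axis=1))
    D = {}
    for idx in range(phylo.n_nodes):
        l = phylo.post_left[idx]
        if l < 0:
            d = np.zeros(n)
            code = next(iter(phylo.tip_states[phylo.tip_label[idx]]))
            d[STATE_IDX[code]] = 1.0
        else:
            r = phylo.post_right[idx]
            d = D[l] * D[r]
        t = phylo.blen[idx]
        D[idx] = expm(Qg * t) @ d if t > 0 else d
    return float(np.log(D[phylo.n_nodes - 1].sum() / n))


STATE_IDX = {"ES": 0, "EG": 1, "CS": 2, "CG": 3}


def test_zero_diversification_reduces_to_mk(three_tip_phylo, cr_m5_spec):
    """With lambda = mu = 0 (and the speciation merge factor disabled) the
    SSE likelihood equals the CTMC character likelihood computed with
    matrix exponentials."""
    params = np.array([0.0, 0.0, 0.05, 0.3, 0.1, 0.2])
    _, _, Q = cr_m5_spec.rates(params)
    oracle = _mk_loglik_expm(three_tip_phylo, Q)
    ll = sse_loglik(
        three_tip_phylo,
        cr_m5_spec,
        params,
        root_mode="flat",
        condition_on_survival=False,
        include_speciation_merge=False,
        rtol=1e-10,
        atol=1e-12,
    )
    assert ll == pytest.approx(oracle, abs=1e-6)


def test_extinction_probability_matches_closed_form(cr_m5_spec):
    """Equal lambda/mu, q = 0: E(t) along any branch equals
    mu (1 - e^{-(lam-mu)t}) / (lam - mu e^{-(lam-mu)t})."""
    tree = dendropy.Tree.get(data="((A:1.0,B:1.0):0.5,C:1.5):0.0;", schema="newick")
    phylo = LabeledPhylogeny(tree, {"A": "ES", "B": "ES", "C": "ES"})
    lam, mu = 1.0, 0.3
    params = np.array([lam, mu, 0, 0, 0, 0], dtype=float)
    _, E_top, _ = sse_loglik(
        phylo, cr_m5_spec, params, return_partials=True, rtol=1e-10, atol=1e-12
    )
    for idx in range(phylo.n_nodes):
        t = phylo.blen[idx]
        if t > 0 and phylo.post_left[idx] < 0:
            assert E_top[idx][0] == pytest.approx(extinction_prob(lam, mu, t), abs=1e-8)


def test_state_independent_factorization(cr_m5_spec):
    """Equal lambda, mu with arbitrary q: SSE loglik = Mk loglik + plain
    birth-death tree loglik (two independent implementations)."""
    spec_sim = make_spec("CR", 1)
    lam, mu = 1.0, 0.3
    phylo = simulate_sse(
        np.array([lam, mu, 0.3, 0.3]), spec_sim, n_tips=20, seed=11
    )
    params = np.array([lam, mu, 0.07, 0.35, 0.12, 0.25])
    _, _, Q = cr_m5_spec.rates(params)
    mk = _mk_loglik_expm(phylo, Q)

    def bd_branch(y0, t):
        def rhs(_t, y):
            E, D = y
            return [
                mu - (lam + mu) * E + lam * E * E,
                -(lam + mu) * D + 2 * lam * E * D,
            ]

        sol = solve_ivp(rhs, (0, t), y0, rtol=1e-12, atol=1e-14)
        return sol.y[:, -1]

    ED = {}
    for idx in range(phylo.n_nodes):
        l = phylo.post_left[idx]
        if l < 0:
            y0 = [0.0, 1.0]
        else:
            r = phylo.post_right[idx]
            y0 = [ED[l][0], ED[l][1] * ED[r][1] * lam]
        ED[idx] = bd_branch(y0, phylo.blen[idx]) if phylo.blen[idx] > 0 else np.array(y0)
    bd = float(np.log(ED[phylo.n_nodes - 1][1]))
    ll = sse_loglik(
        phylo,
        cr_m5_spec,
        params,
        root_mode="flat",
        condition_on_survival=False,
        rtol=1e-10,
        atol=1e-12,
    )
    assert ll == pytest.approx(mk + bd, abs=1e-5)


def _scipy_sse_loglik(phylo, spec, params, root_mode="obs", condition=True):
    """Full-model cross-check path using scipy's integrator only."""
    lam, mu, Q = spec.rates(params)
    qsum = Q.sum(axis=1)
    n = spec.n_states

    def rhs(_t, y):
        E, D = y[:n], y[n:]
        tot = lam + mu + qsum
        return np.concatenate(
            [mu - tot * E + lam * E**2 + Q @ E, -tot * D + 2 * lam * E * D + Q @ D]
        )

    tipD = phylo.tip_D_init(spec)
    tipE = np.tile(1.0 - spec.rho, spec.n_hidden)
    vals = {}
    logcum = 0.0
    for idx in range(phylo.n_nodes):
        l = phylo.post_left[idx]
        if l < 0:
            E0, D0 = tipE.copy(), tipD[idx].copy()
        else:
            r = phylo.post_right[idx]
            D0 = vals[l][1] * vals[r][1] * lam
            E0 = vals[l][0]
        s = D0.sum()
        logcum += np.log(s)
        D0 = D0 / s
        t = phylo.blen[idx]
        if t > 0:
            sol = solve_ivp(rhs, (0, t), np.concatenate([E0, D0]), rtol=1e-11, atol=1e-13)
            E1, D1 = sol.y[:n, -1], sol.y[n:, -1]
        else:
            E1, D1 = E0, D0
        vals[idx] = (E1, D1)
    E_root, D_root = vals[phylo.n_nodes - 1]
    if condition:
        D_root = D_root / (lam * (1 - E_root) ** 2)
    w = D_root / D_root.sum() if root_mode == "obs" else np.full(n, 1 / n)
    return logcum + np.log(float(w @ D_root))


@pytest.mark.parametrize("mode,structure", [("CR", 5), ("ETD", 1), ("CTD", 3)])
def test_kernel_agrees_with_scipy_integrator(mode, structure):
    """The jitted Cash-Karp pruning matches an independent scipy path for
    constant-rate, trait-dependent and concealed-state models."""
    spec_sim = make_spec("CR", 1)
    phylo = simulate_sse(np.array([1.0, 0.2, 0.2, 0.2]), spec_sim, n_tips=10, seed=3)
    spec = make_spec(mode, structure)
    rng = np.random.default_rng(structure)
    params = rng.uniform(0.05, 0.8, spec.k)
    ll_fast = sse_loglik(phylo, spec, params, rtol=1e-10, atol=1e-12)
    ll_scipy = _scipy_sse_loglik(phylo, spec, params)
    assert ll_fast == pytest.approx(ll_scipy, abs=1e-6)


def test_likelihood_invariant_to_child_rotation(cr_m5_spec):
    a = "((A:1.0,B:1.0):0.5,(C:0.7,D:0.7):0.8):0.0;"
    b = "((D:0.7,C:0.7):0.8,(B:1.0,A:1.0):0.5):0.0;"
    states = {"A": "ES", "B": "EG", "C": "CG", "D": "CS"}
    params = np.array([0.9, 0.1, 0.07, 0.35, 0.12, 0.25])
    lls = [
        sse_loglik(
            LabeledPhylogeny(dendropy.Tree.get(data=s, schema="newick"), states),
            cr_m5_spec,
            params,
        )
        for s in (a, b)
    ]
    assert lls[0] == pytest.approx(lls[1], abs=1e-9)


def test_halving_tolerances_is_stable(cr_m5_spec):
    phylo = simulate_sse(
        np.array([1.0, 0.2, 0.1, 0.3, 0.1, 0.1]), cr_m5_spec, n_tips=40, seed=9
    )
    params = np.array([0.8, 0.15, 0.08, 0.3, 0.12, 0.1])
    ll1 = sse_loglik(phylo, cr_m5_spec, params, rtol=1e-7, atol=1e-9)
    ll2 = sse_loglik(phylo, cr_m5_spec, params, rtol=3.5e-8, atol=5e-10)
    assert abs(ll1 - ll2) < 1e-4


def test_partials_stay_in_bounds(cr_m5_spec):
    phylo = simulate_sse(
        np.array([1.0, 0.2, 0.1, 0.3, 0.1, 0.1]), cr_m5_spec, n_tips=30, seed=5
    )
    params = np.array([0.8, 0.4, 0.08, 0.3, 0.12, 0.1])
    ll, E_top, D_top = sse_loglik(phylo, cr_m5_spec, params, return_partials=True)
    assert np.isfinite(ll)
    assert np.all(E_top >= -1e-12) and np.all(E_top <= 1 + 1e-12)
    assert np.all(D_top >= 0)


def test_ambiguous_tip_states_increase_likelihood(cr_m5_spec):
    tree_s = "((A:1.0,B:1.0):0.5,C:1.5):0.0;"
    params = np.array([0.9, 0.1, 0.07, 0.35, 0.12, 0.25])
    known = LabeledPhylogeny(
        dendropy.Tree.get(data=tree_s, schema="newick"),
        {"A": "ES", "B": "EG", "C": "CG"},
    )
    ambig = LabeledPhylogeny(
        dendropy.Tree.get(data=tree_s, schema="newick"),
        {"A": "ES", "B": "EG", "C": {"CG", "CS", "ES", "EG"}},
    )
    ll_known = sse_loglik(known, cr_m5_spec, params)
    ll_ambig = sse_loglik(ambig, cr_m5_spec, params)
    assert ll_ambig > ll_known


def test_tree_validation_errors():
    poly = dendropy.Tree.get(data="(A:1,B:1,C:1):0.0;", schema="newick")
    with pytest.raises(ValueError, match="bifurcating"):
        LabeledPhylogeny(poly, {"A": "ES", "B": "ES", "C": "ES"})
    non_ultra = dendropy.Tree.get(data="((A:1,B:2):0.5,C:1.5):0.0;", schema="newick")
    with pytest.raises(ValueError, match="ultrametric"):
        LabeledPhylogeny(non_ultra, {"A": "ES", "B": "ES", "C": "ES"})
    ok = dendropy.Tree.get(data="((A:1,B:1):0.5,C:1.5):0.0;", schema="newick")
    with pytest.raises(ValueError, match="state"):
        LabeledPhylogeny(ok, {"A": "ES", "B": "ES"})
    with pytest.raises(ValueError, match="invalid state"):
        LabeledPhylogeny(ok, {"A": "ES", "B": "XX", "C": "ES"})
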