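"""Forward birth-death simulation with Markov state transitions.

Companion to the fitted models: generates ultrametric trees with tip
states under a given model spec + parameter vector, for parameter-recovery
and model-selection calibration experiments.  Extinct lineages are pruned
from the returned tree; for concealed-state models the observed tip state
is the examined part of the joint state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import dendropy
import numpy as np

from .likelihood import LabeledPhylogeny
from .models import STATES, SSEModelSpec

__all__ = ["simulate_sse"]


@dataclass
class _Lineage:
    state: int
    birth: float
    parent: Optional["_Lineage"]
    children: List["_Lineage"] = field(default_factory=list)
    death: Optional[float] = None  # extinction time; None = alive or speciated
    alive: bool = True


def _simulate_once(lam, mu, Q, rng, n_tips, max_time):
    qtot = Q.sum(axis=1)
    root = _Lineage(state=0, birth=0.0, parent=None)
    # root state drawn uniformly over states with positive speciation,
    # then an immediate split into two crown lineages
    viable = np.flatnonzero(lam > 0)
    root.state = int(rng.choice(viable))
    t = 0.0
    c1 = _Lineage(root.state, t, root)
    c2 = _Lineage(root.state, t, root)
    root.children = [c1, c2]
    root.alive = False
    active = [c1, c2]
    while active:
        rates = np.array([lam[l.state] + mu[l.state] + qtot[l.state] for l in active])
        R = rates.sum()
        if R <= 0:
            t = max_time if max_time is not None else t
            break
        dt = rng.exponential(1.0 / R)
        if max_time is not None and t + dt > max_time:
            t = max_time
            break
        t += dt
        k = int(rng.choice(len(active), p=rates / R))
        lin = active[k]
        s = lin.state
        u = rng.random() * (lam[s] + mu[s] + qtot[s])
        if u < lam[s]:
            a = _Lineage(s, t, lin)
            b = _Lineage(s, t, lin)
            lin.children = [a, b]
            lin.alive = False
            lin.death = t
            active.pop(k)
            active.extend([a, b])
            if n_tips is not None and len(active) == n_tips:
                # carry all survivors to the present: time to next event
                rates = np.array(
                    [lam[l.state] + mu[l.state] + qtot[l.state] for l in active]
                )
                R = rates.sum()
                t += rng.exponential(1.0 / R) if R > 0 else 0.0
                break
        elif u < lam[s] + mu[s]:
            lin.alive = False
            lin.death = t
            active.pop(k)
        else:
            w = Q[s] / qtot[s]
            lin.state = int(rng.choice(len(w), p=w))
    return root, active, t


def _prune_newick(node, present_time, counter, states, n_examined):
    """Newick of the surviving subtree below (and including) *node*."""
    if node.alive:
        name = f"t{next(counter)}"
        states[name] = STATES[node.state % n_examined]
        return f"{name}:{present_time - node.birth:.12g}"
    parts = [
        _prune_newick(c, present_time, counter, states, n_examined)
        for c in node.children
        if _has_survivor(c)
    ]
    if len(parts) == 0:
        return None
    start = node.children[0].birth if node.children else node.birth
    if len(parts) == 1:
        # unifurcation: splice the branch through
        child_str = parts[0]
        lbl, ln = child_str.rsplit(":", 1)
        total = float(ln) + (start - node.birth)
        return f"{lbl}:{total:.12g}"
    return f"({parts[0]},{parts[1]}):{start - node.birth:.12g}"


def _has_survivor(node) -> bool:
    if node.alive:
        return True
    return any(_has_survivor(c) for c in node.children)


def simulate_sse(
    params,
    spec: SSEModelSpec,
    n_tips: Optional[int] = None,
    max_time: Optional[float] = None,
    seed: int = 0,
    max_retries: int = 100,
) -> LabeledPhylogeny:
    """Simulate a labelled ultrametric tree under an SSE model.

    Exactly one of ``n_tips`` (stop when that many lineages survive) or
    ``max_time`` must be given.  Extinct lineages are pruned; the attempt is
    retried (up to ``max_retries``) if fewer than two lineages survive or
    the tip target is not reached.  Reproducible by seed.
    """
    if (n_tips is None) == (max_time is None):
        raise ValueError("specify exactly one of n_tips or max_time")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    lam, mu, Q = spec.rates(np.asarray(params, dtype=float))
    if not np.any(lam > 0):
        raise ValueError("at least one state must have positive speciation rate")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        root, active, t = _simulate_once(
            lam, mu, Q, rng, n_tips, max_time
        )
        survivors = [l for l in active if l.alive]
        if len(survivors) < 2:
            continue
        if n_tips is not None and len(survivors) != n_tips:
            continue
        counter = iter(range(1, 10**9))
        states: dict = {}
        nwk = _prune_newick(root, t, counter, states, spec.n_examined)
        if nwk is None:
            continue
        # root edge handling: _prune_newick on the root returns the crown
        tree = dendropy.Tree.get(data=nwk + ";", schema="newick")
        return LabeledPhylogeny(tree, states)
    raise RuntimeError(
        f"no surviving clade with the requested size in {max_retries} attempts"
    )
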