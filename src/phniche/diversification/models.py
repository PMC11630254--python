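"""Model specifications for the 18-model state-dependent diversification set.

The examined character has four joint states over two binary traits:

====  =========================  ==============
code  niche breadth              range
====  =========================  ==============
ES    specialist                 endemic
EG    generalist                 endemic
CS    specialist                 cosmopolitan
CG    generalist                 cosmopolitan
====  =========================  ==============

Six transition structures constrain the rate matrix q: single-trait moves
change either the niche state (S<->G, holding range) or the range state
(E<->C, holding niche); "dual" moves change both at once (ES<->CG,
EG<->CS).  Structure 1 uses one symmetric niche rate plus one symmetric
range rate and forbids dual moves; 2 adds dual moves; 3 and 4 free the
niche (respectively range) rate asymmetry; 5 frees both; 6 frees both and
allows dual moves.  Crossing each structure with three diversification
modes — ETD (speciation/extinction indexed by the examined state), CTD (two
concealed states carry the rate variation), CR (one rate for all lineages)
— yields exactly 18 models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "STATES",
    "N_EXAMINED",
    "classify_joint_state",
    "build_structure",
    "SSEModelSpec",
    "make_spec",
    "model_set",
]

STATES: Tuple[str, ...] = ("ES", "EG", "CS", "CG")
N_EXAMINED = 4

# transition move classes as (from, to) index pairs over STATES
_NICHE_S_TO_G = ((0, 1), (2, 3))
_NICHE_G_TO_S = ((1, 0), (3, 2))
_RANGE_E_TO_C = ((0, 2), (1, 3))
_RANGE_C_TO_E = ((2, 0), (3, 1))
_DUAL_TO_G = ((0, 3), (2, 1))  # specialist -> generalist with range flip
_DUAL_TO_S = ((3, 0), (1, 2))

ETD = "ETD"
CTD = "CTD"
CR = "CR"


def classify_joint_state(nb_class: str, range_cls: str) -> str:
    """Map a (niche-breadth class, range class) pair to the joint state code.

    Putative specialists (single-soil phylotypes) are counted as
    specialists for evolutionary analyses.
    """
    niche = {"specialist": "S", "putative_specialist": "S", "generalist": "G"}
    rng = {"endemic": "E", "cosmopolitan": "C"}
    if nb_class not in niche:
        raise ValueError(f"unknown niche-breadth class {nb_class!r}")
    if range_cls not in rng:
        raise ValueError(f"unknown range class {range_cls!r}")
    return rng[range_cls] + niche[nb_class]


def build_structure(structure_id: int, dual_rate_shared: bool = False) -> np.ndarray:
    """Constraint-encoded transition structure as a 4x4 integer matrix.

    Entries are structure-local parameter numbers starting at 1; 0 marks a
    forbidden transition (the diagonal is always 0).  Shared numbers imply
    shared fitted rates.  ``dual_rate_shared`` collapses the two dual-move
    rates of structure 6 into one.
    """
    if structure_id not in range(1, 7):
        raise ValueError(f"structure_id must be in 1..6, got {structure_id}")
    q = np.zeros((N_EXAMINED, N_EXAMINED), dtype=int)

    def assign(pairs, k):
        for i, j in pairs:
            q[i, j] = k

    if structure_id == 1:
        assign(_NICHE_S_TO_G + _NICHE_G_TO_S, 1)
        assign(_RANGE_E_TO_C + _RANGE_C_TO_E, 2)
    elif structure_id == 2:
        assign(_NICHE_S_TO_G + _NICHE_G_TO_S, 1)
        assign(_RANGE_E_TO_C + _RANGE_C_TO_E, 2)
        assign(_DUAL_TO_G + _DUAL_TO_S, 3)
    elif structure_id == 3:
        assign(_NICHE_S_TO_G, 1)
        assign(_NICHE_G_TO_S, 2)
        assign(_RANGE_E_TO_C + _RANGE_C_TO_E, 3)
    elif structure_id == 4:
        assign(_NICHE_S_TO_G + _NICHE_G_TO_S, 1)
        assign(_RANGE_E_TO_C, 2)
        assign(_RANGE_C_TO_E, 3)
    elif structure_id == 5:
        assign(_NICHE_S_TO_G, 1)
        assign(_NICHE_G_TO_S, 2)
        assign(_RANGE_E_TO_C, 3)
        assign(_RANGE_C_TO_E, 4)
    else:  # 6
        assign(_NICHE_S_TO_G, 1)
        assign(_NICHE_G_TO_S, 2)
        assign(_RANGE_E_TO_C, 3)
        assign(_RANGE_C_TO_E, 4)
        if dual_rate_shared:
            assign(_DUAL_TO_G + _DUAL_TO_S, 5)
        else:
            assign(_DUAL_TO_G, 5)
            assign(_DUAL_TO_S, 6)
    return q


@dataclass
class SSEModelSpec:
    """Integer-indexed parameter-sharing scheme for an SSE model.

    ``lambda_ids``/``mu_ids`` index speciation and extinction rates per
    joint (examined x hidden) state into the flat parameter vector;
    ``q_ids[i, j]`` indexes the i->j transition rate (-1 = forbidden).  The
    number of free parameters ``k`` is the number of distinct indices.
    """

    mode: str  # ETD | CTD | CR
    structure_id: int
    n_hidden: int
    lambda_ids: np.ndarray
    mu_ids: np.ndarray
    q_ids: np.ndarray
    param_names: Sequence[str]
    rho: np.ndarray  # per examined state sampling fraction in (0, 1]
    n_examined: int = N_EXAMINED

    @property
    def n_states(self) -> int:
        return self.n_examined * self.n_hidden

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def name(self) -> str:
        return f"{self.mode}-M{self.structure_id}"

    def rates(self, params: np.ndarray):
        """Expand a parameter vector into (lam, mu, Q) full-rate arrays."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.k,):
            raise ValueError(f"expected {self.k} parameters, got {params.shape}")
        if (params < 0).any():
            raise ValueError("rates must be >= 0")
        lam = params[self.lambda_ids]
        mu = params[self.mu_ids]
        Q = np.where(self.q_ids >= 0, params[np.clip(self.q_ids, 0, None)], 0.0)
        np.fill_diagonal(Q, 0.0)
        return lam, mu, Q

    def param_index(self, name: str) -> int:
        return list(self.param_names).index(name)


def make_spec(
    mode: str,
    structure_id: int,
    dual_rate_shared: bool = False,
    rho: Optional[Sequence[float]] = None,
) -> SSEModelSpec:
    """Build one model spec: a transition structure under one diversification mode."""
    if mode not in (ETD, CTD, CR):
        raise ValueError(f"mode must be ETD, CTD or CR, got {mode!r}")
    struct = build_structure(structure_id, dual_rate_shared=dual_rate_shared)
    n_struct = int(struct.max())
    n_hidden = 2 if mode == CTD else 1
    ns = N_EXAMINED * n_hidden
    names = []
    if mode == ETD:
        lambda_ids = np.arange(4)
        mu_ids = np.arange(4, 8)
        names += [f"lambda_{s}" for s in STATES] + [f"mu_{s}" for s in STATES]
        q_off = 8
    elif mode == CR:
        lambda_ids = np.zeros(4, dtype=int)
        mu_ids = np.ones(4, dtype=int)
        names += ["lambda", "mu"]
        q_off = 2
    else:  # CTD: lambda/mu depend only on the hidden state
        lambda_ids = np.repeat([0, 1], 4)
        mu_ids = np.repeat([2, 3], 4)
        names += ["lambda_A", "lambda_B", "mu_A", "mu_B"]
        q_off = 4
    names += [f"q{m + 1}_M{structure_id}" for m in range(n_struct)]
    q_ids = -np.ones((ns, ns), dtype=int)
    for h in range(n_hidden):
        o = 4 * h
        for i in range(4):
            for j in range(4):
                if struct[i, j] > 0:
                    q_ids[o + i, o + j] = q_off + struct[i, j] - 1
    if n_hidden == 2:
        eta = q_off + n_struct
        names.append("eta")
        for e in range(4):
            q_ids[e, 4 + e] = eta
            q_ids[4 + e, e] = eta
    rho_arr = np.ones(4) if rho is None else np.asarray(rho, dtype=float)
    if rho_arr.shape != (4,) or np.any(rho_arr <= 0) or np.any(rho_arr > 1):
        raise ValueError("rho must be 4 per-state sampling fractions in (0, 1]")
    return SSEModelSpec(
        mode=mode,
        structure_id=structure_id,
        n_hidden=n_hidden,
        lambda_ids=np.asarray(lambda_ids),
        mu_ids=np.asarray(mu_ids),
        q_ids=q_ids,
        param_names=names,
        rho=rho_arr,
    )


def model_set(dual_rate_shared: bool = False) -> list:
    """The 18-model set: structures 1..6 x modes {ETD, CTD, CR}."""
    return [
        make_spec(mode, sid, dual_rate_shared=dual_rate_shared)
        for sid in range(1, 7)
        for mode in (ETD, CTD, CR)
    ]
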