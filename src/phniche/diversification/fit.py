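"""Multi-start maximum-likelihood fitting and AIC model comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .likelihood import LabeledPhylogeny, sse_loglik
from .models import SSEModelSpec

logger = logging.getLogger(__name__)

__all__ = ["SSEFit", "fit_model", "compare_aic"]

_LOG_LO, _LOG_HI = np.log(1e-8), np.log(1e3)


@dataclass
class SSEFit:
    spec: SSEModelSpec
    params: np.ndarray
    loglik: float
    k: int
    n_starts: int
    converged: bool
    data_hash: str
    starts: List[dict] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=list(self.spec.param_names))


def _start_points(
    phylo: LabeledPhylogeny, spec: SSEModelSpec, n_starts: int, seed: int
) -> np.ndarray:
    """Dispersed starting points: a Latin hypercube in log-rate space centred
    on a Yule-style rate guess lambda0 = ln(n_tips) / depth."""
    lam0 = max(np.log(max(phylo.n_tips, 3)) / phylo.depth, 1e-6)
    centre = np.log(lam0)
    lo, hi = centre - 2.5, centre + 1.5
    sampler = qmc.LatinHypercube(d=spec.k, seed=seed)
    pts = lo + (hi - lo) * sampler.random(n_starts)
    # first start biased toward the centre guess with small extinction
    pts[0, :] = centre - 1.0
    for i, name in enumerate(spec.param_names):
        if name.startswith("lambda"):
            pts[0, i] = centre
        elif name.startswith("mu"):
            pts[0, i] = centre - 2.0
    return np.clip(pts, _LOG_LO + 1e-6, _LOG_HI - 1e-6)


def fit_model(
    phylo: LabeledPhylogeny,
    spec: SSEModelSpec,
    n_starts: int = 3,
    seed: int = 0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    root_mode: str = "obs",
    condition_on_survival: bool = True,
    maxiter: int = 500,
) -> SSEFit:
    """Box-constrained ML on log-transformed rates from dispersed starts.

    Each start runs L-BFGS-B on log-parameters with bounds [1e-8, 1e3] on
    the natural scale; the best start is returned and all start traces are
    recorded.  A warning is logged when the parameter count approaches the
    information content of the tree (k > n_tips / 5).
    """
    if spec.k > phylo.n_tips / 5:
        logger.warning(
            "PHN-W010 model %s has %d free parameters for %d tips; "
            "estimates may be weakly identified",
            spec.name,
            spec.k,
            phylo.n_tips,
        )

    def objective(x: np.ndarray) -> float:
        ll = sse_loglik(
            phylo,
            spec,
            np.exp(x),
            rtol=rtol,
            atol=atol,
            root_mode=root_mode,
            condition_on_survival=condition_on_survival,
        )
        if not np.isfinite(ll):
            return 1e10
        return -ll

    starts = _start_points(phylo, spec, n_starts, seed)
    records = []
    best = None
    for s in range(n_starts):
        res = optimize.minimize(
            objective,
            starts[s],
            method="L-BFGS-B",
            bounds=[(_LOG_LO, _LOG_HI)] * spec.k,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        rec = {
            "start": s,
            "x0": np.exp(starts[s]),
            "loglik": -float(res.fun),
            "params": np.exp(res.x),
            "success": bool(res.success),
            "nit": int(res.nit),
        }
        records.append(rec)
        if np.isfinite(rec["loglik"]) and (best is None or rec["loglik"] > best["loglik"]):
            best = rec
    if best is None or best["loglik"] <= -1e9:
        raise RuntimeError(
            f"all {n_starts} optimizations failed for {spec.name}; traces: {records}"
        )
    return SSEFit(
        spec=spec,
        params=best["params"],
        loglik=best["loglik"],
        k=spec.k,
        n_starts=n_starts,
        converged=any(r["success"] for r in records),
        data_hash=phylo.data_hash,
        starts=records,
    )


def compare_aic(fits: Sequence[SSEFit]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending); ties go to fewer parameters.

    All fits must be on identical data (checked by data hash).  Returns a
    DataFrame with model, mode, structure, k, loglik, AIC, delta_AIC and
    rank; the best model is row 0.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError(f"fits are not on identical data: hashes {sorted(hashes)}")
    df = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "mode": [f.spec.mode for f in fits],
            "structure": [f.spec.structure_id for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AIC": [f.aic for f in fits],
        }
    )
    df = df.sort_values(["AIC", "k"], kind="mergesort").reset_index(drop=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    return df
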