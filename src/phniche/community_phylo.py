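"""Phylogenetic community structure and phylogenetic signal.

Two questions about the specialist/generalist phylotypes on the marker-gene
phylogeny:

* are the phylotypes co-occurring in a soil more (or less) closely related
  than expected by chance?  Measured by the abundance-weighted mean pairwise
  patristic distance (MPD) and its standardized effect size (ses.mpd)
  against "richness" null communities — random tip subsets of the same size
  carrying the observed abundance values;
* is the generalism trait itself phylogenetically conserved?  Measured by
  Blomberg's K, the ratio of trait variance among tips to phylogenetically
  corrected variance, scaled by its Brownian-motion expectation (K = 1 under
  BM), with a tip-permutation p value.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SesMpdResult",
    "PhylosignalResult",
    "DegenerateNullError",
    "patristic_distance_matrix",
    "vcv_matrix",
    "mpd_weighted",
    "ses_mpd",
    "blomberg_k",
    "ses_mpd_vs_ph",
]


class DegenerateNullError(ValueError):
    """All null communities yield the same MPD; ses undefined."""


@dataclass
class SesMpdResult:
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    n_null: int


@dataclass
class PhylosignalResult:
    K: float
    p: float
    n_perm: int


def patristic_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip patristic distance matrix (zero diagonal)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def vcv_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix: shared root-to-MRCA path lengths.

    C[i, j] = depth of the MRCA of tips i and j; C[i, i] = root-to-tip i
    distance.  Derived from tip depths and patristic distances, so
    polytomies are handled naturally.
    """
    depths = {}
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else depths[node.parent_node] + (node.edge.length or 0.0)
        depths[node] = d
    tip_depth = {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}
    dist = patristic_distance_matrix(tree)
    labels = list(dist.index)
    dvec = np.array([tip_depth[t] for t in labels])
    C = 0.5 * (dvec[:, None] + dvec[None, :] - dist.to_numpy())
    np.fill_diagonal(C, dvec)
    return pd.DataFrame(C, index=labels, columns=labels)


def mpd_weighted(abund: pd.Series, dist: pd.DataFrame) -> float:
    """Abundance-weighted mean pairwise distance.

    MPD = sum_{i != j} w_i w_j d_ij / sum_{i != j} w_i w_j over taxa with
    abundance > 0.
    """
    w = abund[abund > 0]
    if len(w) < 2:
        raise ValueError("need at least 2 taxa with positive abundance")
    missing = [t for t in w.index if t not in dist.index]
    if missing:
        raise KeyError(f"taxa absent from distance matrix: {missing}")
    d = dist.loc[w.index, w.index].to_numpy()
    wv = w.to_numpy(dtype=float)
    ww = np.outer(wv, wv)
    np.fill_diagonal(ww, 0.0)
    return float(np.sum(ww * d) / np.sum(ww))


def ses_mpd(
    abund: pd.Series,
    tree: dendropy.Tree,
    n_null: int = 999,
    null_model: str = "richness",
    seed: int = 0,
    dist: pd.DataFrame | None = None,
) -> SesMpdResult:
    """Standardized effect size of abundance-weighted MPD.

    The "richness" null draws, for each of ``n_null`` null communities, the
    same number of taxa uniformly without replacement from the pool of all
    tree tips and reassigns the observed abundance values to them in random
    order.  ses = (obs - null_mean)/null_sd; negative ses means the
    community is more closely related than chance.  The two-sided p value
    is the rank-based 2*min(p_low, p_high) with the +1 correction.
    """
    if null_model != "richness":
        raise ValueError(f"unsupported null model {null_model!r}")
    if dist is None:
        dist = patristic_distance_matrix(tree)
    pool = list(dist.index)
    present = abund[abund > 0]
    outside = [t for t in present.index if t not in pool]
    if outside:
        raise KeyError(f"community taxa not in tree: {outside}")
    richness = len(present)
    if richness > len(pool):
        raise ValueError("community richness exceeds pool size")
    obs = mpd_weighted(present, dist)
    rng = np.random.default_rng(seed)
    weights = present.to_numpy(dtype=float)
    dmat = dist.to_numpy()
    nulls = np.empty(n_null)
    for k in range(n_null):
        idx = rng.choice(len(pool), size=richness, replace=False)
        wv = rng.permutation(weights)
        ww = np.outer(wv, wv)
        np.fill_diagonal(ww, 0.0)
        sub = dmat[np.ix_(idx, idx)]
        nulls[k] = np.sum(ww * sub) / np.sum(ww)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    if null_sd <= 1e-12 * max(abs(null_mean), 1.0):
        raise DegenerateNullError("null MPD distribution has (numerically) zero variance")
    ses = (obs - null_mean) / null_sd
    p_low = (np.sum(nulls < obs) + 1) / (n_null + 1)
    p_high = (np.sum(nulls > obs) + 1) / (n_null + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return SesMpdResult(obs, null_mean, null_sd, float(ses), float(p), n_null)


def _k_ratio(x: np.ndarray, Cinv: np.ndarray) -> float:
    """Observed MSE0/MSE variance ratio given the inverse VCV."""
    n = len(x)
    ones = np.ones(n)
    Ci1 = Cinv @ ones
    ahat = float(x @ Ci1) / float(ones @ Ci1)
    r = x - ahat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ Cinv @ r) / (n - 1)
    return mse0 / mse


def blomberg_k(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PhylosignalResult:
    """Blomberg's K with a tip-permutation test.

    K = (MSE0/MSE) / E_BM[MSE0/MSE], where MSE0 is the trait variance about
    the phylogenetically weighted mean, MSE the phylogenetically corrected
    variance (quadratic form in the inverse VCV), and the Brownian-motion
    expectation (tr(C) - n / sum(C^-1)) / (n - 1) is computed exactly from
    the tree's VCV.  The p value is the +1-corrected proportion of random
    tip-label permutations whose variance ratio is at least the observed
    (one-sided: high ratio = more signal).  K is invariant to affine trait
    transforms.
    """
    C = vcv_matrix(tree)
    labels = list(C.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 tips")
    missing = [t for t in labels if t not in trait.index]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    x = trait.reindex(labels).to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("trait variance is zero; K undefined")
    Cm = C.to_numpy()
    Cinv = np.linalg.inv(Cm)
    n = len(x)
    ones = np.ones(n)
    expected = (np.trace(Cm) - n / float(ones @ Cinv @ ones)) / (n - 1)
    obs_ratio = _k_ratio(x, Cinv)
    K = obs_ratio / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _k_ratio(rng.permutation(x), Cinv) >= obs_ratio:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PhylosignalResult(float(K), float(p), n_perm)


def ses_mpd_vs_ph(ses_values, ph_values) -> dict:
    """OLS of ses.mpd on soil pH: slope, intercept, R^2, F, p."""
    import statsmodels.api as sm

    y = np.asarray(ses_values, dtype=float)
    x = np.asarray(ph_values, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 paired observations")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "f_statistic": float(model.fvalue),
        "p": float(model.f_pvalue),
        "n": int(len(y)),
    }
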