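"""Weighted MPD, ses.mpd null model, Blomberg's K, and the R oracle."""

import itertools
import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from phniche.community_phylo import (
    DegenerateNullError,
    blomberg_k,
    mpd_weighted,
    patristic_distance_matrix,
    ses_mpd,
    ses_mpd_vs_ph,
    vcv_matrix,
)
from phniche.synthetic_data import gen_bm_traits, gen_yule_tree


def _balanced_tree(n_per_clade=6, split=5.0, pendant=1.0):
    """Two deep clades of n star-like tips each."""
    def clade(prefix):
        tips = ",".join(f"{prefix}{i}:{pendant}" for i in range(n_per_clade))
        return f"({tips}):{split}"

    nwk = f"({clade('a')},{clade('b')});"
    return dendropy.Tree.get(data=nwk, schema="newick")


def test_mpd_two_taxa_equals_distance():
    dist = pd.DataFrame([[0, 3.2], [3.2, 0]], index=["a", "b"], columns=["a", "b"])
    assert mpd_weighted(pd.Series({"a": 1.0, "b": 9.0}), dist) == pytest.approx(3.2)


def test_mpd_star_tree_symmetry():
    tree = dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick")
    dist = patristic_distance_matrix(tree)
    val = mpd_weighted(pd.Series({"a": 0.2, "b": 5.0, "c": 1.0}), dist)
    assert val == pytest.approx(2.0)


def test_mpd_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    taxa = list("abcd")
    d = rng.uniform(1, 5, (4, 4))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    dist = pd.DataFrame(d, index=taxa, columns=taxa)
    w = pd.Series(rng.uniform(0.5, 4, 4), index=taxa)
    num = den = 0.0
    for i, j in itertools.product(range(4), repeat=2):
        if i != j:
            num += w.iloc[i] * w.iloc[j] * d[i, j]
            den += w.iloc[i] * w.iloc[j]
    assert mpd_weighted(w, dist) == pytest.approx(num / den, rel=1e-12)


def test_mpd_equal_weights_equals_unweighted_mean():
    tree = gen_yule_tree(1.0, 8, seed=2)
    dist = patristic_distance_matrix(tree)
    taxa = list(dist.index)[:5]
    w = pd.Series(1.0, index=taxa)
    sub = dist.loc[taxa, taxa].to_numpy()
    off = sub[~np.eye(len(taxa), dtype=bool)]
    assert mpd_weighted(w, dist) == pytest.approx(off.mean(), rel=1e-12)


def test_mpd_requires_two_present_taxa():
    dist = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError):
        mpd_weighted(pd.Series({"a": 1.0, "b": 0.0}), dist)


def test_ses_mpd_clade_confined_community_is_clustered():
    tree = _balanced_tree(8)
    abund = pd.Series(1.0, index=[f"a{i}" for i in range(8)])
    res = ses_mpd(abund, tree, n_null=499, seed=1)
    assert res.ses < 0
    assert res.p <= 0.05


def test_ses_mpd_whole_pool_equal_abundance_degenerates():
    tree = _balanced_tree(4)
    abund = pd.Series(1.0, index=[f"{c}{i}" for c in "ab" for i in range(4)])
    with pytest.raises(DegenerateNullError):
        ses_mpd(abund, tree, n_null=99, seed=0)


def test_ses_mpd_unknown_taxon_and_richness_errors():
    tree = _balanced_tree(4)
    with pytest.raises(KeyError):
        ses_mpd(pd.Series({"zz": 1.0, "a0": 1.0}), tree, n_null=9, seed=0)


def test_ses_mpd_monte_carlo_matches_exhaustive_enumeration():
    """On a 12-tip pool with equal abundances the richness null can be
    enumerated exactly (all C(12,6) subsets); the Monte-Carlo ses agrees."""
    tree = _balanced_tree(6)  # 12 tips
    dist = patristic_distance_matrix(tree)
    taxa = list(dist.index)
    # moderately over-dispersed community spanning both clades
    comm = ["a0", "a1", "a2", "b0", "b1", "b2"]
    abund = pd.Series(1.0, index=comm)
    obs = mpd_weighted(abund, dist)
    dmat = dist.to_numpy()
    vals = []
    for subset in itertools.combinations(range(12), 6):
        sub = dmat[np.ix_(subset, subset)]
        vals.append(sub[~np.eye(6, dtype=bool)].mean())
    vals = np.asarray(vals)
    exact_ses = (obs - vals.mean()) / vals.std(ddof=1)
    mc = ses_mpd(abund, tree, n_null=10_000, seed=3)
    assert abs(mc.ses - exact_ses) < 0.05


def test_ses_mpd_random_communities_centered_on_zero():
    tree = gen_yule_tree(1.0, 16, seed=4)
    dist = patristic_distance_matrix(tree)
    taxa = list(dist.index)
    rng = np.random.default_rng(5)
    ses_vals = []
    for k in range(500):
        comm = rng.choice(taxa, size=6, replace=False)
        abund = pd.Series(rng.uniform(1, 10, 6), index=comm)
        ses_vals.append(ses_mpd(abund, tree, n_null=199, seed=k, dist=dist).ses)
    assert abs(np.mean(ses_vals)) < 0.1


def test_blomberg_k_affine_invariance_and_errors(yule50):
    trait = gen_bm_traits(yule50, 1.0, seed=8)
    k1 = blomberg_k(yule50, trait, n_perm=49, seed=0)
    k2 = blomberg_k(yule50, 3.7 * trait - 11.0, n_perm=49, seed=0)
    assert k1.K == pytest.approx(k2.K, abs=1e-9)
    with pytest.raises(ValueError):
        blomberg_k(yule50, pd.Series(1.0, index=trait.index))


def test_blomberg_k_bm_near_one(yule50):
    """Traits evolved under Brownian motion have expectation K = 1."""
    ks = [blomberg_k(yule50, gen_bm_traits(yule50, 1.0, seed=s), n_perm=0, seed=0).K
          for s in range(100)]
    assert 0.85 < np.mean(ks) < 1.15


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_k_and_mpd_match_picante_oracle(tmp_path):
    """Independent oracle: picante computes the same K, and the same
    weighted MPD once its diagonal-inclusive weighting is accounted for."""
    tree = gen_yule_tree(1.0, 12, seed=5)
    trait = gen_bm_traits(tree, 1.0, seed=6)
    res = blomberg_k(tree, trait, n_perm=9, seed=0)
    dist = patristic_distance_matrix(tree)
    w = pd.Series(np.arange(1, 13, dtype=float), index=[f"t{i}" for i in range(1, 13)])
    my_mpd = mpd_weighted(w, dist)
    sw, sw2 = w.sum(), (w**2).sum()
    my_mpd_diag = my_mpd * (1 - sw2 / sw**2)  # picante averages i=j pairs too
    tree_path, trait_path, ab_path = tmp_path / "t.nwk", tmp_path / "x.csv", tmp_path / "a.csv"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    trait.to_csv(trait_path)
    w.to_csv(ab_path)
    rscript = f"""
    suppressMessages(library(picante))
    tr <- read.tree("{tree_path}")
    tra <- read.csv("{trait_path}", row.names=1)
    x <- setNames(tra[[1]], rownames(tra))[tr$tip.label]
    ps <- phylosignal(x, tr, reps=9)
    ab <- read.csv("{ab_path}", row.names=1)
    comm <- matrix(ab[[1]], nrow=1, dimnames=list("s1", rownames(ab)))
    m <- mpd(comm, cophenetic(tr), abundance.weighted=TRUE)
    cat(sprintf("%.12f %.12f", ps$K, m))
    """
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
    )
    r_k, r_mpd = map(float, out.stdout.split())
    assert res.K == pytest.approx(r_k, rel=1e-6)
    assert my_mpd_diag == pytest.approx(r_mpd, rel=1e-6)


def test_ses_mpd_vs_ph_regression():
    ph = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
    y = 2.0 - 0.5 * ph
    rep = ses_mpd_vs_ph(y, ph)
    assert rep["r_squared"] == pytest.approx(1.0)
    assert rep["slope"] == pytest.approx(-0.5)
    # hand-computed oracle on a noisy 5-point set
    rng = np.random.default_rng(1)
    y2 = 2.0 - 0.5 * ph + rng.normal(0, 0.3, 5)
    rep2 = ses_mpd_vs_ph(y2, ph)
    sxx = ((ph - ph.mean()) ** 2).sum()
    sxy = ((ph - ph.mean()) * (y2 - y2.mean())).sum()
    slope = sxy / sxx
    r2 = sxy**2 / (sxx * ((y2 - y2.mean()) ** 2).sum())
    assert rep2["slope"] == pytest.approx(slope, rel=1e-10)
    assert rep2["r_squared"] == pytest.approx(r2, rel=1e-10)
    assert rep2["f_statistic"] == pytest.approx(r2 / (1 - r2) * 3, rel=1e-9)
    with pytest.raises(ValueError):
        ses_mpd_vs_ph([1.0, 2.0], [4.0, 5.0])
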