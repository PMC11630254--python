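"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs:

* :func:`gen_soil_gradient` — a soil pH gradient (default 47 soils, pH
  3.48–8.74) populated by phylotypes with Gaussian niche response curves on
  the pH axis.  Niche breadths are drawn from a bimodal narrow/broad
  mixture so that true specialists and generalists exist by construction;
  carrying abundances are lognormal and observation noise is lognormal,
  thresholded at a detection limit.  A truth table of the generating
  parameters accompanies every matrix for recovery tests.
* :func:`gen_incubation` — 30-day incubation time courses (days 0, 1, 3,
  10, 30; 3 replicates) under a native pH 6.0 condition and shifts to pH
  4.5 / 7.5, with phenotype-by-condition exponential growth of the active
  fraction, a persistent dormant fraction, and DNA/RNA/SIP read-outs.
* :func:`gen_yule_tree` / :func:`gen_bm_traits` — pure-birth ultrametric
  trees and Brownian-motion tip traits for the community-phylogenetics and
  constant-rate diversification fixtures.

Every generator is a pure function of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .datatypes import ABSOLUTE, AbundanceMatrix, SampleMeta
from .activity import IncubationSeries
from .niche_breadth import GENERALIST, PUTATIVE_SPECIALIST, SPECIALIST

__all__ = [
    "GradientScenario",
    "IncubationScenario",
    "gen_soil_gradient",
    "gen_incubation",
    "gen_bm_traits",
    "gen_yule_tree",
]


@dataclass
class GradientScenario:
    """Parameters of the synthetic soil pH gradient survey."""

    n_soils: int = 47
    ph_min: float = 3.48
    ph_max: float = 8.74
    n_phylotypes: int = 425
    #: sd of the Gaussian niche curve, pH units, for the two mixture modes
    narrow_breadth: float = 0.35
    broad_breadth: float = 1.8
    narrow_fraction: float = 0.6
    #: lognormal carrying abundance at the niche optimum (copies/g analogue)
    carrying_log_mean: float = 0.0
    carrying_log_sd: float = 3.0
    noise_log_sd: float = 0.7
    #: draw observed values as Poisson counts of the expected abundance
    #: (sequencing-like sampling, the source of single-soil phylotypes);
    #: False keeps the continuous lognormal surface
    poisson_counts: bool = True
    detection_threshold: float = 0.0
    #: per-soil total amoA copies/g, lognormal
    qpcr_log_mean: float = float(np.log(1e7))
    qpcr_log_sd: float = 0.5
    ph_grid: bool = True  # evenly spaced soils; False = uniform random
    niche_on_hplus: bool = False  # Gaussian niche on [H+] instead of pH
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("narrow_breadth", "broad_breadth", "noise_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.narrow_fraction <= 1:
            raise ValueError("narrow_fraction must be in [0, 1]")


def gen_soil_gradient(scenario: GradientScenario):
    """Simulate a phylotype x soil abundance matrix along a pH gradient.

    Returns ``(matrix, meta, truth)`` where ``matrix`` is an absolute
    :class:`AbundanceMatrix`, ``meta`` a list of :class:`SampleMeta` with pH
    and qPCR totals, and ``truth`` a DataFrame of the generating niche
    parameters (optimum, breadth, mixture component, carrying abundance).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    if sc.ph_grid:
        ph = np.linspace(sc.ph_min, sc.ph_max, sc.n_soils)
    else:
        ph = np.sort(rng.uniform(sc.ph_min, sc.ph_max, sc.n_soils))
    optimum = rng.uniform(sc.ph_min, sc.ph_max, sc.n_phylotypes)
    narrow = rng.random(sc.n_phylotypes) < sc.narrow_fraction
    breadth = np.where(narrow, sc.narrow_breadth, sc.broad_breadth)
    carrying = rng.lognormal(sc.carrying_log_mean, sc.carrying_log_sd, sc.n_phylotypes)

    if sc.niche_on_hplus:
        axis = 10.0 ** (-ph)
        opt_axis = 10.0 ** (-optimum)
        # breadth interpreted as a multiplicative span on [H+]
        br_axis = opt_axis * (10.0**breadth - 1.0)
        z = (axis[np.newaxis, :] - opt_axis[:, np.newaxis]) / br_axis[:, np.newaxis]
    else:
        z = (ph[np.newaxis, :] - optimum[:, np.newaxis]) / breadth[:, np.newaxis]
    expected = carrying[:, np.newaxis] * np.exp(-0.5 * z**2)
    noise = rng.lognormal(0.0, sc.noise_log_sd, expected.shape)
    obs = expected * noise
    if sc.poisson_counts:
        obs = rng.poisson(obs).astype(float)
    obs[obs <= sc.detection_threshold] = 0.0

    soil_ids = [f"soil{i + 1:02d}" for i in range(sc.n_soils)]
    phylo_ids = [f"otu{i + 1:04d}" for i in range(sc.n_phylotypes)]
    qpcr = rng.lognormal(sc.qpcr_log_mean, sc.qpcr_log_sd, sc.n_soils)
    matrix = AbundanceMatrix(obs, kind=ABSOLUTE, phylotype_ids=phylo_ids, sample_ids=soil_ids)
    meta = [
        SampleMeta(sample_id=s, ph=float(p), qpcr_total=float(q))
        for s, p, q in zip(soil_ids, ph, qpcr)
    ]
    truth = pd.DataFrame(
        {
            "phylotype_id": phylo_ids,
            "optimum_ph": optimum,
            "breadth_ph": breadth,
            "narrow": narrow,
            "carrying": carrying,
        }
    )
    return matrix, meta, truth


#: default per-day exponential growth rates by (phenotype, condition pH):
#: specialists are favoured after the shift toward the extreme (pH 4.5),
#: generalists under the native pH 6.0 and after the shift to 7.5.
DEFAULT_GROWTH_RATES: Dict[str, Dict[float, float]] = {
    SPECIALIST: {4.5: 0.12, 6.0: 0.04, 7.5: 0.02},
    GENERALIST: {4.5: 0.02, 6.0: 0.12, 7.5: 0.10},
    PUTATIVE_SPECIALIST: {4.5: 0.10, 6.0: 0.02, 7.5: 0.01},
}


@dataclass
class IncubationScenario:
    """Parameters of the synthetic 30-day incubation experiment."""

    conditions: Sequence[float] = (4.5, 6.0, 7.5)
    native_ph: float = 6.0
    growth_rates: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROWTH_RATES.items()}
    )
    dormant_fraction: float = 0.5
    noise_log_sd: float = 0.3
    timepoints: Sequence[int] = (0, 1, 3, 10, 30)
    replicates: int = 3
    initial_log_mean: float = float(np.log(1e5))
    initial_log_sd: float = 1.0
    #: RNA transcripts per active cell (scales the RNA read-out)
    transcripts_per_cell: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dormant_fraction <= 1:
            raise ValueError("dormant_fraction must be in [0, 1]")
        for r in self.growth_rates.values():
            for v in r.values():
                if not np.isfinite(v):
                    raise ValueError("growth rates must be finite")


def gen_incubation(scenario: IncubationScenario, classes: pd.Series):
    """Simulate DNA / RNA / SIP incubation read-outs.

    ``classes`` maps phylotype_id -> phenotype class (specialist /
    generalist / putative_specialist).  The active fraction of each
    phylotype grows (or declines) exponentially at its phenotype-by-
    condition rate; the dormant fraction persists unchanged.  The DNA
    read-out reports resident abundance (active + dormant), RNA reports
    transcripts of the active fraction, and SIP reports the day-30 active
    fraction only.  Multiplicative lognormal noise is applied per
    observation.

    Returns a dict mapping ``(condition_ph, assay, replicate)`` to an
    :class:`IncubationSeries` (SIP series have the single final time point).
    """
    sc = scenario
    bad = set(classes.unique()) - {SPECIALIST, GENERALIST, PUTATIVE_SPECIALIST}
    if bad:
        raise ValueError(f"unknown phenotype classes: {sorted(bad)}")
    for cls in classes.unique():
        for cond in sc.conditions:
            if cond not in sc.growth_rates.get(cls, {}):
                raise ValueError(f"missing growth rate for ({cls}, pH {cond})")
    rng = np.random.default_rng(sc.seed)
    pids = list(classes.index)
    n = len(pids)
    x0 = rng.lognormal(sc.initial_log_mean, sc.initial_log_sd, n)
    active0 = (1.0 - sc.dormant_fraction) * x0
    dormant = sc.dormant_fraction * x0
    rates = np.zeros(n)
    out = {}
    tps = list(sc.timepoints)
    for cond in sc.conditions:
        for i, pid in enumerate(pids):
            rates[i] = sc.growth_rates[classes[pid]][cond]
        for rep in range(1, sc.replicates + 1):
            label = "native" if cond == sc.native_ph else "perturbed"
            cond_name = f"{label}_pH{cond}"

            def _mat(values: np.ndarray, sample_id: str) -> AbundanceMatrix:
                noisy = values * rng.lognormal(0.0, sc.noise_log_sd, n) if sc.noise_log_sd > 0 else values
                return AbundanceMatrix(
                    noisy[:, np.newaxis], kind=ABSOLUTE, phylotype_ids=pids, sample_ids=[sample_id]
                )

            dna, rna = [], []
            for t in tps:
                active_t = active0 * np.exp(rates * t)
                dna.append(_mat(active_t + dormant, f"pH{cond}_r{rep}_d{t}_DNA"))
                rna.append(_mat(sc.transcripts_per_cell * active_t, f"pH{cond}_r{rep}_d{t}_RNA"))
            out[(cond, "DNA", rep)] = IncubationSeries(cond_name, "DNA", str(rep), tps, dna)
            out[(cond, "RNA", rep)] = IncubationSeries(cond_name, "RNA", str(rep), tps, rna)
            active_T = active0 * np.exp(rates * tps[-1])
            out[(cond, "SIP", rep)] = IncubationSeries(
                cond_name, "SIP", str(rep), [tps[-1]], [_mat(active_T, f"pH{cond}_r{rep}_d{tps[-1]}_SIP")]
            )
    return out


def gen_yule_tree(birth_rate: float, n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with exactly ``n_tips`` tips.

    Waiting times between speciation events at k extant lineages are
    Exponential(k * birth_rate); a final Exponential(n * birth_rate)
    increment carries all lineages to the present, so the expected
    root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    root.edge.length = 0.0
    c1, c2 = root.new_child(), root.new_child()
    for c in (c1, c2):
        c.edge.length = 0.0
    active = [c1, c2]
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / (len(active) * birth_rate))
        for node in active:
            node.edge.length += dt
        k = rng.integers(len(active))
        parent = active.pop(k)
        left, right = parent.new_child(), parent.new_child()
        left.edge.length = right.edge.length = 0.0
        active.extend([left, right])
    dt = rng.exponential(1.0 / (len(active) * birth_rate))
    for node in active:
        node.edge.length += dt
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_ns.new_taxon(f"t{i + 1}")
    return tree


def gen_bm_traits(tree: dendropy.Tree, sigma2: float, seed: int = 0) -> pd.Series:
    """Brownian-motion tip traits: root value 0, increment variance
    sigma2 * branch length; tip covariance equals sigma2 x shared path length."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    values = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("all branches must have lengths for BM simulation")
        parent_val = values[node.parent_node]
        values[node] = parent_val + rng.normal(0.0, np.sqrt(sigma2 * node.edge.length))
    out = {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    return pd.Series(out)
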