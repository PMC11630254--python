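"""Pipeline orchestration: staged runs over an output directory.

Stages (``simulate``, ``classify``, ``activity``, ``phylo``, ``divfit``,
``all``) communicate through TSV/newick artifacts in the configured output
directory, each written with a provenance header (package version, config
hash, seed).  Any run is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__, io
from .activity import (
    IncubationSeries,
    dormancy_fraction,
    gated_group_test,
    growth,
    phenotype_sums,
    shannon,
    transcriptional_activity,
)
from .community_phylo import blomberg_k, patristic_distance_matrix, ses_mpd, ses_mpd_vs_ph
from .datatypes import ABSOLUTE, AbundanceMatrix
from .diversification import (
    LabeledPhylogeny,
    ancestral_states,
    compare_aic,
    fit_model,
    make_spec,
    simulate_sse,
)
from .niche_breadth import classify_matrix
from .diversification.models import classify_joint_state
from .synthetic_data import (
    GradientScenario,
    IncubationScenario,
    gen_incubation,
    gen_soil_gradient,
    gen_yule_tree,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "DependencyError"]

STAGES = ("simulate", "classify", "activity", "phylo", "divfit", "all")


class DependencyError(RuntimeError):
    """A stage input produced by an earlier stage (or the user) is missing."""


@dataclass
class RunConfig:
    out_dir: str = "phniche_out"
    seed: int = 0
    # user-supplied inputs; the simulate stage writes its own into out_dir
    abundance_path: Optional[str] = None
    abundance_kind: str = "absolute"
    sample_meta_path: Optional[str] = None
    tree_path: Optional[str] = None  # community phylogeny (tips = phylotypes)
    sse_tree_path: Optional[str] = None
    sse_states_path: Optional[str] = None
    # niche breadth
    ties_to_specialist: bool = True
    weighted_moments: bool = False
    presence_threshold: float = 0.0
    endemic_max: int = 3
    # activity / extreme-range grouping
    extreme_low: float = 5.0
    extreme_high: float = 8.5
    # community phylogenetics
    n_null: int = 199
    n_perm: int = 199
    # diversification
    modes: Sequence[str] = ("CR",)
    structures: Sequence[int] = (1, 2, 3, 4, 5, 6)
    n_starts: int = 3
    ode_rtol: float = 1e-7
    ode_atol: float = 1e-9
    # demo-scale simulation scenario
    n_soils: int = 24
    n_phylotypes: int = 80
    sse_tree_tips: int = 60
    sse_sim_asymmetry: float = 6.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        # out_dir is excluded so identical analyses written to different
        # directories produce byte-identical artifacts
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed, "version": __version__}


def _out(cfg: RunConfig, name: str) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p / name


def _require(path: Path, stage: str, producer: str) -> Path:
    if not Path(path).exists():
        raise DependencyError(
            f"stage '{stage}' needs {path}; run '{producer}' first or point the "
            f"config at an existing file"
        )
    return Path(path)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig) -> None:
    seed = _stage_seed(cfg, "simulate")
    scen = GradientScenario(
        n_soils=cfg.n_soils, n_phylotypes=cfg.n_phylotypes, seed=seed
    )
    matrix, meta, truth = gen_soil_gradient(scen)
    io.write_abundance(matrix, _out(cfg, "abundance.tsv"), meta=cfg.provenance())
    io.write_sample_meta(meta, _out(cfg, "sample_meta.tsv"), header=cfg.provenance())
    io.write_table(truth, _out(cfg, "truth.tsv"), meta=cfg.provenance())

    # incubation series from the designed (truth) phenotypes
    classes = pd.Series(
        np.where(truth["narrow"], "specialist", "generalist"),
        index=truth["phylotype_id"],
    )
    inc = gen_incubation(IncubationScenario(seed=seed + 1), classes)
    rows = []
    for (cond, assay, rep), series in inc.items():
        for t, m in zip(series.timepoints, series.matrices):
            col = m.values.iloc[:, 0]
            for pid, v in col.items():
                rows.append(
                    {
                        "condition_ph": cond,
                        "assay": assay,
                        "replicate": rep,
                        "timepoint_days": t,
                        "phylotype_id": pid,
                        "value": v,
                    }
                )
    io.write_table(pd.DataFrame(rows), _out(cfg, "incubation.tsv"), meta=cfg.provenance())

    # community phylogeny over the gradient phylotypes
    tree = gen_yule_tree(1.0, cfg.n_phylotypes, seed=seed + 2)
    for leaf, pid in zip(tree.leaf_node_iter(), truth["phylotype_id"]):
        leaf.taxon.label = pid
    io.write_tree(tree, _out(cfg, "community_tree.nwk"))

    # labelled tree for diversification fitting: state-independent rates,
    # asymmetric niche transitions (generalist -> specialist faster)
    spec = make_spec("CR", 5)
    q_sg = 0.05
    params = np.array([1.0, 0.2, q_sg, q_sg * cfg.sse_sim_asymmetry, 0.1, 0.1])
    phylo = simulate_sse(params, spec, n_tips=cfg.sse_tree_tips, seed=seed + 3)
    io.write_tree(phylo.tree, _out(cfg, "sse_tree.nwk"))
    io.write_tip_states(
        {t: next(iter(s)) for t, s in phylo.tip_states.items()},
        _out(cfg, "sse_states.tsv"),
        meta=cfg.provenance(),
    )


def _load_matrix_meta(cfg: RunConfig, stage: str):
    apath = Path(cfg.abundance_path) if cfg.abundance_path else _out(cfg, "abundance.tsv")
    mpath = Path(cfg.sample_meta_path) if cfg.sample_meta_path else _out(cfg, "sample_meta.tsv")
    _require(apath, stage, "simulate")
    _require(mpath, stage, "simulate")
    matrix = io.read_abundance(apath, kind=cfg.abundance_kind)
    meta = io.read_sample_meta(mpath)
    return matrix, meta


def stage_classify(cfg: RunConfig) -> None:
    matrix, meta = _load_matrix_meta(cfg, "classify")
    table = classify_matrix(
        matrix,
        meta,
        weighted=cfg.weighted_moments,
        presence_threshold=cfg.presence_threshold,
        endemic_max=cfg.endemic_max,
        ties_to_specialist=cfg.ties_to_specialist,
    )
    io.write_table(table, _out(cfg, "classification.tsv"), meta=cfg.provenance())
    joint = pd.DataFrame(
        {
            "tip_id": table["phylotype_id"],
            "state": [
                classify_joint_state(nb, rc)
                for nb, rc in zip(table["nb_class"], table["range_class"])
            ],
        }
    )
    io.write_table(joint, _out(cfg, "joint_states.tsv"), meta=cfg.provenance())


def _read_incubation(cfg: RunConfig, stage: str):
    path = _require(_out(cfg, "incubation.tsv"), stage, "simulate")
    df = io.read_table(path)
    out = {}
    for (cond, assay, rep), grp in df.groupby(["condition_ph", "assay", "replicate"]):
        tps = sorted(grp["timepoint_days"].unique())
        mats = []
        piv = grp.pivot_table(
            index="phylotype_id", columns="timepoint_days", values="value", sort=True
        )
        for t in tps:
            mats.append(
                AbundanceMatrix(
                    piv[[t]].rename(columns={t: f"{cond}_{assay}_{rep}_d{t}"}),
                    kind=ABSOLUTE,
                )
            )
        label = "native" if float(cond) == 6.0 else "perturbed"
        out[(float(cond), assay, str(rep))] = IncubationSeries(
            f"{label}_pH{cond}", assay, str(rep), tps, mats
        )
    return out


def stage_activity(cfg: RunConfig) -> None:
    cls_path = _require(_out(cfg, "classification.tsv"), "activity", "classify")
    classes = io.read_table(cls_path).set_index("phylotype_id")["nb_class"]
    inc = _read_incubation(cfg, "activity")
    inc_pids = next(iter(inc.values())).phylotype_ids
    unclassified = [p for p in inc_pids if p not in classes.index]
    if unclassified:
        logger.warning(
            "PHN-W021 %d incubation phylotypes lack a gradient classification "
            "and are excluded from phenotype sums",
            len(unclassified),
        )
    conditions = sorted({k[0] for k in inc.keys()})
    reps = sorted({k[2] for k in inc.keys()})
    act_rows, pheno_rows, dorm_rows, div_rows = [], [], [], []
    for cond in conditions:
        for rep in reps:
            dna = inc[(cond, "DNA", rep)]
            rna = inc[(cond, "RNA", rep)]
            sip = inc[(cond, "SIP", rep)]
            g = growth(
                dna.matrices[0].values.iloc[:, 0], dna.matrices[-1].values.iloc[:, 0]
            )
            ta = transcriptional_activity(rna)
            sip_ab = sip.matrices[-1].values.iloc[:, 0]
            for method, vals in (("growth", g), ("transcription", ta.attrs["total"]), ("replication", sip_ab)):
                for pid, v in vals.items():
                    act_rows.append(
                        {
                            "condition_ph": cond,
                            "replicate": rep,
                            "phylotype_id": pid,
                            "method": method,
                            "interval_start": dna.timepoints[0],
                            "interval_end": dna.timepoints[-1],
                            "value": v,
                        }
                    )
                sums = phenotype_sums(vals[vals.index.isin(classes.index)], classes)
                for cls_name, v in sums.items():
                    pheno_rows.append(
                        {
                            "condition_ph": cond,
                            "replicate": rep,
                            "method": method,
                            "phenotype": cls_name,
                            "total": v,
                        }
                    )
            resident = dna.matrices[-1].values.iloc[:, 0].sum()
            for method, active_tot in (("growth", g.sum()), ("replication", sip_ab.sum())):
                dorm_rows.append(
                    {
                        "condition_ph": cond,
                        "replicate": rep,
                        "method": method,
                        "dormancy_death_fraction": dormancy_fraction(
                            min(active_tot, resident), resident
                        ),
                    }
                )
            div_rows.append(
                {
                    "condition_ph": cond,
                    "replicate": rep,
                    "community": "resident",
                    "shannon": shannon(dna.matrices[-1].values.iloc[:, 0]),
                }
            )
            div_rows.append(
                {
                    "condition_ph": cond,
                    "replicate": rep,
                    "community": "active",
                    "shannon": shannon(sip_ab) if sip_ab.sum() > 0 else float("nan"),
                }
            )
    io.write_table(pd.DataFrame(act_rows), _out(cfg, "activity.tsv"), meta=cfg.provenance())
    pheno = pd.DataFrame(pheno_rows)
    io.write_table(pheno, _out(cfg, "phenotype_summary.tsv"), meta=cfg.provenance())
    io.write_table(pd.DataFrame(dorm_rows), _out(cfg, "dormancy.tsv"), meta=cfg.provenance())
    io.write_table(pd.DataFrame(div_rows), _out(cfg, "diversity.tsv"), meta=cfg.provenance())

    # gated specialist-vs-generalist comparison per condition (growth method)
    test_rows = []
    for cond in conditions:
        sub = pheno[(pheno["condition_ph"] == cond) & (pheno["method"] == "growth")]
        a = sub[sub["phenotype"] == "specialist"]["total"].to_numpy()
        b = sub[sub["phenotype"] == "generalist"]["total"].to_numpy()
        if len(a) >= 3 and len(b) >= 3:
            rep = gated_group_test(a, b)
            test_rows.append(
                {
                    "condition_ph": cond,
                    "test": rep.test,
                    "statistic": rep.statistic,
                    "p": rep.p,
                    "bartlett_p": rep.bartlett_p,
                }
            )
    if test_rows:
        io.write_table(pd.DataFrame(test_rows), _out(cfg, "group_tests.tsv"), meta=cfg.provenance())


def stage_phylo(cfg: RunConfig) -> None:
    matrix, meta = _load_matrix_meta(cfg, "phylo")
    tpath = Path(cfg.tree_path) if cfg.tree_path else _out(cfg, "community_tree.nwk")
    _require(tpath, "phylo", "simulate")
    tree = io.read_tree(tpath)
    cls_path = _require(_out(cfg, "classification.tsv"), "phylo", "classify")
    cls = io.read_table(cls_path).set_index("phylotype_id")
    dist = patristic_distance_matrix(tree)
    tips = set(dist.index)
    seed = _stage_seed(cfg, "phylo")
    dropped = [p for p in matrix.phylotype_ids if p not in tips]
    if dropped:
        logger.warning("PHN-W020 %d phylotypes absent from tree dropped", len(dropped))
    rows = []
    meta_by_id = {m.sample_id: m for m in meta}
    for k, s in enumerate(matrix.sample_ids):
        ab = matrix.values[s]
        ab = ab[ab.index.isin(tips)]
        if (ab > 0).sum() < 2:
            continue
        res = ses_mpd(ab, tree, n_null=cfg.n_null, seed=seed + k, dist=dist)
        rows.append(
            {
                "sample_id": s,
                "pH": meta_by_id[s].ph,
                "mpd_obs": res.mpd_obs,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "ses": res.ses,
                "p": res.p,
            }
        )
    sesdf = pd.DataFrame(rows)
    io.write_table(sesdf, _out(cfg, "sesmpd.tsv"), meta=cfg.provenance())
    reg = ses_mpd_vs_ph(sesdf["ses"], sesdf["pH"])
    io.write_table(pd.DataFrame([reg]), _out(cfg, "sesmpd_regression.tsv"), meta=cfg.provenance())

    trait = (
        cls["nb_class"]
        .map({"generalist": 1.0, "specialist": 0.0, "putative_specialist": 0.0})
        .reindex(dist.index)
        .dropna()
    )
    if trait.nunique() > 1 and len(trait) >= 3:
        ktree = tree
        if len(trait) < len(dist.index):
            ktree = tree.extract_tree_with_taxa_labels(labels=list(trait.index))
        ps = blomberg_k(ktree, trait, n_perm=cfg.n_perm, seed=seed + 10_000)
        io.write_table(
            pd.DataFrame([{"K": ps.K, "p": ps.p, "n_perm": ps.n_perm}]),
            _out(cfg, "phylosignal.tsv"),
            meta=cfg.provenance(),
        )


def stage_divfit(cfg: RunConfig) -> None:
    tpath = Path(cfg.sse_tree_path) if cfg.sse_tree_path else _out(cfg, "sse_tree.nwk")
    spath = Path(cfg.sse_states_path) if cfg.sse_states_path else _out(cfg, "sse_states.tsv")
    _require(tpath, "divfit", "simulate")
    _require(spath, "divfit", "simulate")
    tree = io.read_tree(tpath)
    states = io.read_tip_states(spath)
    phylo = LabeledPhylogeny(tree, states)
    seed = _stage_seed(cfg, "divfit")
    fits = []
    for mode in cfg.modes:
        for sid in cfg.structures:
            spec = make_spec(mode.upper(), sid)
            fits.append(
                fit_model(
                    phylo,
                    spec,
                    n_starts=cfg.n_starts,
                    seed=seed,
                    rtol=cfg.ode_rtol,
                    atol=cfg.ode_atol,
                )
            )
    if len(fits) > 1:
        ranked = compare_aic(fits)
    else:
        f = fits[0]
        ranked = pd.DataFrame(
            [
                {
                    "model": f.spec.name,
                    "mode": f.spec.mode,
                    "structure": f.spec.structure_id,
                    "k": f.k,
                    "loglik": f.loglik,
                    "AIC": f.aic,
                    "delta_AIC": 0.0,
                    "rank": 1,
                }
            ]
        )
    io.write_table(ranked, _out(cfg, "divfit_aic.tsv"), meta=cfg.provenance())
    recs = []
    for f in fits:
        recs.append(
            {
                "model": f.spec.name,
                "loglik": f.loglik,
                "AIC": f.aic,
                "k": f.k,
                "converged": f.converged,
                "params": json.dumps(dict(zip(f.spec.param_names, map(float, f.params)))),
            }
        )
    io.write_table(pd.DataFrame(recs), _out(cfg, "divfit_fits.tsv"), meta=cfg.provenance())
    best_name = ranked["model"].iloc[0]
    best = next(f for f in fits if f.spec.name == best_name)
    anc = ancestral_states(phylo, best)
    io.write_table(anc.reset_index(), _out(cfg, "ancestral_states.tsv"), meta=cfg.provenance())


def run_pipeline(cfg: RunConfig, stage: str = "all") -> int:
    """Run one stage (or ``all``); returns 0 on success."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    logger.info(
        "phniche v%s stage=%s seed=%d config=%s", __version__, stage, cfg.seed, cfg.config_hash
    )
    if stage == "simulate":
        stage_simulate(cfg)
    elif stage == "classify":
        stage_classify(cfg)
    elif stage == "activity":
        stage_activity(cfg)
    elif stage == "phylo":
        stage_phylo(cfg)
    elif stage == "divfit":
        stage_divfit(cfg)
    else:
        apath = Path(cfg.abundance_path) if cfg.abundance_path else _out(cfg, "abundance.tsv")
        if not apath.exists():
            stage_simulate(cfg)
        stage_classify(cfg)
        stage_activity(cfg)
        stage_phylo(cfg)
        stage_divfit(cfg)
    return 0
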