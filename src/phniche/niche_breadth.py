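"""pH niche-breadth index and specialist/generalist classification.

The niche breadth of phylotype *j* is a modified Levins index computed on
hydrogen-ion concentrations (not pH, whose logarithmic scale distorts
variance-based breadth measures):

    B_j = (1 / sqrt(n_j)) * (sigma_j**2 / mu_j**2)

where ``n_j`` is the number of soils in which the phylotype occurs and
``mu_j``, ``sigma_j**2`` are the mean and variance of [H+] over those soils.
Phylotypes with B at or below the median of defined B values are classed
*specialist*, those above *generalist*; single-soil phylotypes have no
defined B and are *putative specialists*.  A second, occupancy-based axis
classes phylotypes *endemic* (<= 3 soils) or *cosmopolitan*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleMeta

__all__ = [
    "SPECIALIST",
    "GENERALIST",
    "PUTATIVE_SPECIALIST",
    "ENDEMIC",
    "COSMOPOLITAN",
    "NicheBreadthRecord",
    "SingleSoilPhylotype",
    "ph_to_hplus",
    "occupancy",
    "niche_breadth_index",
    "classify_by_median",
    "range_class",
    "classify_matrix",
    "index_diagnostics",
]

SPECIALIST = "specialist"
GENERALIST = "generalist"
PUTATIVE_SPECIALIST = "putative_specialist"
ENDEMIC = "endemic"
COSMOPOLITAN = "cosmopolitan"


class SingleSoilPhylotype(ValueError):
    """Raised when B is requested for a phylotype present in < 2 samples.

    Such phylotypes cannot have a defined breadth and are classified as
    putative specialists by the caller.
    """


@dataclass
class NicheBreadthRecord:
    phylotype_id: str
    n_j: int
    mu_j: Optional[float]  # mean [H+] over occupied samples, mol/L
    sigma2_j: Optional[float]  # variance of [H+], (mol/L)^2
    B_j: Optional[float]  # undefined (None) when n_j == 1
    nb_class: Optional[str] = None
    range_class: Optional[str] = None


def ph_to_hplus(ph):
    """Convert pH to hydrogen-ion concentration, [H+] = 10**(-pH) mol/L."""
    arr = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("pH must be finite")
    out = np.power(10.0, -arr)
    return float(out) if np.isscalar(ph) or arr.ndim == 0 else out


def occupancy(matrix: AbundanceMatrix, phylotype_id: str, presence_threshold: float = 0.0) -> int:
    """Number of samples in which a phylotype is present (value > threshold)."""
    row = matrix.row(phylotype_id)
    return int(np.sum(row > presence_threshold))


def _moments(hplus: np.ndarray, weights: Optional[np.ndarray]) -> tuple:
    """Mean and variance of [H+]; unweighted uses the n-1 denominator,
    weighted uses frequency weights (abundances)."""
    if weights is None:
        mu = float(np.mean(hplus))
        sigma2 = float(np.var(hplus, ddof=1))
    else:
        w = weights / weights.sum()
        mu = float(np.sum(w * hplus))
        sigma2 = float(np.sum(w * (hplus - mu) ** 2))
    return mu, sigma2


def niche_breadth_index(
    abundances: Sequence[float],
    hplus: Sequence[float],
    weighted: bool = False,
    presence_threshold: float = 0.0,
) -> tuple:
    """Modified Levins breadth for one phylotype.

    Returns ``(n_j, mu_j, sigma2_j, B_j)`` computed over the samples in which
    the phylotype is present.  ``weighted=False`` (default) uses plain moments
    of [H+] with the n-1 variance denominator; ``weighted=True`` weights the
    moments by abundance.

    Raises
    ------
    SingleSoilPhylotype
        if fewer than two samples have presence (B undefined).
    ValueError
        if any occupied sample has [H+] <= 0.
    """
    x = np.asarray(abundances, dtype=float)
    h = np.asarray(hplus, dtype=float)
    if x.shape != h.shape:
        raise ValueError("abundances and hplus must have matching length")
    present = x > presence_threshold
    n_j = int(present.sum())
    if n_j < 2:
        raise SingleSoilPhylotype(
            f"presence in {n_j} sample(s): breadth undefined (putative specialist)"
        )
    h_occ = h[present]
    if np.any(h_occ <= 0):
        raise ValueError("[H+] must be strictly positive for occupied samples")
    mu, sigma2 = _moments(h_occ, x[present] if weighted else None)
    B = (1.0 / math.sqrt(n_j)) * (sigma2 / mu**2)
    return n_j, mu, sigma2, B


def range_class(n_j: int, endemic_max: int = 3) -> str:
    """Occupancy-based range class: endemic (n_j <= endemic_max) or cosmopolitan."""
    if n_j < 1:
        raise ValueError(f"n_j must be >= 1, got {n_j}")
    return ENDEMIC if n_j <= endemic_max else COSMOPOLITAN


def classify_by_median(
    records: Sequence[NicheBreadthRecord],
    ties_to_specialist: bool = True,
) -> dict:
    """Assign specialist/generalist by the median of defined B values.

    Records with ``n_j == 1`` are labelled putative specialists and excluded
    from the median.  With the default tie rule, B <= median -> specialist
    and B > median -> generalist; set ``ties_to_specialist=False`` for a
    strict-inequality specialist rule (B < median).

    Returns a dict of class counts; records are modified in place.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to classify")
    defined = [r.B_j for r in records if r.n_j >= 2]
    for r in records:
        if r.n_j >= 2 and r.B_j is None:
            raise ValueError(f"record {r.phylotype_id}: n_j >= 2 but B undefined")
    if not defined:
        # every phylotype is a single-soil putative specialist
        for r in records:
            r.nb_class = PUTATIVE_SPECIALIST
        return {
            SPECIALIST: 0,
            GENERALIST: 0,
            PUTATIVE_SPECIALIST: len(records),
            "median_B": None,
        }
    med = float(np.median(defined))
    counts = {SPECIALIST: 0, GENERALIST: 0, PUTATIVE_SPECIALIST: 0}
    for r in records:
        if r.n_j == 1:
            r.nb_class = PUTATIVE_SPECIALIST
        elif (r.B_j <= med) if ties_to_specialist else (r.B_j < med):
            r.nb_class = SPECIALIST
        else:
            r.nb_class = GENERALIST
        counts[r.nb_class] += 1
    counts["median_B"] = med
    return counts


def classify_matrix(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    weighted: bool = False,
    presence_threshold: float = 0.0,
    endemic_max: int = 3,
    ties_to_specialist: bool = True,
) -> pd.DataFrame:
    """Full classification of every phylotype in an abundance matrix.

    Samples are matched to metadata by id; every sample column must have a
    pH.  Returns a DataFrame with columns phylotype_id, n_j, mu_hplus,
    sigma2_hplus, B, nb_class, range_class (phylotypes with zero occupancy
    are dropped).
    """
    meta_by_id = {m.sample_id: m for m in meta}
    missing = [s for s in matrix.sample_ids if s not in meta_by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    h = np.array([meta_by_id[s].hplus for s in matrix.sample_ids])
    records = []
    for pid in matrix.phylotype_ids:
        row = matrix.row(pid)
        n_j = int(np.sum(row > presence_threshold))
        if n_j == 0:
            continue
        if n_j == 1:
            rec = NicheBreadthRecord(pid, 1, None, None, None)
        else:
            n_j, mu, s2, B = niche_breadth_index(
                row, h, weighted=weighted, presence_threshold=presence_threshold
            )
            rec = NicheBreadthRecord(pid, n_j, mu, s2, B)
        rec.range_class = range_class(rec.n_j, endemic_max=endemic_max)
        records.append(rec)
    classify_by_median(records, ties_to_specialist=ties_to_specialist)
    return pd.DataFrame(
        {
            "phylotype_id": [r.phylotype_id for r in records],
            "n_j": [r.n_j for r in records],
            "mu_hplus": [r.mu_j for r in records],
            "sigma2_hplus": [r.sigma2_j for r in records],
            "B": [r.B_j for r in records],
            "nb_class": [r.nb_class for r in records],
            "range_class": [r.range_class for r in records],
        }
    )


def index_diagnostics(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    presence_threshold: float = 0.0,
    plot_path: Optional[str] = None,
) -> pd.DataFrame:
    """Tabulate candidate breadth indices against mean abundance rank.

    For each phylotype with n_j >= 2 this reports sigma (the [H+] standard
    deviation), the standard error sigma/sqrt(n), and the modified Levins
    index B, together with the phylotype's mean-abundance rank.  A breadth
    index suitable for specialist/generalist attribution should be
    distributed homogeneously across the abundance gradient; the table (and
    optional scatter plot) lets the analyst check that, and also reports the
    Spearman correlation of each candidate with abundance rank.  No
    automatic selection is performed.
    """
    from scipy.stats import spearmanr

    meta_by_id = {m.sample_id: m for m in meta}
    h = np.array([meta_by_id[s].hplus for s in matrix.sample_ids])
    rows = []
    for pid in matrix.phylotype_ids:
        vals = matrix.row(pid)
        present = vals > presence_threshold
        n_j = int(present.sum())
        if n_j < 2:
            continue
        mu, s2 = _moments(h[present], None)
        sigma = math.sqrt(s2)
        rows.append(
            {
                "phylotype_id": pid,
                "mean_abundance": float(vals.mean()),
                "sigma": sigma,
                "sigma_se": sigma / math.sqrt(n_j),
                "B": (1.0 / math.sqrt(n_j)) * (s2 / mu**2),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no phylotypes with n_j >= 2")
    df["abundance_rank"] = df["mean_abundance"].rank()
    for col in ("sigma", "sigma_se", "B"):
        rho, _ = spearmanr(df["abundance_rank"], df[col])
        df.attrs[f"spearman_{col}"] = float(rho)
    if plot_path is not None:  # pragma: no cover - plotting glue
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True)
        for ax, col in zip(axes, ("sigma", "sigma_se", "B")):
            ax.scatter(df["abundance_rank"], df[col], s=8)
            ax.set_xlabel("abundance rank")
            ax.set_ylabel(col)
            ax.set_yscale("log")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
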