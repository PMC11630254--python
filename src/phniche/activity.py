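"""Growth, transcriptional activity, dormancy and diversity analyses.

The incubation experiments follow soil microcosms over 30 days (sampling at
days 0, 1, 3, 10, 30) under a native pH 6.0 condition or after a pH shift to
4.5 or 7.5.  Phylotype relative abundances from amplicon sequencing are
scaled to absolute *amoA* copies per gram of soil with per-sample qPCR
totals.  Activity is the *increase* in absolute abundance — between the
final and initial time points for DNA (growth), or summed over successive
time-point increases for RNA (transcriptional activity); decreases are
truncated to zero, since a loss of copies is not evidence of activity.  The
dormant-plus-dead fraction of a community is the complement of the
active:resident cell ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

from .datatypes import ABSOLUTE, RELATIVE, AbundanceMatrix
from .niche_breadth import GENERALIST, PUTATIVE_SPECIALIST, SPECIALIST

logger = logging.getLogger(__name__)

__all__ = [
    "IncubationSeries",
    "GatedTestReport",
    "to_cell_abundance",
    "growth",
    "transcriptional_activity",
    "phenotype_sums",
    "dormancy_fraction",
    "shannon",
    "bray_curtis",
    "bray_curtis_matrix",
    "gated_group_test",
    "extreme_ph_groups",
]


@dataclass
class IncubationSeries:
    """Absolute phylotype abundances along one incubation time course."""

    condition: str
    assay: str  # DNA | RNA | SIP
    replicate: str
    timepoints: Sequence[int]  # days, strictly increasing
    matrices: Sequence[AbundanceMatrix]  # one per time point, kind=absolute

    def __post_init__(self) -> None:
        tp = list(self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(f"timepoints must be strictly increasing: {tp}")
        if len(tp) != len(self.matrices):
            raise ValueError("one abundance matrix required per time point")
        ids0 = self.matrices[0].phylotype_ids
        for m in self.matrices[1:]:
            if m.phylotype_ids != ids0:
                raise ValueError("phylotype set must be identical across time points")

    @property
    def phylotype_ids(self) -> list:
        return self.matrices[0].phylotype_ids


def to_cell_abundance(rel: AbundanceMatrix, qpcr_totals: Dict[str, float]) -> AbundanceMatrix:
    """Scale a relative matrix to absolute copies/g using per-sample qPCR totals."""
    if rel.kind != RELATIVE:
        raise ValueError("input matrix must be relative")
    missing = [s for s in rel.sample_ids if s not in qpcr_totals]
    if missing:
        raise ValueError(f"missing qPCR totals for samples: {missing}")
    totals = np.array([qpcr_totals[s] for s in rel.sample_ids], dtype=float)
    if (totals < 0).any():
        raise ValueError("qPCR totals must be >= 0")
    out = rel.values.to_numpy() * totals[np.newaxis, :]
    return AbundanceMatrix(
        pd.DataFrame(out, index=rel.values.index, columns=rel.values.columns),
        kind=ABSOLUTE,
    )


def _truncated_diff(final: pd.Series, initial: pd.Series) -> pd.Series:
    return (final - initial).clip(lower=0.0)


def growth(abund_initial: pd.Series, abund_final: pd.Series) -> pd.Series:
    """Per-phylotype growth: max(0, final - initial) absolute abundance.

    Negative differentials (abundance loss) are reported as null.
    """
    if not abund_initial.index.equals(abund_final.index):
        raise ValueError("initial and final abundances must index the same phylotypes")
    return _truncated_diff(abund_final, abund_initial)


def transcriptional_activity(series: IncubationSeries) -> pd.DataFrame:
    """Per-interval truncated transcript increases and their per-phylotype sum.

    Returns a long DataFrame with columns phylotype_id, interval_start,
    interval_end, value; the per-phylotype total over all intervals is in
    ``DataFrame.attrs["total"]`` (a Series).
    """
    if len(series.timepoints) < 2:
        raise ValueError("at least two time points required")
    rows = []
    total = pd.Series(0.0, index=series.phylotype_ids)
    for k in range(len(series.timepoints) - 1):
        t0, t1 = series.timepoints[k], series.timepoints[k + 1]
        x0 = series.matrices[k].values.iloc[:, 0]
        x1 = series.matrices[k + 1].values.iloc[:, 0]
        d = _truncated_diff(x1, x0)
        total = total + d
        for pid, v in d.items():
            rows.append(
                {"phylotype_id": pid, "interval_start": t0, "interval_end": t1, "value": v}
            )
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    return df


def phenotype_sums(activity: pd.Series, classes: pd.Series) -> pd.Series:
    """Sum activity (or abundance) within specialist/generalist/putative classes.

    ``classes`` maps phylotype_id -> nb_class.  Conservation holds exactly:
    the three sums add up to ``activity.sum()``.
    """
    unclassified = [pid for pid in activity.index if pid not in classes.index]
    if unclassified:
        raise ValueError(f"unclassified phylotypes: {unclassified}")
    out = pd.Series(0.0, index=[SPECIALIST, GENERALIST, PUTATIVE_SPECIALIST])
    grouped = activity.groupby(classes.reindex(activity.index)).sum()
    for k, v in grouped.items():
        if k not in out.index:
            raise ValueError(f"unknown phenotype class {k!r}")
        out[k] = v
    return out


def dormancy_fraction(active_total: float, resident_total: float) -> float:
    """Dormant + dead fraction: 1 - active/resident, clipped to [0, 1]."""
    if resident_total <= 0:
        raise ValueError("resident total must be > 0 for a defined dormancy fraction")
    if active_total > resident_total:
        logger.warning(
            "PHN-W001 active (%g) exceeds resident (%g); dormancy clipped to 0",
            active_total,
            resident_total,
        )
    return float(np.clip(1.0 - active_total / resident_total, 0.0, 1.0))


def shannon(abundances: Sequence[float]) -> float:
    """Shannon diversity H = -sum p ln p (nats), no rarefaction."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be >= 0")
    s = x.sum()
    if s <= 0:
        raise ValueError("at least one abundance must be positive")
    p = x[x > 0] / s
    return float(-np.sum(p * np.log(p)))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1]."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("abundances must be >= 0")
    if xa.sum() == 0 and ya.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero communities")
    return float(braycurtis(xa, ya))


def bray_curtis_matrix(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Square Bray-Curtis distance matrix over samples."""
    ids = matrix.sample_ids
    arr = matrix.values.to_numpy().T
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(arr[i], arr[j])
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass
class GatedTestReport:
    test: str  # "welch" | "kruskal"
    statistic: float
    p: float
    shapiro_p: tuple
    bartlett_p: float
    alpha: float
    gates_passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.gates_passed = self.test == "welch"


def gated_group_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
) -> GatedTestReport:
    """Assumption-gated two-group comparison.

    Runs a Shapiro-Wilk normality test on each group and a Bartlett test of
    variance homogeneity across the groups, all at ``alpha``.  If all three
    pass, a Welch two-sample t-test is used; otherwise Kruskal-Wallis.  (The
    Welch test does not itself require homogeneous variances; the variance
    gate is part of the procedure being reproduced and is kept as stated.)
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for tiny/constant input
        sa = stats.shapiro(a).pvalue
        sb = stats.shapiro(b).pvalue
        try:
            bart = stats.bartlett(a, b).pvalue
        except ValueError:
            bart = 0.0  # zero-variance group: gate fails
    if np.isnan(bart):
        bart = 0.0
    if sa > alpha and sb > alpha and bart > alpha:
        res = stats.ttest_ind(a, b, equal_var=False)
        return GatedTestReport("welch", float(res.statistic), float(res.pvalue), (sa, sb), bart, alpha)
    res = stats.kruskal(a, b)
    return GatedTestReport("kruskal", float(res.statistic), float(res.pvalue), (sa, sb), bart, alpha)


def extreme_ph_groups(
    ph: Sequence[float],
    low: float = 5.0,
    high: float = 8.5,
) -> np.ndarray:
    """Label samples as 'extreme' (pH <= low or >= high) or 'classical'.

    Soil pH on Earth mostly spans ~3.5-10; soils at or below pH 5.0 (or at
    or above 8.5) are treated as approaching the limits of the range.
    """
    p = np.asarray(ph, dtype=float)
    return np.where((p <= low) | (p >= high), "extreme", "classical")
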