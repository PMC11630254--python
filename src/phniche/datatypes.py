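"""Core containers shared across the pipeline.

An :class:`AbundanceMatrix` holds phylotype x sample abundances (relative
fractions, read counts, or absolute *amoA* copies per gram of soil) together
with per-sample metadata (:class:`SampleMeta`): soil pH, the derived hydrogen
ion concentration, optional qPCR totals, incubation time point, condition and
assay labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "SampleMeta", "RELATIVE", "ABSOLUTE"]

RELATIVE = "relative"
ABSOLUTE = "absolute"

#: tolerance on relative-abundance column sums
_REL_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    ``hplus`` (mol/L) is derived from pH as 10**(-pH); a supplied value is
    validated against that identity to 1e-12 relative tolerance.
    """

    sample_id: str
    ph: float
    hplus: float = field(default=None)  # type: ignore[assignment]
    qpcr_total: Optional[float] = None
    timepoint_days: Optional[int] = None
    condition: Optional[str] = None
    assay: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ph):
            raise ValueError(f"sample {self.sample_id}: non-finite pH {self.ph}")
        expected = 10.0 ** (-self.ph)
        if self.hplus is None:
            object.__setattr__(self, "hplus", expected)
        elif abs(self.hplus - expected) > 1e-12 * max(abs(expected), 1e-300):
            raise ValueError(
                f"sample {self.sample_id}: hplus {self.hplus!r} inconsistent "
                f"with pH {self.ph} (expected {expected!r})"
            )
        if self.qpcr_total is not None and self.qpcr_total < 0:
            raise ValueError(f"sample {self.sample_id}: negative qPCR total")
        if self.timepoint_days is not None and self.timepoint_days < 0:
            raise ValueError(f"sample {self.sample_id}: negative time point")
        if self.assay is not None and self.assay not in ("DNA", "RNA", "SIP"):
            raise ValueError(f"sample {self.sample_id}: unknown assay {self.assay!r}")


class AbundanceMatrix:
    """Phylotype x sample abundance table.

    Parameters
    ----------
    values
        DataFrame with phylotype ids as the index and sample ids as columns,
        or anything :func:`pandas.DataFrame` accepts plus explicit id lists.
    kind
        ``"relative"`` (each sample column sums to 1, all-zero columns
        allowed and flagged) or ``"absolute"`` (copies per gram, counts...).
    """

    def __init__(
        self,
        values,
        kind: str,
        phylotype_ids: Optional[Sequence[str]] = None,
        sample_ids: Optional[Sequence[str]] = None,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            df = values.copy()
        else:
            df = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=list(phylotype_ids),
                columns=list(sample_ids),
            )
        df = df.astype(float)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate phylotype ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = df.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("abundance matrix contains non-finite values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at phylotype {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        if kind not in (RELATIVE, ABSOLUTE):
            raise ValueError(f"kind must be 'relative' or 'absolute', got {kind!r}")
        if kind == RELATIVE:
            sums = arr.sum(axis=0)
            bad = ~np.isclose(sums, 1.0, rtol=0, atol=_REL_SUM_TOL) & (sums != 0.0)
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"relative matrix: column {df.columns[j]!r} sums to "
                    f"{sums[j]!r}, expected 1 (tolerance {_REL_SUM_TOL})"
                )
            self.empty_samples = [c for c, s in zip(df.columns, sums) if s == 0.0]
        else:
            self.empty_samples = [
                c for c, s in zip(df.columns, arr.sum(axis=0)) if s == 0.0
            ]
        self.values = df
        self.kind = kind

    @property
    def phylotype_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def row(self, phylotype_id: str) -> np.ndarray:
        if phylotype_id not in self.values.index:
            raise KeyError(f"unknown phylotype {phylotype_id!r}")
        return self.values.loc[phylotype_id].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"AbundanceMatrix({n} phylotypes x {m} samples, kind={self.kind})"
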