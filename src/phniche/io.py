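"""Readers and writers for the pipeline's on-disk formats.

Canonical table dialect: UTF-8 TSV with '#'-prefixed header metadata lines;
CSV is accepted on read (delimiter chosen by file extension).  Trees are
newick with branch lengths; tip states are a two-column TSV (tip_id,
state), with ambiguous states as comma-joined sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .datatypes import AbundanceMatrix, SampleMeta

__all__ = [
    "FormatError",
    "read_abundance",
    "write_abundance",
    "read_sample_meta",
    "write_sample_meta",
    "write_table",
    "read_table",
    "read_tree",
    "write_tree",
    "read_tip_states",
    "write_tip_states",
]


class FormatError(ValueError):
    pass


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_df(path: Union[str, Path], index_col=0) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep=_sep(path), comment="#", index_col=index_col)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _meta_header(meta: Optional[Mapping] = None) -> str:
    lines = [f"# phniche v{__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def read_abundance(
    path: Union[str, Path],
    kind: str,
    orientation: str = "rows",
) -> AbundanceMatrix:
    """Read a phylotype x sample abundance matrix.

    ``orientation="rows"`` means phylotypes are rows (the canonical layout);
    ``"columns"`` transposes on read.  Negative values, duplicate ids and
    mis-normalised relative columns are rejected with the offending
    row/column named.
    """
    df = _read_df(path)
    if orientation == "columns":
        df = df.T
    elif orientation != "rows":
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    arr = df.to_numpy()
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise FormatError(
            f"{path}: negative value at row {df.index[i]!r} (line {i + 2}), "
            f"column {df.columns[j]!r}"
        )
    try:
        return AbundanceMatrix(df, kind=kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_abundance(
    matrix: AbundanceMatrix, path: Union[str, Path], meta: Optional[Mapping] = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_header({**(meta or {}), "kind": matrix.kind}))
        matrix.values.to_csv(fh, sep=_sep(path), index_label="phylotype_id")


def read_sample_meta(path: Union[str, Path]) -> List[SampleMeta]:
    """Sample metadata TSV: sample_id, pH, optional qpcr_total,
    timepoint_days, condition, assay."""
    df = _read_df(path, index_col=None)
    if "sample_id" not in df.columns or "pH" not in df.columns:
        raise FormatError(f"{path}: need at least sample_id and pH columns")
    out = []
    for _, row in df.iterrows():
        def _opt(col, cast=float):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                ph=float(row["pH"]),
                qpcr_total=_opt("qpcr_total"),
                timepoint_days=_opt("timepoint_days", int),
                condition=_opt("condition", str),
                assay=_opt("assay", str),
            )
        )
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample ids")
    return out


def write_sample_meta(
    meta: List[SampleMeta], path: Union[str, Path], header: Optional[Mapping] = None
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "pH": [m.ph for m in meta],
            "qpcr_total": [m.qpcr_total for m in meta],
            "timepoint_days": [m.timepoint_days for m in meta],
            "condition": [m.condition for m in meta],
            "assay": [m.assay for m in meta],
        }
    )
    with open(path, "w") as fh:
        fh.write(_meta_header(header))
        df.to_csv(fh, sep=_sep(path), index=False)


def write_table(df: pd.DataFrame, path: Union[str, Path], meta: Optional[Mapping] = None, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, sep=_sep(path), index=index)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return _read_df(path, index_col=None)


def read_tree(path: Union[str, Path], require_lengths: bool = True) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    if require_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None and edge.length is None:
                raise FormatError(f"{path}: branch without length")
    return tree


def write_tree(tree: dendropy.Tree, path: Union[str, Path]) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tip_states(path: Union[str, Path]) -> Dict[str, object]:
    """Two-column TSV tip_id -> state; 'ES,CS' style entries become sets."""
    df = _read_df(path, index_col=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (tip_id, state)")
    out: Dict[str, object] = {}
    for _, row in df.iterrows():
        tid, state = str(row.iloc[0]), str(row.iloc[1])
        out[tid] = set(state.split(",")) if "," in state else state
    return out


def write_tip_states(states: Mapping[str, object], path: Union[str, Path], meta: Optional[Mapping] = None) -> None:
    rows = []
    for tid, s in states.items():
        rows.append({"tip_id": tid, "state": ",".join(sorted(s)) if isinstance(s, (set, frozenset)) else s})
    write_table(pd.DataFrame(rows), path, meta=meta)
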