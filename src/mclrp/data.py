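"""Core matrix containers, normalization, alignment, and delimited-text I/O.

Drug-response matrices are cell line x drug tables with missing entries;
expression matrices are complete cell line x gene tables; mutation profiles
are binary cell line x gene tables. All three travel as plain TSV/CSV with a
header row of column ids and a first column of row ids.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Orientation = Literal["higher_is_sensitive", "lower_is_sensitive"]

#: Missing-value tokens accepted in response files (case-insensitive).
NA_TOKENS = frozenset({"", "na", "nan"})


@dataclass
class NormState:
    """Per-column mean and standard deviation recorded at normalization time.

    Statistics are computed over observed entries only, with the sample
    (k-1 divisor) standard deviation, so observed entries round-trip exactly.
    """

    means: np.ndarray
    sds: np.ndarray
    ddof: int = 1


@dataclass
class ResponseMatrix:
    """Partially observed cell line x drug response matrix.

    ``values[i, j]`` is meaningful only where ``mask[i, j] == 1`` (the
    observed set Omega); unobserved entries hold NaN before normalization
    and 0 afterwards.
    """

    values: np.ndarray
    mask: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    orientation: Orientation = "higher_is_sensitive"
    norm_state: Optional[NormState] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        m, p = self.values.shape
        if len(self.row_ids) != m or len(self.col_ids) != p:
            raise ValueError("id lengths do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_normalized(self) -> bool:
        return self.norm_state is not None

    def observed_values(self, col: int) -> np.ndarray:
        return self.values[self.mask[:, col], col]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            self.values.copy(), self.mask.copy(), list(self.row_ids),
            list(self.col_ids), self.orientation,
            None if self.norm_state is None else NormState(
                self.norm_state.means.copy(), self.norm_state.sds.copy(),
                self.norm_state.ddof),
        )


@dataclass
class ExpressionMatrix:
    """Complete cell line x gene expression matrix."""

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("expression matrix must be complete (no NaN)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MutationProfile:
    """Binary cell line x gene mutation calls (1 = mutant, 0 = wild-type)."""

    calls: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls)
        if not np.isin(calls, (0, 1)).all():
            raise ValueError("mutation calls must be binary {0,1}")
        self.calls = calls.astype(np.int8)


@dataclass
class TissueMap:
    """Cell line id -> tissue label (one label per cell line)."""

    assignments: dict[str, str]


@dataclass
class AlignedBundle:
    """All structures restricted to a shared, canonically ordered row set."""

    response: ResponseMatrix
    expression: ExpressionMatrix
    mutations: Optional[MutationProfile] = None
    tissues: Optional[TissueMap] = None
    dropped_ids: list[str] = field(default_factory=list)


def _detect_sep(path: Path) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter


def _parse_cell(token: str, row_id: str, col_id: str, allow_missing: bool) -> float:
    token = token.strip()
    if token.lower() in NA_TOKENS:
        if not allow_missing:
            raise ValueError(
                f"missing value at ({row_id}, {col_id}) in a complete matrix: "
                f"gene/column {col_id!r} has a missing measurement")
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"non-numeric cell {token!r} at row {row_id!r}, column {col_id!r}"
        ) from None


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate row ids: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column ids: {dups}")
    return df


def read_matrix(path: str | Path,
                kind: Literal["response", "expression", "mutation"],
                orientation: Orientation = "higher_is_sensitive"):
    """Read a typed matrix from delimited text.

    Response files may encode missing entries as an empty cell, ``NA`` or
    ``NaN`` (case-insensitive); expression files must be complete; mutation
    files must be strictly binary.
    """
    df = _read_frame(path)
    row_ids = df.index.tolist()
    col_ids = df.columns.tolist()
    allow_missing = kind == "response"
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(col_ids):
            values[i, j] = _parse_cell(raw[i, j], rid, cid, allow_missing)

    if kind == "response":
        mask = ~np.isnan(values)
        return ResponseMatrix(values, mask, row_ids, col_ids, orientation)
    if kind == "expression":
        return ExpressionMatrix(values, row_ids, col_ids)
    if kind == "mutation":
        if not np.isin(values, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
            raise ValueError(
                f"mutation matrix must be binary; value {values[tuple(bad)]} "
                f"at row {row_ids[bad[0]]!r}, column {col_ids[bad[1]]!r}")
        return MutationProfile(values.astype(np.int8), row_ids, col_ids)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(obj, path: str | Path) -> None:
    """Write a typed matrix back to delimited text (dialect from extension).

    Unobserved response entries are written as empty cells so that
    ``read_matrix`` round-trips values, ids and mask exactly.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() != ".csv" else ","
    if isinstance(obj, ResponseMatrix):
        vals = obj.values.astype(float).copy()
        vals[~obj.mask] = np.nan
        df = pd.DataFrame(vals, index=obj.row_ids, columns=obj.col_ids)
    elif isinstance(obj, ExpressionMatrix):
        df = pd.DataFrame(obj.values, index=obj.row_ids, columns=obj.gene_ids)
    elif isinstance(obj, MutationProfile):
        df = pd.DataFrame(obj.calls, index=obj.row_ids, columns=obj.gene_ids)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    df.to_csv(path, sep=sep, na_rep="")


def read_tissue_map(path: str | Path) -> TissueMap:
    """Read a two-column (cell_line_id, tissue) TSV, with or without header."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, header=None)
    first = df.iloc[0]
    if first.iloc[0].lower() in {"cell_line_id", "cell_line", "id"}:
        df = df.iloc[1:]
    return TissueMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_tissue_map(tm: TissueMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_line_id\ttissue\n")
        for cid, tissue in tm.assignments.items():
            fh.write(f"{cid}\t{tissue}\n")


def normalize_response(raw: ResponseMatrix) -> ResponseMatrix:
    """Zero-fill missing entries and standardize each drug column.

    Column means and sample standard deviations are computed over observed
    entries only, so heavily missing columns are not biased by the zero
    fill; after standardization the fill value 0 coincides with the
    observed-entry column mean. The recorded ``norm_state`` allows exact
    de-normalization of observed entries.
    """
    m, p = raw.shape
    means = np.empty(p)
    sds = np.empty(p)
    out = np.zeros((m, p))
    for j in range(p):
        obs = raw.observed_values(j)
        if obs.size < 2:
            raise ValueError(
                f"drug {raw.col_ids[j]!r} has fewer than 2 observed entries")
        mu = obs.mean()
        sd = obs.std(ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            raise ValueError(
                f"drug {raw.col_ids[j]!r} has constant observed values")
        means[j] = mu
        sds[j] = sd
        col = raw.values[:, j]
        out[raw.mask[:, j], j] = (col[raw.mask[:, j]] - mu) / sd
    return ResponseMatrix(out, raw.mask.copy(), list(raw.row_ids),
                          list(raw.col_ids), raw.orientation,
                          NormState(means, sds))


def denormalize(rm: ResponseMatrix, values: Optional[np.ndarray] = None) -> np.ndarray:
    """Map a normalized-scale matrix back to raw measurement units."""
    if rm.norm_state is None:
        raise ValueError("response matrix carries no norm_state")
    vals = rm.values if values is None else np.asarray(values, dtype=float)
    return vals * rm.norm_state.sds + rm.norm_state.means


def align(response: ResponseMatrix, expression: ExpressionMatrix,
          mutations: Optional[MutationProfile] = None,
          tissues: Optional[TissueMap] = None) -> AlignedBundle:
    """Restrict all structures to the shared cell lines, in response order."""
    sets = [set(expression.row_ids)]
    if mutations is not None:
        sets.append(set(mutations.row_ids))
    common = set(response.row_ids).intersection(*sets)
    if not common:
        raise ValueError("no shared cell line ids across inputs")
    keep = [rid for rid in response.row_ids if rid in common]
    dropped = sorted(
        (set(response.row_ids) | set().union(*sets)) - common)
    if dropped:
        logger.info("align: dropped %d unshared cell lines: %s",
                    len(dropped), dropped[:10])

    ridx = [response.row_ids.index(r) for r in keep]
    resp = ResponseMatrix(response.values[ridx], response.mask[ridx], keep,
                          list(response.col_ids), response.orientation,
                          response.norm_state)
    eidx = [expression.row_ids.index(r) for r in keep]
    expr = ExpressionMatrix(expression.values[eidx], keep,
                            list(expression.gene_ids))
    mut = None
    if mutations is not None:
        midx = [mutations.row_ids.index(r) for r in keep]
        mut = MutationProfile(mutations.calls[midx], keep,
                              list(mutations.gene_ids))
    tis = None
    if tissues is not None:
        tis = TissueMap({k: v for k, v in tissues.assignments.items()
                         if k in common})
    return AlignedBundle(resp, expr, mut, tis, dropped)


@dataclass
class MaskSummary:
    n_rows: int
    n_cols: int
    total_entries: int
    observed: int
    missing: int
    missing_pct: float

    def as_dict(self) -> dict:
        return {
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "total_entries": self.total_entries, "observed": self.observed,
            "missing": self.missing, "missing_pct": self.missing_pct,
        }


def mask_summary(rm: ResponseMatrix, ndigits: int = 1) -> MaskSummary:
    """Summarize matrix geometry and missingness (percentage rounded)."""
    m, p = rm.shape
    total = m * p
    observed = int(rm.mask.sum())
    missing = total - observed
    pct = round(100.0 * missing / total, ndigits)
    summary = MaskSummary(m, p, total, observed, missing, pct)
    logger.info("mask_summary: %s", summary.as_dict())
    return summary
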