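"""Expression-matrix input, probe summarization and chip scaling.

The entry point for every downstream stage is the :class:`ExpressionMatrix`:
a dense genes x samples table of finite, non-negative expression values
(intensity-like units, e.g. MAS5-normalized microarray signal). Values are
used untransformed; no logging is applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_map",
    "summarize_probes",
    "scale_normalize",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples table of finite non-negative expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique row (gene or probe) identifiers.
    sample_ids : list of str
        Unique column (sample / chip) identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Dense float matrix, finite and non-negative.
    meta : dict
        Free-form provenance (e.g. the non-negativity offset applied by the
        simulator).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return a genes x samples DataFrame view (copy)."""
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "ExpressionMatrix":
        """Build from a genes x samples DataFrame."""
        return cls(
            gene_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            meta=dict(meta or {}),
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {', '.join(sorted(dups))}")


def read_expression_matrix(
    path,
    genes_in: str = "rows",
    missing: str = "reject",
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    Layout: first column holds gene/probe identifiers, header row holds sample
    identifiers (``genes_in="rows"``); pass ``genes_in="columns"`` for the
    transposed layout. Complete cases are required: by default a file with
    missing cells is rejected (``missing="reject"``); ``missing="drop"``
    removes incomplete gene rows instead.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    if missing not in ("reject", "drop"):
        raise ValueError("missing must be 'reject' or 'drop'")
    raw = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if raw.empty:
        raise ValueError(f"empty expression matrix in {path}")
    if genes_in == "columns":
        raw = raw.T
    _check_unique([str(i) for i in raw.index], "gene")
    _check_unique([str(c) for c in raw.columns], "sample")

    def _parse(cell):
        # float() is correctly rounded; pandas' to_numeric fast path is not
        if pd.isna(cell):
            return np.nan
        try:
            return float(cell)
        except ValueError:
            return np.nan

    numeric = raw.map(_parse)
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        if missing == "reject":
            n = int(numeric.isna().to_numpy().sum())
            raise ValueError(f"{n} missing value(s); pass missing='drop' to drop incomplete rows")
        numeric = numeric.dropna(axis=0, how="any")
        if numeric.empty:
            raise ValueError("all rows dropped as incomplete")
    return ExpressionMatrix.from_frame(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path, genes_in: str = "rows") -> None:
    """Write a TSV readable back by :func:`read_expression_matrix`.

    Uses repr-precision floats so a write/read roundtrip is bit-exact.
    """
    frame = matrix.to_frame()
    if genes_in == "columns":
        frame = frame.T
    elif genes_in != "rows":
        raise ValueError("genes_in must be 'rows' or 'columns'")
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_probe_map(path) -> pd.DataFrame:
    """Read a two-column probe->gene TSV (header ``probe_id``, ``gene_id``)."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if list(pm.columns[:2]) != ["probe_id", "gene_id"]:
        raise ValueError("probe map must have header columns probe_id, gene_id")
    pm = pm[["probe_id", "gene_id"]]
    if pm["probe_id"].duplicated().any():
        dups = sorted(pm.loc[pm["probe_id"].duplicated(), "probe_id"].unique())
        raise ValueError(f"duplicate probe_id entries: {', '.join(dups)}")
    return pm


def summarize_probes(matrix: ExpressionMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by per-sample probe means.

    Every probe row of ``matrix`` must be mapped, and every mapped probe must
    be present in ``matrix`` (the map belongs to this chip). Output rows are in
    lexicographic gene order; each cell is the arithmetic mean of the mapped
    probes' values in that sample, so it never leaves the contributing probes'
    range.
    """
    mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    unmapped = [p for p in matrix.gene_ids if p not in mapping]
    if unmapped:
        raise ValueError(f"probes without mapping: {', '.join(sorted(unmapped))}")
    missing = sorted(set(mapping) - set(matrix.gene_ids))
    if missing:
        raise ValueError(f"mapped probes absent from matrix: {', '.join(missing)}")
    frame = matrix.to_frame()
    genes = frame.groupby([mapping[p] for p in matrix.gene_ids]).mean()
    genes = genes.sort_index()
    return ExpressionMatrix.from_frame(genes, meta=dict(matrix.meta))


def scale_normalize(matrix: ExpressionMatrix, target_mean: float = 1000.0) -> ExpressionMatrix:
    """Scale each sample (chip) so its mean expression equals ``target_mean``.

    Mirrors the second scaling normalization applied after MAS5 to make chips
    comparable. Rescaling is per-column multiplicative, so within-column rank
    order is preserved and the operation is idempotent.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    col_means = matrix.values.mean(axis=0)
    zero = np.flatnonzero(col_means <= 0)
    if zero.size:
        names = ", ".join(matrix.sample_ids[i] for i in zero)
        raise ValueError(f"sample(s) with non-positive mean cannot be scaled: {names}")
    scaled = matrix.values * (target_mean / col_means)[None, :]
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=scaled,
        meta=dict(matrix.meta),
    )
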