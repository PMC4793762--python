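"""Low-order partial correlations and the co-expression network.

Step 1 of the pipeline. For every gene pair the *direct* correlation is the
second-order Pearson partial correlation r_xy.zq (conditioning on two other
network genes z, q) and the *indirect* correlation is the difference between
the zeroth-order correlation and the direct one:

    r_zero     = cov(x, y) / sqrt(var(x) var(y))
    r_xy.z     = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))
    r_xy.zq    = (r_xy.z - r_xq.z r_yq.z) / sqrt((1 - r_xq.z^2)(1 - r_yq.z^2))
    r_indirect = r_zero - r_direct

so r_direct + r_indirect == r_zero holds exactly by construction. Only pairs
whose filtered correlation is significant (two-sided t test, p < alpha) become
network edges.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateConditioningError",
    "CoexpressionEdge",
    "CoexpressionNetwork",
    "partial_correlation",
    "partial_pvalue",
    "build_coexpression_network",
]

# denominators below this are treated as degenerate (conditioner collinear
# with x or y); the affected conditioning pair is skipped
_EPS = 1e-12


class DegenerateConditioningError(ValueError):
    """A conditioner is (numerically) perfectly correlated with x or y."""


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in x or y")
    return float(np.clip((xc @ yc) / np.sqrt(vx * vy), -1.0, 1.0))


def _first_order(r_xy: float, r_xz: float, r_yz: float) -> float:
    den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if den <= _EPS:
        raise DegenerateConditioningError(
            "conditioner perfectly correlated with x or y; partial correlation undefined"
        )
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(den), -1.0, 1.0))


def partial_correlation(x, y, conditioners=()) -> float:
    """Pearson partial correlation of ``x`` and ``y`` given 0-2 conditioners.

    With no conditioners this is the plain Pearson coefficient; with one or
    two it applies the first-order recursion once or twice. The result is
    clamped to [-1, 1] against floating drift.

    Raises
    ------
    ValueError
        If x or y has zero variance, or vector lengths disagree / are too
        short (n >= 3 + number of conditioners).
    DegenerateConditioningError
        If a recursion denominator vanishes (conditioner collinear with x
        or y); callers building networks skip the conditioning pair.
    """
    conditioners = [np.asarray(c, dtype=float) for c in conditioners]
    if len(conditioners) > 2:
        raise ValueError("at most two conditioners are supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n or any(c.shape[0] != n for c in conditioners):
        raise ValueError("all vectors must have the same length")
    if n < 3 + len(conditioners):
        raise ValueError(f"need at least {3 + len(conditioners)} samples, got {n}")

    if not conditioners:
        return _pearson(x, y)
    if len(conditioners) == 1:
        z = conditioners[0]
        return _first_order(_pearson(x, y), _pearson(x, z), _pearson(y, z))
    z, q = conditioners
    r_xy_z = _first_order(_pearson(x, y), _pearson(x, z), _pearson(y, z))
    r_xq_z = _first_order(_pearson(x, q), _pearson(x, z), _pearson(q, z))
    r_yq_z = _first_order(_pearson(y, q), _pearson(y, z), _pearson(q, z))
    return _first_order(r_xy_z, r_xq_z, r_yq_z)


def partial_pvalue(r: float, n: int, order: int) -> float:
    """Two-sided p-value for a (partial) Pearson correlation.

    Classical exact null under Gaussianity: t = r sqrt(df / (1 - r^2)) with
    df = n - 2 - order degrees of freedom, where ``order`` is the number of
    conditioned variables (0, 1 or 2).
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    df = n - 2 - order
    if df < 1:
        raise ValueError(f"insufficient samples: n={n} gives df={df} < 1 at order {order}")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


@dataclass
class CoexpressionEdge:
    """A significant unordered gene pair with its correlation decomposition.

    ``gene_a < gene_b`` lexicographically; ``conditioning_pair`` records the
    two genes (z, q) behind ``r_direct`` for auditability.
    """

    gene_a: str
    gene_b: str
    r_zero: float
    r_direct: float
    r_indirect: float
    p_value: float
    conditioning_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-pair is not a valid edge")
        if self.gene_a > self.gene_b:
            raise ValueError("edge genes must be stored with gene_a < gene_b")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class CoexpressionNetwork:
    """Collection of significant co-expression edges plus build provenance."""

    edges: list[CoexpressionEdge]
    n_samples: int
    alpha: float
    conditioning_strategy: str
    filter_on: str = "direct"
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ValueError("second-order partial correlation needs n_samples >= 5")
        pairs = [e.pair for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate edges for the same unordered pair")

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "r_zero": e.r_zero,
                    "r_direct": e.r_direct,
                    "r_indirect": e.r_indirect,
                    "p_value": e.p_value,
                    "conditioner_1": e.conditioning_pair[0],
                    "conditioner_2": e.conditioning_pair[1],
                }
                for e in self.edges
            ],
            columns=[
                "gene_a",
                "gene_b",
                "r_zero",
                "r_direct",
                "r_indirect",
                "p_value",
                "conditioner_1",
                "conditioner_2",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        n_samples: int,
        alpha: float,
        conditioning_strategy: str = "unknown",
        filter_on: str = "direct",
    ) -> "CoexpressionNetwork":
        edges = [
            CoexpressionEdge(
                gene_a=str(r.gene_a),
                gene_b=str(r.gene_b),
                r_zero=float(r.r_zero),
                r_direct=float(r.r_direct),
                r_indirect=float(r.r_indirect),
                p_value=float(r.p_value),
                conditioning_pair=(str(r.conditioner_1), str(r.conditioner_2)),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(
            edges=edges,
            n_samples=n_samples,
            alpha=alpha,
            conditioning_strategy=conditioning_strategy,
            filter_on=filter_on,
        )

    @classmethod
    def from_tsv(cls, path, n_samples: int, alpha: float, **kwargs) -> "CoexpressionNetwork":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls.from_frame(frame, n_samples, alpha, **kwargs)

    def to_sif(self, path, relation: str = "coexp") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.edges:
                fh.write(f"{e.gene_a}\t{relation}\t{e.gene_b}\n")


def _second_order_grid(R: np.ndarray, i: int, j: int, cond: np.ndarray) -> np.ndarray:
    """r_ij.kl for every ordered conditioning pair (k, l) drawn from ``cond``.

    Returns an (m, m) matrix over conditioner positions; invalid (degenerate
    or diagonal) entries are NaN. Conditioning via the recursion applied first
    on k then on l.
    """
    r_ij = R[i, j]
    r_ik = R[i, cond]
    r_jk = R[j, cond]
    Rcc = R[np.ix_(cond, cond)]
    with np.errstate(divide="ignore", invalid="ignore"):
        den1 = (1.0 - r_ik**2) * (1.0 - r_jk**2)
        r_ij_k = np.where(den1 > _EPS, (r_ij - r_ik * r_jk) / np.sqrt(den1), np.nan)
        r_ij_k = np.clip(r_ij_k, -1.0, 1.0)

        # A[k, l] = r_il.k ; B[k, l] = r_jl.k
        den_a = (1.0 - r_ik[:, None] ** 2) * (1.0 - Rcc**2)
        A = np.where(den_a > _EPS, (r_ik[None, :] - r_ik[:, None] * Rcc) / np.sqrt(den_a), np.nan)
        den_b = (1.0 - r_jk[:, None] ** 2) * (1.0 - Rcc**2)
        B = np.where(den_b > _EPS, (r_jk[None, :] - r_jk[:, None] * Rcc) / np.sqrt(den_b), np.nan)
        A = np.clip(A, -1.0, 1.0)
        B = np.clip(B, -1.0, 1.0)

        den2 = (1.0 - A**2) * (1.0 - B**2)
        S = np.where(den2 > _EPS, (r_ij_k[:, None] - A * B) / np.sqrt(den2), np.nan)
        S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, np.nan)
    return S


def _exact_split(r_zero: float, r_direct: float) -> tuple[float, float]:
    """(r_direct', r_indirect) with r_direct' + r_indirect == r_zero exactly.

    The naive difference can be an ulp off; a compensated correction on the
    indirect part repairs it, and in the rare round-to-even tie where no
    neighbor works, r_direct itself is nudged by one ulp (far below any
    statistical noise in the estimate).
    """
    a = r_direct
    for _ in range(4):
        b = r_zero - a
        for _ in range(3):
            err = (a + b) - r_zero
            if err == 0.0:
                return a, b
            b -= err
        a = math.nextafter(a, r_zero)
    return a, r_zero - a


def build_coexpression_network(
    matrix,
    alpha: float = 0.05,
    strategy: str = "exhaustive",
    n_condition_samples: int = 100,
    filter_on: str = "direct",
    seed: int | None = None,
) -> CoexpressionNetwork:
    """Build the significant co-expression network with direct/indirect parts.

    For each unordered gene pair (x, y) a conditioning pair (z, q) is chosen
    among the remaining genes and the direct correlation set to r_xy.zq:

    - ``strategy="exhaustive"``: evaluate every (z, q) pair and keep the value
      of minimum absolute magnitude (the most conservative direct estimate);
      float ties resolve to the lexicographically smallest (z, q).
    - ``strategy="sampled"``: evaluate ``n_condition_samples`` seeded random
      (z, q) pairs instead (for large gene sets).

    The significance filter (p < ``alpha``) is applied to the direct
    correlation by default (``filter_on="direct"``, order-2 test) or to the
    zeroth-order correlation (``filter_on="zero"``, order-0 test). Pairs whose
    every conditioning pair is degenerate are skipped and recorded.
    """
    from .expression import ExpressionMatrix  # local to avoid cycle at import

    if not isinstance(matrix, ExpressionMatrix):
        raise TypeError("matrix must be an ExpressionMatrix")
    if strategy not in ("exhaustive", "sampled"):
        raise ValueError("strategy must be 'exhaustive' or 'sampled'")
    if filter_on not in ("direct", "zero"):
        raise ValueError("filter_on must be 'direct' or 'zero'")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n_genes, n_samples = matrix.values.shape
    if n_genes < 5:
        raise ValueError("need at least 5 genes (a pair, two conditioners, one spare)")
    if n_samples < 5:
        raise ValueError("need at least 5 samples (df = n - 4 >= 1)")

    variances = matrix.values.var(axis=1, ddof=1)
    flat = np.flatnonzero(variances <= 0)
    if flat.size:
        names = ", ".join(matrix.gene_ids[i] for i in flat)
        raise ValueError(f"zero-variance gene(s): {names}")

    # gene order fixed to lexicographic id order so conditioning tie-breaks
    # and edge enumeration are deterministic regardless of input row order
    order = np.argsort(np.asarray(matrix.gene_ids, dtype=object))
    ids = [matrix.gene_ids[k] for k in order]
    R = np.corrcoef(matrix.values[order])
    np.fill_diagonal(R, 1.0)

    rng = np.random.default_rng(seed)
    test_order = 2 if filter_on == "direct" else 0
    edges: list[CoexpressionEdge] = []
    skipped: list[tuple[str, str]] = []
    all_idx = np.arange(len(ids))

    for i, j in itertools.combinations(range(len(ids)), 2):
        cond = all_idx[(all_idx != i) & (all_idx != j)]
        if cond.size < 2:
            raise ValueError("fewer than 2 candidate conditioners")
        S = _second_order_grid(R, i, j, cond)
        iu, ju = np.triu_indices(cond.size, k=1)
        vals = S[iu, ju]
        if strategy == "sampled":
            n_pairs = vals.size
            take = min(n_condition_samples, n_pairs)
            pick = rng.choice(n_pairs, size=take, replace=False)
            pick.sort()  # keep lexicographic order within the sample
            iu, ju, vals = iu[pick], ju[pick], vals[pick]
        valid = np.isfinite(vals)
        if not valid.any():
            skipped.append((ids[i], ids[j]))
            continue
        absvals = np.where(valid, np.abs(vals), np.inf)
        best = int(np.argmin(absvals))  # first occurrence = lexicographic (z, q)
        r_direct = float(vals[best])
        z, q = ids[cond[iu[best]]], ids[cond[ju[best]]]
        r_zero = float(R[i, j])
        r_test = r_direct if filter_on == "direct" else r_zero
        p = partial_pvalue(r_test, n_samples, test_order)
        if p < alpha:
            r_direct, r_indirect = _exact_split(r_zero, r_direct)
            edges.append(
                CoexpressionEdge(
                    gene_a=ids[i],
                    gene_b=ids[j],
                    r_zero=r_zero,
                    r_direct=r_direct,
                    r_indirect=r_indirect,
                    p_value=p,
                    conditioning_pair=(z, q),
                )
            )

    return CoexpressionNetwork(
        edges=edges,
        n_samples=n_samples,
        alpha=alpha,
        conditioning_strategy=strategy,
        filter_on=filter_on,
        skipped_pairs=skipped,
    )
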