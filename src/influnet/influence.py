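"""Orientation of correlation components and the influence network.

Step 2 of the pipeline. Each significant edge's direct and indirect
correlations become directed *investments*, oriented by the slope-ratio
criterion

    SR = min(|b_yx|, |b_xy|) / max(|b_yx|, |b_xy|),

where b_yx = cov(x, y)/var(x) and b_xy = cov(x, y)/var(y) are the two
least-squares slopes. Because the slopes share a numerator, the direction
whose slope has the larger magnitude starts at the smaller-variance gene, so
the direct correlation is always committed as the investment from the
smaller-variance gene to the larger-variance gene and the indirect
correlation flows the opposite way.

Investments are then normalized into influences:

    Influence(A, B) = Invests(B, A) / sum_X Invests(B, X)

i.e. the fraction of investor B's total outgoing investments committed to A
(the "forward influence" along A -> B). Positive and negative investments are
normalized within their own sign class: a positive numerator is divided by
the investor's total positive investments and a negative numerator by its
total negative investments, so conferred influences sum to one per investor
and sign class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .partialcorr import CoexpressionEdge, CoexpressionNetwork

__all__ = [
    "SlopePair",
    "DirectedInvestment",
    "OrientedEdge",
    "InfluenceNetwork",
    "regression_slopes",
    "orient_investments",
    "compute_influence_network",
    "build_influence_network",
]


class SlopePair(NamedTuple):
    """The two least-squares slopes of a gene pair and their slope ratio."""

    b_yx: float  # slope of y regressed on x: cov / var(x)
    b_xy: float  # slope of x regressed on y: cov / var(y)
    sr: float  # min(|b_yx|, |b_xy|) / max(|b_yx|, |b_xy|), in (0, 1]


@dataclass(frozen=True)
class DirectedInvestment:
    """A signed weight one gene commits toward another.

    ``kind`` records which correlation component was committed: the edge's
    direct (second-order partial) correlation travels from the
    smaller-variance gene to the larger-variance one, the indirect component
    the other way.
    """

    investor: str
    target: str
    weight: float
    kind: str  # "direct" | "indirect"


class OrientedEdge(NamedTuple):
    direct: DirectedInvestment
    indirect: DirectedInvestment
    sr: float
    tied: bool


def regression_slopes(x, y) -> SlopePair:
    """Both least-squares slopes of a pair of expression vectors, plus SR.

    Raises on zero variance (slope undefined); a zero covariance makes the
    orientation undefined and is also raised — callers flag and skip the edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    var_x = float(xc @ xc)
    var_y = float(yc @ yc)
    if var_x <= 0 or var_y <= 0:
        raise ValueError("zero variance; regression slope undefined")
    cov = float(xc @ yc)
    if cov == 0:
        raise ValueError("zero covariance; orientation undefined")
    b_yx = cov / var_x
    b_xy = cov / var_y
    hi, lo = max(abs(b_yx), abs(b_xy)), min(abs(b_yx), abs(b_xy))
    return SlopePair(b_yx=b_yx, b_xy=b_xy, sr=lo / hi)


def orient_investments(edge: CoexpressionEdge, slopes: SlopePair) -> OrientedEdge:
    """Commit an edge's direct/indirect correlations as directed investments.

    ``slopes`` must come from ``regression_slopes(x_a, x_b)`` with x_a the
    expression vector of ``edge.gene_a``. |b_yx| > |b_xy| iff
    var(a) < var(b), in which case the direct correlation is invested a -> b.
    An exact slope tie (equal variances, SR = 1) is broken toward the
    lexicographically smaller gene and flagged ``tied`` so consumers can drop
    the edge.
    """
    a, b = edge.gene_a, edge.gene_b
    tied = abs(slopes.b_yx) == abs(slopes.b_xy)
    if tied or abs(slopes.b_yx) > abs(slopes.b_xy):
        src, dst = a, b  # a has the smaller (or tied) variance
    else:
        src, dst = b, a
    direct = DirectedInvestment(investor=src, target=dst, weight=edge.r_direct, kind="direct")
    indirect = DirectedInvestment(investor=dst, target=src, weight=edge.r_indirect, kind="indirect")
    return OrientedEdge(direct=direct, indirect=indirect, sr=slopes.sr, tied=tied)


@dataclass
class InfluenceNetwork:
    """Weighted bidirectional influence graph over the co-expression pairs.

    ``influences`` maps an ordered pair (a, b) to the forward influence
    Influence(a, b) = Invests(b, a) / total investments of b (within the
    numerator's sign class). ``annotations`` carries per-unordered-pair SR and
    tie flags when built from expression data.
    """

    influences: dict[tuple[str, str], float]
    sign_class: dict[tuple[str, str], str]
    annotations: dict[tuple[str, str], dict] = field(default_factory=dict)
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered pairs with both orientations defined, sorted."""
        seen = set()
        out = []
        for a, b in self.influences:
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            if (key[0], key[1]) in self.influences and (key[1], key[0]) in self.influences:
                out.append(key)
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), val in sorted(self.influences.items()):
            key = (min(a, b), max(a, b))
            ann = self.annotations.get(key, {})
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "influence": val,
                    "sign_class": self.sign_class[(a, b)],
                    "sr": ann.get("sr", float("nan")),
                    "tied": ann.get("tied", False),
                }
            )
        return pd.DataFrame(
            rows, columns=["source", "target", "influence", "sign_class", "sr", "tied"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InfluenceNetwork":
        influences: dict[tuple[str, str], float] = {}
        sign_class: dict[tuple[str, str], str] = {}
        annotations: dict[tuple[str, str], dict] = {}
        for r in frame.itertuples(index=False):
            pair = (str(r.source), str(r.target))
            influences[pair] = float(r.influence)
            sign_class[pair] = str(r.sign_class)
            key = (min(pair), max(pair))
            sr = float(r.sr)
            if np.isfinite(sr):
                annotations[key] = {"sr": sr, "tied": bool(r.tied)}
        return cls(influences=influences, sign_class=sign_class, annotations=annotations)

    @classmethod
    def from_tsv(cls, path) -> "InfluenceNetwork":
        return cls.from_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for (a, b), val in self.influences.items():
            g.add_edge(a, b, weight=float(val), sign_class=self.sign_class[(a, b)])
        nx.write_graphml(g, path)


def compute_influence_network(
    investments: list[DirectedInvestment], sign_split: bool = True
) -> InfluenceNetwork:
    """Normalize directed investments into the bidirectional influence network.

    With ``sign_split`` on (default) each investment is divided by the
    investor's total investments *of the same sign*; off pools all of an
    investor's investments by absolute value (sensitivity-analysis mode).
    A zero-weight investment confers zero influence. An influence whose
    sign-class total is zero while its numerator is not is recorded as
    undefined and excluded (cannot occur under sign_split, where the
    numerator contributes to its own class total).
    """
    totals: dict[tuple[str, str], float] = {}
    for inv in investments:
        if sign_split:
            cls = "positive" if inv.weight > 0 else "negative" if inv.weight < 0 else "zero"
            key = (inv.investor, cls)
            totals[key] = totals.get(key, 0.0) + inv.weight
        else:
            key = (inv.investor, "pooled")
            totals[key] = totals.get(key, 0.0) + abs(inv.weight)

    influences: dict[tuple[str, str], float] = {}
    sign_class: dict[tuple[str, str], str] = {}
    undefined: list[tuple[str, str]] = []
    for inv in investments:
        # Invests(B, A) becomes Influence(A, B): pair keyed (target, investor)
        pair = (inv.target, inv.investor)
        if inv.weight == 0.0:
            influences[pair] = 0.0
            sign_class[pair] = "zero"
            continue
        cls = "positive" if inv.weight > 0 else "negative"
        total = totals[(inv.investor, cls)] if sign_split else totals[(inv.investor, "pooled")]
        if total == 0.0:
            undefined.append(pair)
            continue
        influences[pair] = inv.weight / total
        sign_class[pair] = cls
    return InfluenceNetwork(
        influences=influences, sign_class=sign_class, undefined=undefined
    )


def build_influence_network(
    matrix,
    network: CoexpressionNetwork,
    sign_split: bool = True,
    sr_max: float | None = None,
) -> InfluenceNetwork:
    """Orient every co-expression edge and normalize into influences.

    ``sr_max``, if given, drops edges whose slope ratio exceeds it before
    investment assignment (an optional confidence filter; by default every
    significant edge is oriented). Edges with zero covariance are skipped and
    recorded as undefined.
    """
    from .expression import ExpressionMatrix

    if not isinstance(matrix, ExpressionMatrix):
        raise TypeError("matrix must be an ExpressionMatrix")
    rows = {g: matrix.values[i] for i, g in enumerate(matrix.gene_ids)}
    investments: list[DirectedInvestment] = []
    annotations: dict[tuple[str, str], dict] = {}
    undefined: list[tuple[str, str]] = []
    for edge in network.edges:
        try:
            slopes = regression_slopes(rows[edge.gene_a], rows[edge.gene_b])
        except ValueError:
            undefined.append(edge.pair)
            continue
        if sr_max is not None and slopes.sr > sr_max:
            continue
        oriented = orient_investments(edge, slopes)
        investments.extend([oriented.direct, oriented.indirect])
        annotations[edge.pair] = {"sr": oriented.sr, "tied": oriented.tied}
    net = compute_influence_network(investments, sign_split=sign_split)
    net.annotations = annotations
    net.undefined.extend(undefined)
    return net
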