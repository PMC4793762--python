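"""Scoring predicted directions against a directed gold standard.

A prediction is *evaluated* only if its unordered gene pair appears in the
gold standard; it is *correct* if the predicted ordered pair is listed. A
pair regulated in both directions (mutual) is therefore correct whichever way
it is predicted — which is also why the random-assignment null scores above
50% whenever mutual pairs are present. The null is an empirical population of
random directionality assignments (one fair coin per pair), scored exactly
like the method, yielding a z-score and an empirical p for the method's
percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causality import CausalPrediction

__all__ = [
    "GoldStandardEdge",
    "EvaluationResult",
    "load_gold_standard",
    "score_directionality",
    "random_null_comparison",
    "evaluate_predictions",
]

_VALID_SIGNS = {"activation", "inhibition", "unknown"}


@dataclass(frozen=True)
class GoldStandardEdge:
    """A directed, signed literature (or simulated ground-truth) interaction."""

    source: str
    target: str
    sign: str = "unknown"
    reference: str = ""

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop {self.source}->{self.target} not allowed")
        if self.sign not in _VALID_SIGNS:
            raise ValueError(
                f"unknown sign {self.sign!r} (expected one of {sorted(_VALID_SIGNS)})"
            )


@dataclass
class EvaluationResult:
    """Directionality scoring plus (optionally) the random-null comparison.

    ``percent_correct`` is 100 * n_correct / n_evaluated (NaN when nothing is
    evaluable). Null fields are filled by :func:`random_null_comparison`.
    """

    n_predicted: int
    n_evaluated: int
    n_correct: int
    n_incorrect: int
    percent_correct: float
    null_mean: float | None = None
    null_sd: float | None = None
    null_scores: np.ndarray | None = None
    z_score: float | None = None
    empirical_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self, include_null_scores: bool = False) -> dict:
        out = {
            "n_predicted": self.n_predicted,
            "n_evaluated": self.n_evaluated,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "percent_correct": self.percent_correct,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_score": self.z_score,
            "empirical_p": self.empirical_p,
        }
        if include_null_scores and self.null_scores is not None:
            out["null_scores"] = [float(s) for s in self.null_scores]
        return out


def load_gold_standard(path) -> list[GoldStandardEdge]:
    """Read a gold-standard TSV (header: source, target, sign, reference).

    Duplicate (source, target, sign) rows are collapsed with a warning; both
    orders of the same pair may appear (mutual regulation). Self-loops and
    unknown sign tokens are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["source", "target", "sign", "reference"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"gold standard must have header columns {required}")
    before = len(df)
    df = df.drop_duplicates(subset=["source", "target", "sign"])
    if len(df) < before:
        warnings.warn(f"dropped {before - len(df)} duplicate gold-standard row(s)")
    return [
        GoldStandardEdge(r.source, r.target, r.sign, r.reference)
        for r in df.itertuples(index=False)
    ]


def write_gold_standard(edges: list[GoldStandardEdge], path) -> None:
    pd.DataFrame(
        [(e.source, e.target, e.sign, e.reference) for e in edges],
        columns=["source", "target", "sign", "reference"],
    ).to_csv(path, sep="\t", index=False)


def _ordered_pairs(gold: list[GoldStandardEdge]) -> set[tuple[str, str]]:
    return {(e.source, e.target) for e in gold}


def score_directionality(
    predictions: list[CausalPrediction], gold: list[GoldStandardEdge]
) -> EvaluationResult:
    """Score retained predictions against the gold standard (no null fields).

    Only predictions whose unordered pair is in the gold standard count as
    evaluated; a prediction is correct when its ordered pair is listed, so
    mutual pairs are correct in either direction.
    """
    ordered = _ordered_pairs(gold)
    unordered = {frozenset(p) for p in ordered}
    retained = [p for p in predictions if p.retained]
    n_correct = n_incorrect = 0
    for p in retained:
        if frozenset((p.source, p.target)) not in unordered:
            continue
        if (p.source, p.target) in ordered:
            n_correct += 1
        else:
            n_incorrect += 1
    n_eval = n_correct + n_incorrect
    percent = 100.0 * n_correct / n_eval if n_eval else float("nan")
    return EvaluationResult(
        n_predicted=len(retained),
        n_evaluated=n_eval,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        percent_correct=percent,
    )


def random_null_comparison(
    evaluable_pairs,
    gold: list[GoldStandardEdge],
    n_draws: int = 10_000,
    seed: int | None = None,
    method_percent: float | None = None,
) -> EvaluationResult:
    """Score a population of random directionality assignments.

    Each draw assigns every evaluable pair a direction with probability 0.5
    each way and is scored exactly as :func:`score_directionality`: a mutual
    gold pair is correct either way, a single-direction pair with probability
    one half. Returns the score distribution with its mean/sd and, when
    ``method_percent`` is given, the method's z-score on the percentage scale
    and the empirical p-value (fraction of draws >= method score, with the
    (k+1)/(n+1) correction so p is never zero).
    """
    pairs = sorted({(min(a, b), max(a, b)) for a, b in evaluable_pairs})
    if not pairs:
        raise ValueError("evaluable_pairs must be nonempty")
    ordered = _ordered_pairs(gold)
    unordered = {frozenset(p) for p in ordered}
    pairs = [p for p in pairs if frozenset(p) in unordered]
    if not pairs:
        raise ValueError("no evaluable pair appears in the gold standard")

    mutual = sum(1 for a, b in pairs if (a, b) in ordered and (b, a) in ordered)
    n_single = len(pairs) - mutual
    rng = np.random.default_rng(seed)
    # one fair coin per single-direction pair per draw; mutual pairs are
    # correct under either outcome so their coins never change the score
    coins = rng.random((n_draws, n_single)) < 0.5 if n_single else np.zeros((n_draws, 0), bool)
    correct = mutual + coins.sum(axis=1)
    scores = 100.0 * correct / len(pairs)
    null_mean = float(scores.mean())
    null_sd = float(scores.std(ddof=1)) if n_draws > 1 else 0.0

    z = emp_p = None
    if method_percent is not None and np.isfinite(method_percent):
        if null_sd > 0:
            z = (method_percent - null_mean) / null_sd
        k = int((scores >= method_percent).sum())
        emp_p = (k + 1) / (n_draws + 1)
    return EvaluationResult(
        n_predicted=0,
        n_evaluated=len(pairs),
        n_correct=0,
        n_incorrect=0,
        percent_correct=float("nan") if method_percent is None else method_percent,
        null_mean=null_mean,
        null_sd=null_sd,
        null_scores=scores,
        z_score=z,
        empirical_p=emp_p,
    )


def evaluate_predictions(
    predictions: list[CausalPrediction],
    gold: list[GoldStandardEdge],
    n_draws: int = 10_000,
    seed: int | None = None,
) -> EvaluationResult:
    """Full evaluation: score the method, then compare to the random null."""
    result = score_directionality(predictions, gold)
    if result.n_evaluated == 0:
        result.notes.append("no evaluable predictions; null comparison skipped")
        return result
    unordered = {frozenset(p) for p in _ordered_pairs(gold)}
    evaluable = [
        (p.source, p.target)
        for p in predictions
        if p.retained and frozenset((p.source, p.target)) in unordered
    ]
    null = random_null_comparison(
        evaluable, gold, n_draws=n_draws, seed=seed, method_percent=result.percent_correct
    )
    result.null_mean = null.null_mean
    result.null_sd = null.null_sd
    result.null_scores = null.null_scores
    result.z_score = null.z_score
    result.empirical_p = null.empirical_p
    return result
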