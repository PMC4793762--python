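"""Scikit-learn style estimators wrapping the inference pipeline.

Two estimators, in the spirit of ``sklearn.covariance.GraphicalLasso``
(structure learned from a samples x features matrix, exposed as fitted
attributes):

- :class:`PartialCorrelationNetwork` — step 1 only: the significant
  co-expression network with its direct/indirect decomposition.
- :class:`InfluenceCausality` — the full pipeline: co-expression network,
  influence network, and directed causal predictions.

``X`` may be an :class:`~influnet.expression.ExpressionMatrix` (genes x
samples with identifiers), a pandas DataFrame (samples as rows, genes as
columns, sklearn orientation), or a plain 2-D array (samples x genes,
genes auto-named). Both estimators are clonable, support
``get_params``/``set_params`` and compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .causality import predict_directions, predictions_to_frame
from .evaluation import evaluate_predictions
from .expression import ExpressionMatrix
from .influence import build_influence_network
from .partialcorr import build_coexpression_network

__all__ = ["PartialCorrelationNetwork", "InfluenceCausality", "as_expression_matrix"]


def as_expression_matrix(X) -> ExpressionMatrix:
    """Coerce estimator input to a genes x samples ExpressionMatrix.

    DataFrames and arrays follow the sklearn samples-as-rows convention and
    are transposed; arrays get generated gene names ``G001``... Values must
    be finite and non-negative.
    """
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix.from_frame(X.T)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_genes)")
    n_genes = arr.shape[1]
    width = max(3, len(str(n_genes)))
    names = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, arr.shape[0] + 1)]
    return ExpressionMatrix(gene_ids=names, sample_ids=samples, values=arr.T)


class PartialCorrelationNetwork(BaseEstimator):
    """Significant co-expression network with direct/indirect correlations.

    Parameters
    ----------
    alpha : float, default=0.05
        Significance threshold on the filtered correlation's p-value.
    strategy : {"exhaustive", "sampled"}, default="exhaustive"
        How the second-order conditioning pair is chosen per gene pair
        (exhaustive minimum-magnitude search, or a seeded random subsample).
    n_condition_samples : int, default=100
        Conditioning pairs evaluated per gene pair under ``strategy="sampled"``.
    filter_on : {"direct", "zero"}, default="direct"
        Which correlation the significance filter tests.
    random_state : int or None
        Seed for the sampled strategy.

    Attributes
    ----------
    network_ : CoexpressionNetwork
    edges_ : pandas.DataFrame
        One row per significant pair with r_zero, r_direct, r_indirect,
        p_value and the conditioning genes.
    gene_ids_ : list of str
    n_samples_ : int
    """

    def __init__(
        self,
        alpha: float = 0.05,
        strategy: str = "exhaustive",
        n_condition_samples: int = 100,
        filter_on: str = "direct",
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.strategy = strategy
        self.n_condition_samples = n_condition_samples
        self.filter_on = filter_on
        self.random_state = random_state

    def fit(self, X, y=None):
        matrix = as_expression_matrix(X)
        self.network_ = build_coexpression_network(
            matrix,
            alpha=self.alpha,
            strategy=self.strategy,
            n_condition_samples=self.n_condition_samples,
            filter_on=self.filter_on,
            seed=self.random_state,
        )
        self.edges_ = self.network_.to_frame()
        self.gene_ids_ = sorted(matrix.gene_ids)
        self.n_samples_ = matrix.n_samples
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the fitted edge table (the learned structure)."""
        check_is_fitted(self, "network_")
        return self.edges_.copy()


class InfluenceCausality(BaseEstimator):
    """End-to-end directionality inference for co-expression networks.

    Fits the three pipeline stages on an expression matrix: (1) significant
    pairs with direct (second-order partial) and indirect correlation
    components, (2) slope-ratio-oriented investments normalized into the
    bidirectional influence network, (3) directed predictions opposite to the
    main flux of influence, with the weakest quantile discarded.

    Parameters mirror the stage functions; see their docstrings. ``sr_max``
    optionally drops near-symmetric edges (slope ratio above the cutoff)
    before orientation; ``discard_fraction`` (default 0.25) sets the
    weakest-quantile discard; ``sign_split`` normalizes positive and negative
    investments separately (default, matching the influence definition).

    Attributes
    ----------
    coexpression_ : CoexpressionNetwork
    influence_ : InfluenceNetwork
    predictions_ : list of CausalPrediction
    predictions_frame_ : pandas.DataFrame
    """

    def __init__(
        self,
        alpha: float = 0.05,
        strategy: str = "exhaustive",
        n_condition_samples: int = 100,
        filter_on: str = "direct",
        sign_split: bool = True,
        sr_max: float | None = None,
        discard_fraction: float = 0.25,
        quantile_population: str = "winning",
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.strategy = strategy
        self.n_condition_samples = n_condition_samples
        self.filter_on = filter_on
        self.sign_split = sign_split
        self.sr_max = sr_max
        self.discard_fraction = discard_fraction
        self.quantile_population = quantile_population
        self.random_state = random_state

    def fit(self, X, y=None):
        matrix = as_expression_matrix(X)
        self.coexpression_ = build_coexpression_network(
            matrix,
            alpha=self.alpha,
            strategy=self.strategy,
            n_condition_samples=self.n_condition_samples,
            filter_on=self.filter_on,
            seed=self.random_state,
        )
        self.influence_ = build_influence_network(
            matrix,
            self.coexpression_,
            sign_split=self.sign_split,
            sr_max=self.sr_max,
        )
        if self.influence_.pairs():
            self.predictions_ = predict_directions(
                self.influence_,
                discard_fraction=self.discard_fraction,
                quantile_population=self.quantile_population,
            )
        else:
            self.predictions_ = []
        self.predictions_frame_ = predictions_to_frame(self.predictions_)
        self.gene_ids_ = sorted(matrix.gene_ids)
        self.n_samples_ = matrix.n_samples
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Retained directed predictions as a (source, target, ...) table.

        ``X`` is accepted for pipeline compatibility: if given and the
        estimator is unfitted, it is fitted first.
        """
        if not hasattr(self, "predictions_"):
            if X is None:
                check_is_fitted(self, "predictions_")
            self.fit(X)
        frame = self.predictions_frame_
        return frame[frame["retained"]].reset_index(drop=True)

    def evaluate(self, gold, n_draws: int = 10_000, seed: int | None = None):
        """Score fitted predictions against a gold standard with the random null."""
        check_is_fitted(self, "predictions_")
        return evaluate_predictions(self.predictions_, gold, n_draws=n_draws, seed=seed)
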