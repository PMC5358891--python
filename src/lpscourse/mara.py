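"""Motif activity response analysis (MARA).

Expression across samples is modelled as a linear combination of
promoter motif counts with sample-dependent motif activities:

    E'_{fs} = sum_m N_{fm} A_{ms} + noise

where E' is log2(TPM+1) after double centering (row and column means
removed) and N is the feature x motif count matrix, standardized per motif
so that activities are comparable across motifs of different site
frequency. Activities are estimated by ridge regression,

    A = (N^T N + lambda I)^{-1} N^T E',

with per-motif standard errors from the sandwich of the ridge projector and
the residual variance, activities re-centred to sum to zero across samples
per motif, and Z = A / dA. The ridge penalty defaults to 5-fold
cross-validation over a log grid scaled by mean(diag N^T N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable
from .errors import AnalysisError, SchemaError

log = logging.getLogger(__name__)


def read_motif_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature x motif count matrix: non-negative, no all-zero
    motif column."""
    values = frame.to_numpy()
    if (values < 0).any() or not np.isfinite(values).all():
        raise SchemaError("motif counts must be non-negative and finite")
    zero_cols = frame.columns[values.sum(axis=0) == 0].tolist()
    if zero_cols:
        raise SchemaError(f"all-zero motif column(s): {zero_cols[:5]}")
    return frame


def center_expression(table: ExpressionTable) -> pd.DataFrame:
    """log2(TPM + 1), then remove each feature's row mean and each sample's
    column mean (double centering); the grand mean of the result is 0."""
    x = np.log2(table.data.to_numpy() + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    x = x - x.mean(axis=0, keepdims=True)
    return pd.DataFrame(x, index=table.data.index, columns=table.data.columns)


@dataclass
class MaraFit:
    """Fitted motif activities with errors and Z-scores (motif x sample)."""

    activities: pd.DataFrame
    activity_errors: pd.DataFrame
    zscores: pd.DataFrame
    ridge_lambda: float
    residual_variance: float


class MotifActivityModel:
    """Ridge decomposition of centred expression into motif activities.

    Parameters
    ----------
    ridge_lambda : float or None
        Penalty on the standardized motif-count scale. ``None`` (default)
        selects it by ``cv``-fold cross-validation over
        ``lambda_grid * mean(diag N^T N)``.
    standardize : bool, default True
        Centre and unit-variance scale motif columns before fitting.
    cv : int, default 5
    lambda_grid : sequence, default logspace(-3, 3, 7)

    Attributes
    ----------
    activities_, activity_errors_, zscores_ : DataFrame (motif x sample)
    ridge_lambda_ : float  (the value actually used)
    residual_variance_ : float
    """

    def __init__(
        self,
        ridge_lambda: float | None = None,
        standardize: bool = True,
        cv: int = 5,
        lambda_grid=None,
        random_state: int = 0,
    ):
        self.ridge_lambda = ridge_lambda
        self.standardize = standardize
        self.cv = cv
        self.lambda_grid = lambda_grid
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "ridge_lambda": self.ridge_lambda,
            "standardize": self.standardize,
            "cv": self.cv,
            "lambda_grid": self.lambda_grid,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "MotifActivityModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _solve(n: np.ndarray, e: np.ndarray, lam: float) -> np.ndarray:
        gram = n.T @ n + lam * np.eye(n.shape[1])
        try:
            return np.linalg.solve(gram, n.T @ e)
        except np.linalg.LinAlgError as exc:
            raise AnalysisError(
                "singular motif design (collinear motifs); refit with a "
                "ridge penalty lambda > 0"
            ) from exc

    def _cv_lambda(self, n: np.ndarray, e: np.ndarray) -> float:
        grid = (
            np.asarray(self.lambda_grid, dtype=float)
            if self.lambda_grid is not None
            else np.logspace(-3, 3, 7)
        )
        scale = float(np.mean(np.diag(n.T @ n)))
        candidates = grid * scale
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(n.shape[0])
        folds = np.array_split(order, self.cv)
        errors = np.zeros(len(candidates))
        for test in folds:
            train = np.setdiff1d(order, test, assume_unique=False)
            for k, lam in enumerate(candidates):
                a = self._solve(n[train], e[train], lam)
                resid = e[test] - n[test] @ a
                errors[k] += float((resid ** 2).sum())
        best = int(np.argmin(errors))
        return float(candidates[best])

    def fit(self, motif_counts: pd.DataFrame, expression) -> "MotifActivityModel":
        """Fit activities from a feature x motif count matrix and centred
        expression (a DataFrame from :func:`center_expression`, or an
        ExpressionTable that will be centred first)."""
        if isinstance(expression, ExpressionTable):
            expression = center_expression(expression)
        if not motif_counts.index.equals(expression.index):
            common = motif_counts.index.intersection(expression.index)
            if len(common) == 0:
                raise SchemaError("motif matrix and expression share no features")
            log.info("aligning on %d shared features", len(common))
            motif_counts = motif_counts.loc[common]
            expression = expression.loc[common]
        read_motif_matrix(motif_counts)

        n = motif_counts.to_numpy(dtype=float)
        if self.standardize:
            sd = n.std(axis=0)
            sd[sd == 0] = 1.0
            n = (n - n.mean(axis=0)) / sd
        e = expression.to_numpy(dtype=float)
        n_features, n_motifs = n.shape
        n_samples = e.shape[1]

        lam = (
            float(self.ridge_lambda)
            if self.ridge_lambda is not None
            else self._cv_lambda(n, e)
        )
        if lam < 0:
            raise AnalysisError("ridge_lambda must be >= 0")
        if lam == 0:
            cond = np.linalg.cond(n.T @ n)
            if not np.isfinite(cond) or cond > 1e12:
                raise AnalysisError(
                    "motif design is singular at lambda=0 (collinear motifs); "
                    "use a ridge penalty lambda > 0"
                )
        a = self._solve(n, e, lam)

        resid = e - n @ a
        dof = max((n_features - n_motifs) * n_samples, 1)
        sigma2 = float((resid ** 2).sum()) / dof
        gram = n.T @ n
        inv = np.linalg.inv(gram + lam * np.eye(n_motifs))
        var_a = sigma2 * np.diag(inv @ gram @ inv)
        errors = np.sqrt(np.maximum(var_a, 1e-300))[:, None] * np.ones(
            (1, n_samples)
        )

        a = a - a.mean(axis=1, keepdims=True)  # zero-sum across samples
        motifs = motif_counts.columns
        samples = expression.columns
        self.activities_ = pd.DataFrame(a, index=motifs, columns=samples)
        self.activity_errors_ = pd.DataFrame(errors, index=motifs, columns=samples)
        self.zscores_ = self.activities_ / self.activity_errors_
        self.ridge_lambda_ = lam
        self.residual_variance_ = sigma2
        self.feature_ids_ = motif_counts.index.tolist()
        return self

    def predict(self, motif_counts: pd.DataFrame) -> pd.DataFrame:
        """Model-predicted centred expression for the given motif counts."""
        n = motif_counts.to_numpy(dtype=float)
        if self.standardize:
            sd = n.std(axis=0)
            sd[sd == 0] = 1.0
            n = (n - n.mean(axis=0)) / sd
        return pd.DataFrame(
            n @ self.activities_.to_numpy(),
            index=motif_counts.index,
            columns=self.activities_.columns,
        )

    @property
    def fit_(self) -> MaraFit:
        return MaraFit(
            self.activities_,
            self.activity_errors_,
            self.zscores_,
            self.ridge_lambda_,
            self.residual_variance_,
        )


def fit_motif_activities(
    expression_centered, motif_counts: pd.DataFrame, ridge_lambda: float | None = None,
    **kwargs,
) -> MaraFit:
    """Functional wrapper around :class:`MotifActivityModel`."""
    model = MotifActivityModel(ridge_lambda=ridge_lambda, **kwargs)
    model.fit(motif_counts, expression_centered)
    return model.fit_


def motif_significance(fit: MaraFit) -> pd.DataFrame:
    """Per-motif activity summary: score = sqrt(mean over samples of Z^2),
    plus the SD of Z across samples, ranked by descending score."""
    z = fit.zscores
    score = np.sqrt((z ** 2).mean(axis=1))
    out = pd.DataFrame(
        {"score": score, "z_sd": z.std(axis=1, ddof=1)}
    ).sort_values("score", ascending=False)
    out.index.name = "motif_id"
    return out
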