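"""Denoising, replicate averaging, normalization and feature filtering.

The outlier smoother implements the replicate-pool rule used on dense CAGE
time courses: each value is compared with a pool built from its temporal
neighbours in the same donor plus the corresponding timepoints in the other
donors (8 values for an interior timepoint of a 3-donor design), and values
deviating more than k standard deviations from the pool mean are replaced by
that mean. All decisions are made on the original tensor and applied
simultaneously, so replacement never cascades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable, FilterReport, TimeCourseTensor
from .errors import NormalizationError, SchemaError

log = logging.getLogger(__name__)


def tpm_normalize(table: ExpressionTable) -> ExpressionTable:
    """Scale raw tag counts to tags-per-million per sample.

    Refuses already-normalized input (``unit == "tpm"``) to guard against
    double normalization, and refuses zero-sum library columns.
    """
    if table.unit == "tpm":
        raise NormalizationError("input is already TPM; refusing to renormalize")
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise NormalizationError(
            f"zero-sum library for sample(s): {zero.index.tolist()[:5]}"
        )
    return ExpressionTable(table.data * 1e6 / sums, unit="tpm")


class OutlierSmoother:
    """Replicate-pool outlier replacement on a time-course tensor.

    Parameters
    ----------
    k_sd : float, default 3
        Replace a value when it deviates more than ``k_sd`` pool standard
        deviations (ddof=1) from the pool mean. A zero-SD pool replaces any
        value differing from the pool mean at all (the limit of the rule).

    Attributes
    ----------
    outlier_mask_ : ndarray of bool, shape of the tensor
        Cells that were replaced in the last :meth:`transform` call.
    n_replaced_ : int
    n_skipped_ : int
        Cells whose pool had fewer than 3 members and were left untouched.
    """

    def __init__(self, k_sd: float = 3.0):
        self.k_sd = k_sd

    def get_params(self, deep: bool = True) -> dict:
        return {"k_sd": self.k_sd}

    def set_params(self, **params) -> "OutlierSmoother":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, tensor: TimeCourseTensor) -> "OutlierSmoother":
        return self

    def transform(self, tensor: TimeCourseTensor) -> TimeCourseTensor:
        x = tensor.values
        n_f, n_t, n_d = x.shape
        if n_d < 2 or n_t < 2:
            raise SchemaError("outlier replacement needs >=2 donors and >=2 timepoints")

        replaced = np.zeros_like(x, dtype=bool)
        means = np.zeros_like(x)
        skipped = 0
        for t in range(n_t):
            steps = [s for s in (t - 1, t + 1) if 0 <= s < n_t]
            for d in range(n_d):
                others = [od for od in range(n_d) if od != d]
                # pool: same donor at t-1/t+1, other donors at t-1, t, t+1
                members = [x[:, s, d] for s in steps]
                members += [x[:, s, od] for od in others for s in steps + [t]]
                pool = np.stack(members, axis=1)  # (n_f, pool_size)
                size = pool.shape[1]
                if size < 3:
                    skipped += n_f
                    continue
                mean = pool.mean(axis=1)
                sd = pool.std(axis=1, ddof=1)
                dev = np.abs(x[:, t, d] - mean)
                hit = dev > self.k_sd * sd
                replaced[:, t, d] = hit
                means[:, t, d] = mean
        if skipped:
            log.warning("outlier smoother skipped %d cells with pool < 3", skipped)

        out = x.copy()
        out[replaced] = means[replaced]
        self.outlier_mask_ = replaced
        self.n_replaced_ = int(replaced.sum())
        self.n_skipped_ = skipped
        return TimeCourseTensor(
            tensor.feature_ids, tensor.timepoints_minutes, tensor.donors, out
        )

    def fit_transform(self, tensor: TimeCourseTensor) -> TimeCourseTensor:
        return self.fit(tensor).transform(tensor)


def replace_outliers(
    tensor: TimeCourseTensor, k: float = 3.0
) -> tuple[TimeCourseTensor, np.ndarray]:
    """Functional wrapper around :class:`OutlierSmoother`."""
    smoother = OutlierSmoother(k_sd=k)
    smoothed = smoother.fit_transform(tensor)
    return smoothed, smoother.outlier_mask_


def average_donors(tensor: TimeCourseTensor) -> ExpressionTable:
    """Arithmetic mean over donors, yielding a feature x timepoint table
    whose columns are ``t<minutes>``."""
    mean = tensor.values.mean(axis=2)
    columns = [f"t{int(m)}" for m in tensor.timepoints_minutes]
    return ExpressionTable(
        pd.DataFrame(mean, index=tensor.feature_ids, columns=columns), unit="tpm"
    )


class ExpressionFilter:
    """Keep features with max expression >= ``min_tpm`` in at least one
    timepoint and coefficient of variation > ``min_cv``.

    CV is the sample (ddof=1) standard deviation over timepoints divided by
    the mean; all-zero features have undefined CV and are removed.

    Attributes
    ----------
    support_ : boolean Series over input features (True = retained)
    report_ : FilterReport
    """

    def __init__(self, min_tpm: float = 10.0, min_cv: float = 0.5):
        self.min_tpm = min_tpm
        self.min_cv = min_cv

    def get_params(self, deep: bool = True) -> dict:
        return {"min_tpm": self.min_tpm, "min_cv": self.min_cv}

    def set_params(self, **params) -> "ExpressionFilter":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, profiles: ExpressionTable) -> "ExpressionFilter":
        data = profiles.data
        peak = data.max(axis=1)
        mean = data.mean(axis=1)
        sd = data.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mean
        pass_tpm = peak >= self.min_tpm
        pass_cv = cv.fillna(-np.inf) > self.min_cv
        n_zero = int((mean == 0).sum())
        if n_zero:
            log.info("%d all-zero features removed (undefined CV)", n_zero)
        self.support_ = pass_tpm & pass_cv
        self.cv_ = cv
        self.report_ = FilterReport(
            n_input=len(data),
            n_pass_tpm=int(pass_tpm.sum()),
            n_pass_cv=int((pass_tpm & pass_cv).sum()),
            removed_ids=data.index[~self.support_].tolist(),
            thresholds={"min_tpm": self.min_tpm, "min_cv": self.min_cv},
        )
        return self

    def transform(self, profiles: ExpressionTable) -> ExpressionTable:
        return ExpressionTable(
            profiles.data.loc[self.support_.reindex(profiles.data.index, fill_value=False)],
            profiles.unit,
        )

    def fit_transform(self, profiles: ExpressionTable) -> ExpressionTable:
        return self.fit(profiles).transform(profiles)


def filter_features(
    profiles: ExpressionTable, min_tpm: float = 10.0, min_cv: float = 0.5
) -> tuple[ExpressionTable, FilterReport]:
    """Functional wrapper around :class:`ExpressionFilter`."""
    filt = ExpressionFilter(min_tpm=min_tpm, min_cv=min_cv)
    kept = filt.fit_transform(profiles)
    return kept, filt.report_


def aggregate_gene_expression(
    table: ExpressionTable,
    promoter_to_gene,
    min_tpm: float = 20.0,
) -> ExpressionTable:
    """Sum promoter-level TPM into gene-level expression and keep genes whose
    profile reaches ``min_tpm`` in at least one sample.

    ``promoter_to_gene`` is a mapping or an iterable of (promoter_id,
    gene_id) pairs; a promoter mapped to two genes is a schema error, and
    unmapped promoters are ignored (count logged).
    """
    if hasattr(promoter_to_gene, "items"):
        pairs = list(promoter_to_gene.items())
    else:
        pairs = [tuple(p) for p in promoter_to_gene]
    mapping = pd.DataFrame(pairs, columns=["promoter", "gene"])
    dup = mapping["promoter"].duplicated(keep=False)
    conflicted = mapping.loc[dup].groupby("promoter")["gene"].nunique()
    if (conflicted > 1).any():
        bad = conflicted.index[conflicted > 1].tolist()
        raise SchemaError(f"promoter(s) mapped to multiple genes: {bad[:5]}")
    mapping = mapping.drop_duplicates("promoter")

    in_table = mapping["promoter"].isin(table.data.index)
    n_unmapped = len(set(table.data.index) - set(mapping["promoter"]))
    if n_unmapped:
        log.info("%d promoters without a gene mapping ignored", n_unmapped)
    mapping = mapping.loc[in_table]

    sub = table.data.loc[mapping["promoter"]]
    sub.index = mapping["gene"].to_numpy()
    gene = sub.groupby(level=0).sum()
    keep = gene.max(axis=1) >= min_tpm
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("%d genes below %g TPM at every sample removed", n_drop, min_tpm)
    return ExpressionTable(gene.loc[keep], table.unit)
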