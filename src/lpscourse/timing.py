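"""Onset/peak timing and enhancer-promoter lead-lag analysis.

Tests the observation that transient eRNA transcription precedes the
activation of nearby promoters: each feature's donor-averaged profile gets a
peak time (earliest timepoint attaining the maximum) and an onset time
(earliest timepoint reaching max(onset_floor, onset_frac * peak)); enhancers
are paired with promoters within a genomic window and the lead of each pair
is promoter peak minus enhancer peak, positive when the enhancer fires
first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable
from .errors import SchemaError


@dataclass
class TimingRecord:
    feature_id: str
    peak_time_minutes: float
    onset_time_minutes: float | None
    peak_tpm: float
    baseline_tpm: float


def _minutes_from_columns(columns) -> np.ndarray:
    try:
        return np.array([float(str(c).lstrip("t")) for c in columns])
    except ValueError as exc:
        raise SchemaError(
            "profile columns must be timepoints named like 't120'"
        ) from exc


def peak_time(
    profile: pd.Series,
    onset_floor: float = 1.0,
    onset_frac: float = 0.1,
    feature_id: str | None = None,
) -> TimingRecord:
    """Timing record for one donor-averaged profile (index = timepoints).

    Ties at the maximum break to the earliest timepoint. Onset is the
    earliest timepoint with TPM >= max(onset_floor, onset_frac * peak), or
    absent if the profile never reaches that level.
    """
    minutes = _minutes_from_columns(profile.index)
    values = profile.to_numpy(dtype=float)
    peak_idx = int(np.argmax(values))  # argmax returns the first maximum
    peak = float(values[peak_idx])
    threshold = max(onset_floor, onset_frac * peak)
    above = np.flatnonzero(values >= threshold)
    onset = float(minutes[above[0]]) if len(above) else None
    return TimingRecord(
        feature_id=feature_id if feature_id is not None else str(profile.name),
        peak_time_minutes=float(minutes[peak_idx]),
        onset_time_minutes=onset,
        peak_tpm=peak,
        baseline_tpm=float(values[0]),
    )


def timing_table(
    profiles: ExpressionTable, onset_floor: float = 1.0, onset_frac: float = 0.1
) -> pd.DataFrame:
    """Vectorized timing records for every profile in a feature x timepoint
    table."""
    minutes = _minutes_from_columns(profiles.data.columns)
    values = profiles.data.to_numpy(dtype=float)
    peak_idx = values.argmax(axis=1)
    peak = values[np.arange(len(values)), peak_idx]
    threshold = np.maximum(onset_floor, onset_frac * peak)
    reached = values >= threshold[:, None]
    has_onset = reached.any(axis=1)
    onset_idx = reached.argmax(axis=1)
    onset = np.where(has_onset, minutes[onset_idx], np.nan)
    return pd.DataFrame(
        {
            "feature_id": profiles.data.index,
            "peak_time_minutes": minutes[peak_idx],
            "onset_time_minutes": onset,
            "peak_tpm": peak,
            "baseline_tpm": values[:, 0],
        }
    ).set_index("feature_id")


def associate_pairs(loci: pd.DataFrame, window: int = 500_000) -> pd.DataFrame:
    """All (enhancer, promoter) pairs on the same chromosome with
    |enhancer position - promoter TSS| <= window.

    ``loci`` needs columns feature_id, chrom, tss_pos, feature_class; for
    enhancers tss_pos holds the element midpoint.
    """
    rows = []
    for _, group in loci.groupby("chrom"):
        proms = group.loc[group["feature_class"] == "promoter"]
        enhs = group.loc[group["feature_class"] == "enhancer"]
        if proms.empty or enhs.empty:
            continue
        ep = enhs["tss_pos"].to_numpy()[:, None]
        pp = proms["tss_pos"].to_numpy()[None, :]
        dist = np.abs(ep - pp)
        ei, pi = np.nonzero(dist <= window)
        for e, p in zip(ei, pi):
            rows.append(
                (
                    enhs["feature_id"].iloc[e],
                    proms["feature_id"].iloc[p],
                    int(dist[e, p]),
                )
            )
    return pd.DataFrame(rows, columns=["enhancer_id", "promoter_id", "distance_bases"])


def lead_lag(
    pairs: pd.DataFrame, timing: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Lead-lag table and summary for enhancer-promoter pairs.

    lead_minutes = promoter peak - enhancer peak (positive: enhancer first);
    onset_lead_minutes = promoter peak - enhancer onset, undefined when the
    enhancer has no onset. The summary reports the fraction of pairs with a
    positive peak lead and, per promoter, how many associated enhancers had
    detectable activity (onset) before the promoter's peak.
    """
    missing = (set(pairs["enhancer_id"]) | set(pairs["promoter_id"])) - set(
        timing.index
    )
    if missing:
        raise SchemaError(f"pairs reference features without timing: {sorted(missing)[:5]}")
    e = timing.loc[pairs["enhancer_id"]]
    p = timing.loc[pairs["promoter_id"]]
    lead = p["peak_time_minutes"].to_numpy() - e["peak_time_minutes"].to_numpy()
    onset_lead = p["peak_time_minutes"].to_numpy() - e["onset_time_minutes"].to_numpy()
    table = pairs.copy()
    table["lead_minutes"] = lead
    table["onset_lead_minutes"] = onset_lead

    defined = table["onset_lead_minutes"].notna()
    early = table.loc[defined & (table["onset_lead_minutes"] > 0)]
    per_promoter = early.groupby("promoter_id").size()
    summary = {
        "n_pairs": int(len(table)),
        "frac_positive_lead": float((table["lead_minutes"] > 0).mean())
        if len(table)
        else float("nan"),
        "median_lead_minutes": float(table["lead_minutes"].median())
        if len(table)
        else float("nan"),
        "n_pairs_with_onset": int(defined.sum()),
        "enhancers_active_before_promoter_peak": {
            str(k): int(v) for k, v in per_promoter.items()
        },
    }
    return table, summary
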