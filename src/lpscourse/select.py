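"""A-priori expression-pattern criteria for monocyte/macrophage candidates.

Each criterion compares pseudocounted condition-group means: downregulation
on monocyte-to-macrophage differentiation, specific induction by a stimulus
relative to every other group, and the explicit >= 5-fold change between
monocytes and CSF1-grown macrophages. A feature enters the candidate set
only when every requested criterion holds. The SNP-proximal subset picks
features whose TSS lies within a window of a significant GWAS variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable, validate_design
from .errors import SchemaError


@dataclass
class GroupSummary:
    """Per-feature arithmetic mean TPM per condition group."""

    group_means: pd.DataFrame  # features x groups
    pseudocount: float = 1.0

    @property
    def groups(self) -> list:
        return self.group_means.columns.tolist()


@dataclass
class CandidateSet:
    """Features passing all requested criteria, with per-criterion flags."""

    feature_ids: set
    criteria_flags: pd.DataFrame  # features x criteria, boolean
    fold_threshold: float = 5.0
    specificity_fold: float = 2.0


def summarize_groups(
    table: ExpressionTable, design: pd.DataFrame, pseudocount: float = 1.0
) -> GroupSummary:
    """Mean TPM per feature per condition group from a sample design."""
    validate_design(design, table)
    if "condition_group" not in design.columns:
        raise SchemaError("design table has no condition_group column")
    groups = design.set_index("sample_id")["condition_group"]
    missing = groups.isna() | (groups == "")
    if missing.any():
        raise SchemaError(
            f"samples without a condition group: {groups.index[missing].tolist()[:5]}"
        )
    assignment = groups.reindex(table.sample_ids)
    means = table.data.T.groupby(assignment.to_numpy()).mean().T
    if (means.count() == 0).any():
        raise SchemaError("empty condition group in design")
    return GroupSummary(means, pseudocount)


def _require_groups(summary: GroupSummary, *names: str) -> None:
    missing = [n for n in names if n not in summary.group_means.columns]
    if missing:
        raise SchemaError(f"condition group(s) absent from summary: {missing}")


def criterion_down_in_mdm(summary: GroupSummary, fold: float = 2.0) -> pd.Series:
    """True where monocyte expression exceeds MDM expression ``fold``-times
    (pseudocounted ratio)."""
    _require_groups(summary, "unstimulated_monocyte", "unstimulated_MDM")
    pc = summary.pseudocount
    ratio = (summary.group_means["unstimulated_monocyte"] + pc) / (
        summary.group_means["unstimulated_MDM"] + pc
    )
    return (ratio >= fold).rename("down_in_mdm")


def criterion_specific_induction(
    summary: GroupSummary, stimulus_group: str, specificity_fold: float = 2.0
) -> pd.Series:
    """True where the stimulus group's mean exceeds ``specificity_fold``
    times the largest other group mean (both pseudocounted)."""
    _require_groups(summary, stimulus_group)
    if len(summary.groups) < 2:
        raise SchemaError("specific induction needs at least two groups")
    pc = summary.pseudocount
    others = summary.group_means.drop(columns=stimulus_group)
    flag = (summary.group_means[stimulus_group] + pc) >= specificity_fold * (
        others.max(axis=1) + pc
    )
    return flag.rename(f"specific_{stimulus_group}")


def fold_change_select(
    summary: GroupSummary, fold: float = 5.0, direction: str = "both"
) -> CandidateSet:
    """Features changed >= ``fold``-times between monocytes and MDM.

    ``direction``: "down" (higher in monocytes), "up" (higher in MDM), or
    "both".
    """
    _require_groups(summary, "unstimulated_monocyte", "unstimulated_MDM")
    if direction not in ("down", "up", "both"):
        raise SchemaError(f"unknown direction {direction!r}")
    pc = summary.pseudocount
    mono = summary.group_means["unstimulated_monocyte"] + pc
    mdm = summary.group_means["unstimulated_MDM"] + pc
    down = (mono / mdm >= fold).rename("down")
    up = (mdm / mono >= fold).rename("up")
    if direction == "down":
        selected = down
    elif direction == "up":
        selected = up
    else:
        selected = down | up
    flags = pd.concat([down, up], axis=1)
    return CandidateSet(
        set(selected.index[selected]), flags, fold_threshold=fold
    )


def select_candidates(
    summary: GroupSummary,
    stimulus_group: str = "inflammatory_monocyte",
    fold: float = 5.0,
    specificity_fold: float = 2.0,
) -> CandidateSet:
    """The composite monocyte/macrophage candidate definition: >= ``fold``
    down in MDM relative to monocytes AND specifically induced by
    ``stimulus_group``."""
    down = fold_change_select(summary, fold=fold, direction="down")
    down_flag = pd.Series(
        summary.group_means.index.isin(down.feature_ids),
        index=summary.group_means.index,
        name="down_in_mdm",
    )
    spec = criterion_specific_induction(summary, stimulus_group, specificity_fold)
    flags = pd.concat([down_flag, spec], axis=1)
    selected = flags.all(axis=1)
    return CandidateSet(
        set(selected.index[selected]),
        flags,
        fold_threshold=fold,
        specificity_fold=specificity_fold,
    )


def snp_proximal_subset(
    loci: pd.DataFrame,
    variants: pd.DataFrame,
    p_threshold: float = 1e-6,
    window: int = 2000,
) -> set:
    """Features whose TSS lies within ``window`` bases of a variant with
    p < ``p_threshold``.

    Distance is strand-agnostic and boundary inclusive; variant positions
    (1-based) are shifted into the loci's 0-based frame before comparison.
    Chromosomes are partitioned, so cross-chromosome pairs never match.
    """
    sig = variants.loc[variants["pvalue"] < p_threshold]
    hits: set = set()
    for chrom, group in loci.groupby("chrom"):
        pos = np.sort(sig.loc[sig["chrom"] == chrom, "pos"].to_numpy() - 1)
        if len(pos) == 0:
            continue
        tss = group["tss_pos"].to_numpy()
        idx = np.searchsorted(pos, tss)
        dist = np.full(len(tss), np.iinfo(np.int64).max, dtype=np.int64)
        for shift in (-1, 0):
            j = np.clip(idx + shift, 0, len(pos) - 1)
            dist = np.minimum(dist, np.abs(tss - pos[j]))
        hits |= set(group.loc[dist <= window, "feature_id"])
    return hits
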