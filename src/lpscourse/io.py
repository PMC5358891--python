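"""Readers and writers for every on-disk format the pipeline touches.

All tables are plain tab-separated text. Genomic conventions: BED input is
0-based half-open; GWAS variant positions are 1-based; every internal
distance is computed in a single 0-based frame after conversion. Floats are
written with repr-level precision so writer -> reader round trips reproduce
values to better than 1e-9.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable, validate_design
from .errors import CoordinateError, ParseError, SchemaError

log = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.17g"


def read_expression_table(path, unit: str = "tpm") -> ExpressionTable:
    """Tab-separated matrix: first column feature id, header of sample ids."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.isna().any().any():
        rows = frame.index[frame.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing cells in rows {rows[:5]}")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric column(s) {non_numeric[:5]}")
    try:
        return ExpressionTable(frame, unit)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_expression_table(table: ExpressionTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id",
                      float_format=_FLOAT_FORMAT)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    return validate_design(design)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED6 (chrom, start, end, name, score, strand) into a loci table.

    The feature class is taken from a 7th column when present, else
    "promoter". Promoter TSS: start for '+' strand, end-1 for '-';
    promoters must be stranded. Enhancer positions are the interval
    midpoint.
    """
    path = Path(path)
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            feature_class = parts[6] if len(parts) > 6 else "promoter"
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer interval") from exc
            if start < 0 or start >= end:
                raise CoordinateError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if feature_class == "promoter":
                if strand == "+":
                    tss = start
                elif strand == "-":
                    tss = end - 1
                else:
                    raise SchemaError(
                        f"{path}:{lineno}: promoter {name!r} lacks a strand"
                    )
            else:
                tss = (start + end) // 2
            rows.append((name, chrom, tss, strand, feature_class))
    loci = pd.DataFrame(
        rows, columns=["feature_id", "chrom", "tss_pos", "strand", "feature_class"]
    )
    if loci["feature_id"].duplicated().any():
        dupes = loci.loc[loci["feature_id"].duplicated(), "feature_id"].tolist()
        raise SchemaError(f"{path}: duplicate feature ids {dupes[:5]}")
    return loci


def write_bed(loci: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_bed` for single-base TSS records (promoters
    become 1-bp intervals; enhancers 1-bp intervals at their midpoint)."""
    with open(path, "w") as handle:
        for row in loci.itertuples(index=False):
            start, end = row.tss_pos, row.tss_pos + 1
            handle.write(
                f"{row.chrom}\t{start}\t{end}\t{row.feature_id}\t0\t"
                f"{row.strand}\t{row.feature_class}\n"
            )


def read_summary_stats(path) -> pd.DataFrame:
    """GWAS summary statistics: tab-separated with columns chrom, pos, id, p.

    Rows with p outside (0, 1] are rejected; the casualty count is logged.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "id", "p"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    frame = frame.rename(columns={"id": "variant_id", "p": "pvalue"})
    valid = (frame["pvalue"] > 0) & (frame["pvalue"] <= 1)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("%s: rejected %d rows with p outside (0, 1]", path, n_bad)
    return frame.loc[valid, ["variant_id", "chrom", "pos", "pvalue"]].reset_index(
        drop=True
    )


def write_summary_stats(variants: pd.DataFrame, path) -> None:
    out = variants.rename(columns={"variant_id": "id", "pvalue": "p"})
    out[["chrom", "pos", "id", "p"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FORMAT
    )


def write_clusters(path, clusters) -> None:
    """Two-column table (feature_id, cluster_id), sorted by (cluster_id,
    feature_id); unclustered features are omitted."""
    rows = [
        (member, k)
        for k, members in enumerate(clusters.clusters)
        for member in members
    ]
    frame = pd.DataFrame(rows, columns=["feature_id", "cluster_id"])
    frame = frame.sort_values(["cluster_id", "feature_id"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


def read_motif_counts(path) -> pd.DataFrame:
    from .mara import read_motif_matrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return read_motif_matrix(frame)


def write_motif_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def write_manifest(config, path, extra: dict | None = None) -> None:
    """JSON run manifest echoing the full configuration."""
    payload = {"config": config.to_dict() if hasattr(config, "to_dict") else dict(config)}
    if extra:
        payload.update(extra)
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def write_truth(truth, outdir) -> None:
    """Serialize whatever ground-truth components a SimTruth carries as
    tab-separated tables under ``outdir``."""
    outdir = Path(outdir)
    if truth.cluster_label is not None:
        truth.cluster_label.rename_axis("feature_id").to_csv(
            outdir / "truth_archetypes.tsv", sep="\t"
        )
    if truth.outlier_mask is not None:
        f, t, d = np.nonzero(truth.outlier_mask)
        pd.DataFrame({"feature_idx": f, "timepoint_idx": t, "donor_idx": d}).to_csv(
            outdir / "truth_spikes.tsv", sep="\t", index=False
        )
    if truth.class_label is not None:
        truth.class_label.rename_axis("feature_id").to_csv(
            outdir / "truth_classes.tsv", sep="\t"
        )
    if truth.planted_activity is not None:
        truth.planted_activity.to_csv(
            outdir / "truth_activities.tsv", sep="\t",
            index_label="motif_id", float_format=_FLOAT_FORMAT,
        )
    if truth.pairs is not None:
        truth.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    if truth.enriched_tss_ids is not None:
        pd.Series(sorted(truth.enriched_tss_ids), name="feature_id").to_csv(
            outdir / "truth_enriched_tss.tsv", sep="\t", index=False
        )
    if truth.variant_sig_flag is not None:
        truth.variant_sig_flag.rename_axis("variant_id").to_csv(
            outdir / "truth_variant_flags.tsv", sep="\t"
        )
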