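"""Peak-set algebra and TSS-window regulatory potential.

Coordinates are BED-style 0-based half-open throughout.  Gained peaks are
case peaks with no (or sub-threshold) overlap against the control set;
regulatory potential sums a distance-decayed contribution of each peak
center within a TSS window, following the BETA-minus convention of a
100 kb window with an exponential decay kernel.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .ingest import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed",
    "write_bed",
    "normalize_peaks",
    "gained_peaks",
    "regulatory_potential",
    "average_score",
    "tss_window_peaks",
    "read_annotation",
    "decay_weight",
]

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def normalize_peaks(peaks: pd.DataFrame, name: str = "peaks") -> pd.DataFrame:
    """Validate and sort a peak table (chrom, start, end[, name, score, strand])."""
    missing = [c for c in ("chrom", "start", "end") if c not in peaks.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")
    out = peaks.copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    bad = out.index[~(out["start"] < out["end"])]
    if len(bad):
        raise ValidationError(f"{name}: start >= end at row(s) {list(bad[:5])}")
    if (out["start"] < 0).any():
        raise ValidationError(f"{name}: negative coordinates")
    return out.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column headerless BED file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed interval ({exc})") from exc
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = float(parts[4])
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    df = pd.DataFrame(rows, columns=[c for c in BED_COLUMNS if rows and c in rows[0]])
    if not len(df):
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return normalize_peaks(df, name=str(path))


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def _to_pyranges(peaks: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": peaks["chrom"].astype(str),
                "Start": peaks["start"].astype(int),
                "End": peaks["end"].astype(int),
                "row_id": np.arange(len(peaks)),
            }
        )
    )


def gained_peaks(
    case: pd.DataFrame,
    control: pd.DataFrame,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Case peaks with less than ``min_overlap_bp`` overlap to any control peak."""
    case = normalize_peaks(case, "case")
    control = normalize_peaks(control, "control")
    if len(case) == 0 or len(control) == 0:
        return case
    joined = _to_pyranges(case).join(_to_pyranges(control)).df
    if len(joined) == 0:
        return case
    overlap = np.minimum(joined["End"], joined["End_b"]) - np.maximum(
        joined["Start"], joined["Start_b"]
    )
    hit = joined.loc[overlap >= min_overlap_bp, "row_id"].unique()
    keep = ~case.index.isin(hit)
    return case.loc[keep].reset_index(drop=True)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene_id, chrom, tss, strand)."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("gene_id", "chrom", "tss", "strand") if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation: missing column(s) {missing}")
    if ann["gene_id"].duplicated().any():
        raise ValidationError("annotation: duplicate gene_id (one TSS per gene)")
    if (ann["tss"] < 0).any():
        raise ValidationError("annotation: negative TSS")
    if not ann["strand"].isin(["+", "-"]).all():
        raise ValidationError("annotation: strand must be + or -")
    return ann


def decay_weight(delta: np.ndarray) -> np.ndarray:
    """BETA-style exponential decay at normalized distance delta in [0, 1]."""
    return np.exp(-(0.5 + 4.0 * np.asarray(delta, dtype=float)))


def regulatory_potential(
    peaks: pd.DataFrame,
    ann: pd.DataFrame,
    window_bp: int = 100_000,
    kernel: str = "exponential",
) -> pd.Series:
    """Per-gene regulatory potential from peaks within +/-window_bp of the TSS.

    Each peak contributes by its interval midpoint: a peak at normalized
    distance ``delta = |center - tss| / window_bp`` (<= 1) adds
    ``exp(-(0.5 + 4 delta))`` (kernel "exponential"), ``1 - delta``
    ("linear") or 1 ("flat").  Every annotated gene is scored; genes with
    no peak in the window score 0.  Peaks on chromosomes absent from the
    annotation are skipped with a logged count.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    kernels = {
        "exponential": decay_weight,
        "linear": lambda d: 1.0 - np.asarray(d, dtype=float),
        "flat": lambda d: np.ones_like(np.asarray(d, dtype=float)),
    }
    if kernel not in kernels:
        raise ValueError(f"unknown kernel {kernel!r}")
    peaks = normalize_peaks(peaks)
    ann = validate_annotation(ann)
    known = set(ann["chrom"])
    skipped = int((~peaks["chrom"].isin(known)).sum())
    if skipped:
        logger.warning("%d peak(s) on chromosomes absent from annotation skipped", skipped)
    scores = pd.Series(0.0, index=pd.Index(ann["gene_id"], name="gene_id"), name="reg_potential")
    centers = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0
    for chrom, sub_ann in ann.groupby("chrom"):
        on_chrom = peaks["chrom"].to_numpy() == chrom
        if not on_chrom.any():
            continue
        c = centers[on_chrom]
        for gene, tss in zip(sub_ann["gene_id"], sub_ann["tss"]):
            dist = np.abs(c - float(tss))
            inside = dist <= window_bp
            if inside.any():
                scores[gene] = float(kernels[kernel](dist[inside] / window_bp).sum())
    return scores


def average_score(tables: Sequence[pd.Series]) -> pd.Series:
    """Per-gene mean regulatory potential over the tables that score the gene.

    The denominator for each gene counts only the tables whose index
    contains it (a gene scored 0 counts; a gene absent does not).
    """
    if not tables:
        raise ValidationError("need at least one score table")
    df = pd.concat(tables, axis=1, keys=range(len(tables)))
    return df.mean(axis=1, skipna=True).rename("avg_reg_potential")


def tss_window_peaks(
    peaks: pd.DataFrame,
    gene: str,
    ann: pd.DataFrame,
    window_bp: int = 200_000,
) -> pd.DataFrame:
    """Peaks within +/-window_bp of one gene's TSS, with strand-aware offsets.

    Offsets are signed so that upstream of the gene is negative regardless
    of strand.  Full peak coordinates (and intensity if a score column is
    present) are retained.
    """
    ann = validate_annotation(ann)
    row = ann.loc[ann["gene_id"] == gene]
    if not len(row):
        raise ValidationError(f"unknown gene {gene!r}")
    chrom, tss, strand = row.iloc[0][["chrom", "tss", "strand"]]
    peaks = normalize_peaks(peaks)
    sub = peaks[peaks["chrom"] == chrom].copy()
    center = (sub["start"] + sub["end"]) / 2.0
    offset = center - float(tss)
    if strand == "-":
        offset = -offset
    sub["offset"] = offset
    sub = sub[np.abs(sub["offset"]) <= window_bp]
    if "score" not in sub.columns:
        sub["score"] = np.nan
    return sub.sort_values("offset").reset_index(drop=True)
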