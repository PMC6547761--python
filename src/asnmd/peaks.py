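"""eCLIP peak handling: reading, filtering, replicate merging, proximity.

Peaks are strand-specific crosslinking intervals for one RNA-binding
protein (RBP), assayed in replicate within each cell line. Following the
standard reproducibility practice for this assay, peaks are first filtered
by enrichment over the size-matched input (log2 fold enrichment >= 3 and
P < 0.001), then the union of the two replicates is taken within each cell
line, and the resulting sets are pooled across cell lines.

All coordinates are 0-based half-open. Distances are gap-style: any overlap
is distance 0; window membership is inclusive (distance <= window).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "log2_enrichment",
    "neg_log10_p",
    "neg_log10_q",
    "rbp",
    "cell_line",
    "replicate",
]

NARROWPEAK_FIELDS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]


def read_narrowpeak(path: str, rbp: str, cell_line: str, replicate: str) -> pd.DataFrame:
    """Read a 10-column narrowPeak file into the internal peak frame.

    signalValue maps to log2 fold enrichment over input; pValue/qValue are
    -log10 scaled, as in the narrowPeak dialect.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_FIELDS,
                     dtype={0: str, 5: str})
    if df.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    if len(df.columns) < 10:
        raise ValueError(f"{path}: expected 10 narrowPeak columns")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: start >= end at row {bad + 1}")
    for col in ("signalValue", "pValue", "qValue"):
        if not np.isfinite(df[col]).all():
            raise ValueError(f"{path}: non-finite {col}")
    out = df[["chrom", "start", "end", "name", "score", "strand"]].copy()
    out["log2_enrichment"] = df["signalValue"].astype(float)
    out["neg_log10_p"] = df["pValue"].astype(float)
    out["neg_log10_q"] = df["qValue"].astype(float)
    out["rbp"] = rbp
    out["cell_line"] = cell_line
    out["replicate"] = replicate
    return out


def read_bed_peaks(
    path: str,
    rbp: str,
    cell_line: str,
    replicate: str,
    fc_column: int = 6,
    p_column: int = 7,
    p_scale: str = "neglog10",
) -> pd.DataFrame:
    """Read a BED6+ peak file with enrichment / p-value at given 0-based columns."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 5: str})
    if df.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    need = max(fc_column, p_column)
    if df.shape[1] <= need:
        raise ValueError(f"{path}: missing score column {need}")
    if (df[1] >= df[2]).any():
        bad = df.index[df[1] >= df[2]][0]
        raise ValueError(f"{path}: start >= end at row {bad + 1}")
    pvals = df[p_column].astype(float)
    if p_scale == "raw":
        pvals = -np.log10(np.maximum(pvals, np.finfo(float).tiny))
    elif p_scale != "neglog10":
        raise ValueError(f"unknown p_scale {p_scale!r}")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "name": df[3] if df.shape[1] > 3 else ".",
            "score": df[4] if df.shape[1] > 4 else 0,
            "strand": df[5] if df.shape[1] > 5 else ".",
            "log2_enrichment": df[fc_column].astype(float),
            "neg_log10_p": pvals,
            "neg_log10_q": np.nan,
            "rbp": rbp,
            "cell_line": cell_line,
            "replicate": replicate,
        }
    )
    return out


def filter_peaks(
    peaks: pd.DataFrame, min_log2fc: float = 3.0, max_p: float = 1e-3
) -> pd.DataFrame:
    """Retain peaks with log2 enrichment >= min_log2fc and p < max_p."""
    if peaks.empty:
        return peaks
    keep = (peaks["log2_enrichment"] >= min_log2fc) & (
        peaks["neg_log10_p"] > -np.log10(max_p)
    )
    return peaks.loc[keep].reset_index(drop=True)


def _coalesce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping/touching same-strand intervals, keeping the
    maximum of any score columns present."""
    score_cols = [c for c in ("log2_enrichment", "neg_log10_p", "neg_log10_q") if c in df]
    rows = []
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for r in grp.itertuples(index=False):
            if cur is None or r.start > cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(r.start), "end": int(r.end), "strand": strand}
                for c in score_cols:
                    cur[c] = getattr(r, c)
            else:
                cur["end"] = max(cur["end"], int(r.end))
                for c in score_cols:
                    cur[c] = np.nanmax([cur[c], getattr(r, c)])
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"] + score_cols)
    return out.sort_values(["chrom", "start", "end"], ignore_index=True)


def merge_replicates_and_pool(peak_frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union of replicate peaks within each cell line, pooled across lines.

    All frames must belong to the same RBP. Overlapping same-strand
    intervals are coalesced; score columns carry the max over merged peaks.
    """
    frames = [f for f in peak_frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    rbps = {r for f in frames for r in f["rbp"].unique()}
    if len(rbps) > 1:
        raise ValueError(f"mixed RBP names in merge: {sorted(rbps)}")
    per_line = []
    df = pd.concat(frames, ignore_index=True)
    for _, grp in df.groupby("cell_line", sort=True):
        per_line.append(_coalesce_frame(grp))
    pooled = pd.concat(per_line, ignore_index=True)
    out = _coalesce_frame(pooled)
    out["rbp"] = sorted(rbps)[0]
    return out


def total_bp(peaks: pd.DataFrame) -> int:
    merged = _coalesce_frame(peaks) if not peaks.empty else peaks
    return int((merged["end"] - merged["start"]).sum()) if not merged.empty else 0


def jaccard(set_a: pd.DataFrame, set_b: pd.DataFrame) -> tuple[float, float]:
    """Base-pair Jaccard (index, distance) between two coalesced peak sets."""
    la, lb = total_bp(set_a), total_bp(set_b)
    if la == 0 and lb == 0:
        warnings.warn("jaccard undefined for two empty peak sets")
        return float("nan"), float("nan")
    a = _coalesce_frame(set_a) if not set_a.empty else set_a
    b = _coalesce_frame(set_b) if not set_b.empty else set_b
    inter = 0
    if not (a.empty or b.empty):
        for (chrom, strand), ga in a.groupby(["chrom", "strand"]):
            gb = b[(b["chrom"] == chrom) & (b["strand"] == strand)]
            if gb.empty:
                continue
            ia = ga[["start", "end"]].to_numpy()
            ib = gb[["start", "end"]].to_numpy()
            i = j = 0
            while i < len(ia) and j < len(ib):
                lo = max(ia[i, 0], ib[j, 0])
                hi = min(ia[i, 1], ib[j, 1])
                if hi > lo:
                    inter += hi - lo
                if ia[i, 1] < ib[j, 1]:
                    i += 1
                else:
                    j += 1
    union = la + lb - inter
    index = inter / union if union else float("nan")
    return index, 1.0 - index


def self_binding(
    peaks: pd.DataFrame,
    gene_span: tuple[str, int, int, str],
    ignore_strand: bool = False,
) -> tuple[bool, int]:
    """Does the RBP's (filtered, merged) peak set hit its own gene locus?

    Returns (any peak overlaps the gene span on the same strand, count of
    such peaks). eCLIP is strand-specific, so same-strand is the default.
    """
    chrom, start, end, strand = gene_span
    if peaks.empty:
        return False, 0
    sel = (peaks["chrom"] == chrom) & (peaks["start"] < end) & (peaks["end"] > start)
    if not ignore_strand:
        sel &= peaks["strand"] == strand
    n = int(sel.sum())
    return n > 0, n


def nearest_peak_distance(
    exon: tuple[str, int, int, str],
    peaks: pd.DataFrame,
    ignore_strand: bool = False,
) -> float:
    """Minimal nucleotide gap between the exon and any peak (0 on overlap).

    Returns +inf when no peak shares the exon's chromosome (and strand).
    """
    chrom, start, end, strand = exon
    if peaks.empty:
        return float("inf")
    sel = peaks["chrom"] == chrom
    if not ignore_strand:
        sel &= peaks["strand"] == strand
    sub = peaks.loc[sel]
    if sub.empty:
        return float("inf")
    ps = sub["start"].to_numpy()
    pe = sub["end"].to_numpy()
    gap = np.maximum(0, np.maximum(ps - end, start - pe))
    return float(gap.min())


def within_window(
    exon: tuple[str, int, int, str],
    peaks: pd.DataFrame,
    window_nt: int,
    ignore_strand: bool = False,
) -> bool:
    """True iff the nearest peak lies within ``window_nt`` (inclusive)."""
    if window_nt < 0:
        raise ValueError("window must be >= 0")
    return nearest_peak_distance(exon, peaks, ignore_strand) <= window_nt
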