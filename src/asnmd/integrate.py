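"""Integration of annotation, differential inclusion and eCLIP proximity.

A candidate autoregulatory AS-NMD feedback loop is an exon in an RBP gene
that (i) changes inclusion substantially under NMD-pathway inactivation,
(ii) changes inclusion substantially under knockdown of its own host RBP,
and (iii) lies near a cognate eCLIP peak (the RBP binding its own
pre-mRNA). The sign pattern separates loop classes: a poison exon in a
negative feedback loop gains inclusion when NMD is off (its inclusion
product is no longer degraded) and loses inclusion when its activating RBP
is depleted; an essential exon shows the opposite signs; same-sign changes
indicate a codirectional (putative positive-feedback) pattern.
"""

from __future__ import annotations

import math
import os
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import combine_neglog_q

LOOP_POISON = "poison-negative"
LOOP_ESSENTIAL = "essential-negative"
LOOP_CODIRECTIONAL = "codirectional"
LOOP_UNCLASSIFIED = "unclassified"

MASTER_COLUMNS = [
    "exon_id",
    "gene_id",
    "rbp",
    "chrom",
    "start",
    "end",
    "strand",
    "poison",
    "essential",
    "frame_class",
    "dpsi_nmd",
    "p_nmd",
    "q_nmd",
    "dpsi_kd",
    "p_kd",
    "q_kd",
    "nearest_peak_nt",
    "q_eclip",
]


def build_master_table(
    exon_annotation: pd.DataFrame,
    dpsi_nmd: pd.DataFrame,
    kd_tables: Mapping[str, pd.DataFrame],
    peak_distances: pd.DataFrame | None,
    rbp_by_gene: Mapping[str, str],
) -> pd.DataFrame:
    """One row per (cassette exon, cognate RBP of the host gene).

    Joins are outer on exon_id: missing statistics stay missing, never
    imputed. ``kd_tables`` maps RBP name -> genome-wide contrast table; each
    exon picks up the contrast of its host gene's RBP only. Exons of genes
    without an RBP profile keep a missing ``rbp``/``dpsi_kd``.
    """
    base = exon_annotation.loc[exon_annotation["cassette"]].copy()
    if base["exon_id"].duplicated().any():
        dup = base.loc[base["exon_id"].duplicated(), "exon_id"].iloc[0]
        raise ValueError(f"duplicate exon key in annotation: {dup}")
    base["rbp"] = base["gene_id"].map(lambda g: rbp_by_gene.get(g, np.nan))

    nmd = dpsi_nmd[["exon_id", "dpsi_nmd", "p_nmd", "q_nmd"]]
    if nmd["exon_id"].duplicated().any():
        raise ValueError("duplicate exon key in NMD contrast table")
    out = base.merge(nmd, on="exon_id", how="left")

    kd_parts = []
    for rbp, table in sorted(kd_tables.items()):
        t = table[["exon_id", "dpsi_corrected", "p", "q"]].copy()
        if t["exon_id"].duplicated().any():
            raise ValueError(f"duplicate exon key in KD table for {rbp}")
        t.columns = ["exon_id", "dpsi_kd", "p_kd", "q_kd"]
        t["rbp"] = rbp
        kd_parts.append(t)
    if kd_parts:
        kd = pd.concat(kd_parts, ignore_index=True)
        out = out.merge(kd, on=["exon_id", "rbp"], how="left")
    else:
        out["dpsi_kd"] = np.nan
        out["p_kd"] = np.nan
        out["q_kd"] = np.nan

    if peak_distances is not None and not peak_distances.empty:
        pk = peak_distances[["exon_id", "rbp", "nearest_peak_nt", "q_eclip"]]
        if pk.duplicated(["exon_id", "rbp"]).any():
            raise ValueError("duplicate (exon, rbp) key in peak distance table")
        out = out.merge(pk, on=["exon_id", "rbp"], how="left")
    else:
        out["nearest_peak_nt"] = np.nan
        out["q_eclip"] = np.nan

    return out[MASTER_COLUMNS].sort_values("exon_id", ignore_index=True)


def classify_loop_sign(dpsi_nmd: float, dpsi_kd: float) -> str:
    """Loop class from the sign pattern of the two inclusion changes."""
    if dpsi_nmd is None or dpsi_kd is None or math.isnan(dpsi_nmd) or math.isnan(dpsi_kd):
        return LOOP_UNCLASSIFIED
    if dpsi_nmd == 0 or dpsi_kd == 0:
        return LOOP_UNCLASSIFIED
    if dpsi_nmd > 0 and dpsi_kd < 0:
        return LOOP_POISON
    if dpsi_nmd < 0 and dpsi_kd > 0:
        return LOOP_ESSENTIAL
    return LOOP_CODIRECTIONAL


def call_candidates(
    master: pd.DataFrame,
    dpsi_threshold: float = 0.1,
    peak_window_nt: float = 5000,
) -> pd.DataFrame:
    """Gate the master table into ranked candidate feedback loops.

    A candidate needs |dpsi_nmd| >= threshold AND |dpsi_kd| >= threshold
    (both inclusive) AND a cognate peak within the window (inclusive).
    Candidates are ranked by the combined q (product of q_nmd, q_kd and the
    eCLIP peak q; missing components count as 1), ties broken by larger
    total |dpsi|, then exon key.
    """
    if dpsi_threshold < 0 or peak_window_nt < 0:
        raise ValueError("thresholds must be >= 0")
    df = master.copy()
    ok = (
        df["dpsi_nmd"].abs().ge(dpsi_threshold)
        & df["dpsi_kd"].abs().ge(dpsi_threshold)
        & df["nearest_peak_nt"].le(peak_window_nt)
    )
    df = df.loc[ok.fillna(False)].copy()
    df["loop_class"] = [
        classify_loop_sign(a, b) for a, b in zip(df["dpsi_nmd"], df["dpsi_kd"])
    ]
    df["combined_q"] = [
        combine_neglog_q(
            q1 if np.isfinite(q1) else 1.0,
            q2 if np.isfinite(q2) else 1.0,
            q3 if np.isfinite(q3) else 1.0,
        )
        for q1, q2, q3 in zip(df["q_nmd"], df["q_kd"], df["q_eclip"])
    ]
    df["effect_total"] = df["dpsi_nmd"].abs() + df["dpsi_kd"].abs()
    df = df.sort_values(
        ["combined_q", "effect_total", "exon_id"],
        ascending=[True, False, True],
        ignore_index=True,
    )
    return df.drop(columns="effect_total")


# ---------------------------------------------------------------------------
# UCSC track export
# ---------------------------------------------------------------------------

RED = "255,0,0"
BLUE = "0,0,255"
BLACK = "0,0,0"


def _bed9_row(chrom, start, end, name, score, strand, rgb) -> str:
    return "\t".join(
        [chrom, str(start), str(end), name, str(score), strand, str(start), str(end), rgb]
    )


def export_tracks(
    dpsi_tables: Mapping[str, pd.DataFrame],
    exon_annotation: pd.DataFrame,
    peaks: pd.DataFrame | None,
    out_dir: str,
    hub_name: str = "asnmd",
    genome_label: str = "custom",
) -> dict[str, str]:
    """Write BED9 tracks (red: dpsi > 0, blue: dpsi < 0; peaks black) + hub text.

    ``dpsi_tables`` maps contrast name -> table with exon_id and a dpsi
    column (``dpsi_nmd`` or ``dpsi_corrected``). Scores encode
    round(1000*|dpsi|) clipped to [0, 1000]. Exons with dpsi == 0 or
    missing are omitted. Returns the mapping of written file paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    coords = exon_annotation.set_index("exon_id")[["chrom", "start", "end", "strand"]]
    written: dict[str, str] = {}
    track_stanzas = []
    for contrast, table in sorted(dpsi_tables.items()):
        col = "dpsi_nmd" if "dpsi_nmd" in table.columns else "dpsi_corrected"
        lines = []
        for r in table.sort_values("exon_id").itertuples(index=False):
            d = getattr(r, col)
            if d is None or not np.isfinite(d) or d == 0:
                continue
            if r.exon_id not in coords.index:
                continue
            c = coords.loc[r.exon_id]
            score = int(min(1000, round(1000 * abs(d))))
            rgb = RED if d > 0 else BLUE
            lines.append(_bed9_row(c.chrom, c.start, c.end, r.exon_id, score, c.strand, rgb))
        path = os.path.join(out_dir, f"{contrast}.bed")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
        written[contrast] = path
        track_stanzas.append(
            f"track {contrast}\ntype bigBed 9\nitemRgb on\n"
            f"bigDataUrl {contrast}.bed\nshortLabel {contrast}\n"
            f"longLabel exon inclusion change, {contrast}\nvisibility dense\n"
        )
    if peaks is not None and not peaks.empty:
        lines = [
            _bed9_row(r.chrom, r.start, r.end, getattr(r, "rbp", "peak"), 0, r.strand, BLACK)
            for r in peaks.sort_values(["chrom", "start", "end"]).itertuples(index=False)
        ]
        path = os.path.join(out_dir, "peaks.bed")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        written["peaks"] = path
        track_stanzas.append(
            "track eclip_peaks\ntype bigBed 9\nitemRgb on\nbigDataUrl peaks.bed\n"
            "shortLabel eCLIP peaks\nlongLabel pooled filtered eCLIP peaks\nvisibility dense\n"
        )
    hub = os.path.join(out_dir, "hub.txt")
    with open(hub, "w") as fh:
        fh.write(
            f"hub {hub_name}\nshortLabel {hub_name}\nlongLabel AS-NMD feedback loop "
            f"predictions\ngenomesFile genomes.txt\nemail none@example.org\n"
        )
    with open(os.path.join(out_dir, "genomes.txt"), "w") as fh:
        fh.write(f"genome {genome_label}\ntrackDb trackDb.txt\n")
    with open(os.path.join(out_dir, "trackDb.txt"), "w") as fh:
        fh.write("\n".join(track_stanzas))
    written["hub"] = hub
    return written


def read_bed9(path: str) -> pd.DataFrame:
    """Re-read an exported BED9 track (for round-trips and downstream use)."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "item_rgb"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={0: str, 5: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    return df
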