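"""End-to-end orchestration: scenario directory -> candidate feedback loops.

Wires the stages together for a scenario laid out on disk in the formats
the generator writes (GTF + FASTA annotation, per-sample junction-count
TSVs with a sample sheet, replicate narrowPeak files with a manifest, and
an RBP-to-gene mapping). Real data prepared in the same formats runs
through the identical code path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import integrate, peaks as pk, splice_quant as sq
from .annotation import GenomeSequence, annotate_exons, parse_annotation, transcript_nmd_table


@dataclass
class PipelineResult:
    exon_table: pd.DataFrame
    nmd_contrast: pd.DataFrame
    kd_tables: dict[str, pd.DataFrame]
    peaksets: dict[str, pd.DataFrame]
    peak_distances: pd.DataFrame
    master: pd.DataFrame
    candidates: pd.DataFrame
    fits: dict[str, sq.RegressionFit | None] = field(default_factory=dict)
    transcript_table: pd.DataFrame | None = None


def exon_peak_stats(
    exon: tuple[str, int, int, str], peakset: pd.DataFrame, window_nt: float
) -> tuple[float, float]:
    """(nearest cognate peak distance, best peak q within the window)."""
    dist = pk.nearest_peak_distance(exon, peakset)
    q = float("nan")
    if np.isfinite(dist) and dist <= window_nt and "neg_log10_q" in peakset.columns:
        chrom, start, end, strand = exon
        sel = peakset[(peakset["chrom"] == chrom) & (peakset["strand"] == strand)]
        ps, pe = sel["start"].to_numpy(), sel["end"].to_numpy()
        gaps = np.maximum(0, np.maximum(ps - end, start - pe))
        best = sel.loc[gaps <= window_nt, "neg_log10_q"]
        if len(best) and np.isfinite(best.max()):
            q = 10.0 ** (-float(best.max()))
    return dist, q


def run_pipeline(
    scenario_dir: str,
    dpsi_threshold: float = 0.1,
    peak_window_nt: float = 5000,
    min_bin_records: int = 100,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run annotate -> quantify -> test -> peaks -> integrate on a directory."""
    d = str(scenario_dir)
    gtf = os.path.join(d, "annotation.gtf")
    fasta = os.path.join(d, "genome.fa")
    genes = parse_annotation(gtf, fasta)
    genome = GenomeSequence.from_fasta(fasta)
    exon_table = annotate_exons(genes, genome)
    cassette = exon_table.loc[exon_table["cassette"]].reset_index(drop=True)
    introns_by_gene = {g.gene_id: sorted(g.all_introns()) for g in genes}

    sheet = pd.read_csv(os.path.join(d, "sample_sheet.tsv"), sep="\t").fillna("")
    counts = {}
    for r in sheet.itertuples(index=False):
        counts[r.sample_id] = sq.read_junction_counts(
            os.path.join(d, "counts", f"{r.sample_id}.tsv")
        )
    control_ids = sheet.loc[sheet["role"] == "control", "sample_id"].tolist()
    if not control_ids:
        raise ValueError("sample sheet has no control sample")
    ctrl = sq.pool_counts(*[counts[s] for s in control_ids])

    fits: dict[str, sq.RegressionFit | None] = {}
    contrast_tables: dict[str, pd.DataFrame] = {}
    for r in sheet.loc[sheet["role"] == "kd"].itertuples(index=False):
        table, fit = sq.run_contrast(
            cassette, introns_by_gene, counts[r.sample_id], ctrl,
            min_bin_records=min_bin_records,
        )
        contrast_tables[r.contrast_id] = table
        fits[r.contrast_id] = fit

    nmd = sq.average_nmd_contrasts(
        contrast_tables["nmd_upf1"], contrast_tables["nmd_smg6"]
    )
    kd_tables = {
        cid[3:]: tbl for cid, tbl in contrast_tables.items() if cid.startswith("kd_")
    }

    rbp_map = pd.read_csv(os.path.join(d, "rbp_map.tsv"), sep="\t")
    rbp_by_gene = dict(zip(rbp_map["gene_id"], rbp_map["rbp"]))

    manifest = pd.read_csv(os.path.join(d, "peaks_manifest.tsv"), sep="\t")
    peaksets: dict[str, pd.DataFrame] = {}
    for rbp, grp in manifest.groupby("rbp", sort=True):
        frames = [
            pk.filter_peaks(
                pk.read_narrowpeak(os.path.join(d, r.path), rbp, r.cell_line, r.replicate)
            )
            for r in grp.itertuples(index=False)
        ]
        peaksets[rbp] = pk.merge_replicates_and_pool(frames)

    dist_rows = []
    for r in cassette.itertuples(index=False):
        rbp = rbp_by_gene.get(r.gene_id)
        if rbp is None or rbp not in peaksets:
            continue
        exon = (r.chrom, int(r.start), int(r.end), r.strand)
        dist, q = exon_peak_stats(exon, peaksets[rbp], peak_window_nt)
        dist_rows.append(
            {"exon_id": r.exon_id, "rbp": rbp, "nearest_peak_nt": dist, "q_eclip": q}
        )
    peak_distances = pd.DataFrame(
        dist_rows, columns=["exon_id", "rbp", "nearest_peak_nt", "q_eclip"]
    )

    master = integrate.build_master_table(
        exon_table, nmd, kd_tables, peak_distances, rbp_by_gene
    )
    candidates = integrate.call_candidates(
        master, dpsi_threshold=dpsi_threshold, peak_window_nt=peak_window_nt
    )
    result = PipelineResult(
        exon_table=exon_table,
        nmd_contrast=nmd,
        kd_tables=kd_tables,
        peaksets=peaksets,
        peak_distances=peak_distances,
        master=master,
        candidates=candidates,
        fits=fits,
        transcript_table=transcript_nmd_table(genes),
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        master.to_csv(os.path.join(out_dir, "master.tsv"), sep="\t", index=False)
        candidates.to_csv(os.path.join(out_dir, "candidates.tsv"), sep="\t", index=False)
        all_peaks = (
            pd.concat(peaksets.values(), ignore_index=True) if peaksets else None
        )
        integrate.export_tracks(
            {"nmd": nmd}, exon_table, all_peaks, os.path.join(out_dir, "tracks")
        )
    return result


PLANTED_CLASSES = {"poison_loop", "essential_loop", "codirectional"}
EXPECTED_LOOP_CLASS = {
    "poison_loop": integrate.LOOP_POISON,
    "essential_loop": integrate.LOOP_ESSENTIAL,
    "codirectional": integrate.LOOP_CODIRECTIONAL,
}


def evaluate_calls(candidates: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare called candidate loops against the generator's ground truth."""
    planted = truth.loc[truth["gene_class"].isin(PLANTED_CLASSES)]
    planted_ids = set(planted["exon_id"])
    called_ids = set(candidates["exon_id"])
    hit = called_ids & planted_ids
    expected = dict(zip(planted["exon_id"], planted["gene_class"].map(EXPECTED_LOOP_CLASS)))
    observed = dict(zip(candidates["exon_id"], candidates["loop_class"]))
    correct = sum(1 for e in hit if observed[e] == expected[e])
    n_called = len(called_ids)
    n_false = len(called_ids - planted_ids)
    return {
        "n_planted": len(planted_ids),
        "n_called": n_called,
        "n_hit": len(hit),
        "sensitivity_pct": 100.0 * len(hit) / len(planted_ids) if planted_ids else float("nan"),
        "class_accuracy_pct": 100.0 * correct / len(hit) if hit else float("nan"),
        "false_call_pct": 100.0 * n_false / n_called if n_called else 0.0,
        "n_false": n_false,
    }
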