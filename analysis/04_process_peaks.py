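#!/usr/bin/env python
"""Filter and merge eCLIP peaks; assess RBP self-binding.

Applies the enrichment filter (log2 FC >= 3, P < 0.001), unions replicate
peaks within each cell line, pools across cell lines, and checks which
RBPs bind their own gene locus. Writes results/self_binding.tsv.
"""

import warnings

import numpy as np
import pandas as pd

from asnmd.annotation import parse_annotation
from asnmd.peaks import filter_peaks, jaccard, merge_replicates_and_pool, read_narrowpeak, self_binding
from common import RESULTS, ensure_scenario


def main() -> None:
    out = ensure_scenario()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genes = {g.gene_id: g for g in parse_annotation(out / "annotation.gtf")}
    manifest = pd.read_csv(out / "peaks_manifest.tsv", sep="\t")
    rbp_map = pd.read_csv(out / "rbp_map.tsv", sep="\t")
    gene_of = dict(zip(rbp_map["rbp"], rbp_map["gene_id"]))

    rows, rep_jaccards = [], []
    for rbp, grp in manifest.groupby("rbp", sort=True):
        frames = {}
        for r in grp.itertuples(index=False):
            raw = read_narrowpeak(out / r.path, rbp, r.cell_line, r.replicate)
            frames[(r.cell_line, r.replicate)] = filter_peaks(raw)
        for cell in sorted({c for c, _ in frames}):
            reps = [frames[k] for k in frames if k[0] == cell]
            if len(reps) == 2 and not (reps[0].empty or reps[1].empty):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep_jaccards.append(jaccard(reps[0], reps[1])[0])
        merged = merge_replicates_and_pool(list(frames.values()))
        gene = genes[gene_of[rbp]]
        span = (gene.chrom, *gene.span, gene.strand)
        bound, n = self_binding(merged, span)
        rows.append(
            {"rbp": rbp, "gene_id": gene.gene_id, "gwn": gene.gwn,
             "n_merged_peaks": len(merged), "self_binding": bound,
             "self_peaks_in_gene": n}
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "self_binding.tsv", sep="\t", index=False)
    print(table.to_string(index=False, max_rows=12))
    print(f"\nself-binding RBPs: {int(table.self_binding.sum())} / {len(table)}")
    if rep_jaccards:
        print(f"median replicate Jaccard index after filtering: "
              f"{np.median(rep_jaccards):.2f}")


if __name__ == "__main__":
    main()
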