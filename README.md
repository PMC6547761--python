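# asnmd — autoregulatory splicing coupled to nonsense-mediated decay

Many RNA-binding proteins (RBPs) keep their own expression in check
through a negative feedback loop: the protein binds its own pre-mRNA and
shifts splicing toward an isoform carrying a premature termination codon
(PTC), which nonsense-mediated decay (NMD) then destroys. `asnmd` is an
analysis package for finding candidate loops of this kind by integrating
three data axes — transcript annotation, splice-junction counts from
knockdown RNA-seq (of the NMD pathway and of each RBP), and eCLIP binding
peaks — together with a fully specified synthetic-data generator so that
every stage is testable without downloads. It is aimed at computational
biologists studying post-transcriptional gene regulation.

## The model

**Exon classes.** A transcript is an NMD target when its stop codon ends
more than 50 nt upstream of the last exon–exon junction. A cassette exon
[x, y] (annotated introns [a, x], [y, b] and [a, b]) is *poison* if it
contains the stop codon of an NMD isoform — included, it kills the
transcript; it is *essential* if splicing it out and translating puts the
first in-frame stop >50 nt upstream of a remaining junction — skipped, it
kills the transcript.

**Inclusion quantification.** From junction read counts,

    Ψ = inc / (inc + 2·exc),        ΔΨ = Ψ(KD) − Ψ(Control)

where `inc` counts reads on the exon's two flanking junctions and `exc`
reads on junctions skipping it (denominators under 20 reads are
discarded). ΔΨ is corrected for the expression confound by residualizing
against log₁₀ of the denominator fold change (ΔΨᵢ = β₀ + β₁·log₁₀FCᵢ + eᵢ),
and significance comes from z-scores standardized within read-depth bins,
with Benjamini–Hochberg q-values.

**Loop calling.** Poison and essential exons must respond with *opposite*
signs to NMD inactivation and to depletion of their own host RBP:
ΔΨ(NMD) > 0 with ΔΨ(KD) < 0 is a poison-negative loop, the mirrored signs
an essential-negative loop, same signs a codirectional (putative positive
feedback) pattern. Candidates need |ΔΨ| ≥ 0.1 on both axes plus a cognate
eCLIP peak (log₂FC ≥ 3, P < 0.001, replicate-unioned and cell-line
pooled) within 5 kb, and are ranked by the product of the three q-values
(additive in −log₁₀).

## Worked example

The numbered scripts under `analysis/` run the whole study on the bundled
generator (bulky intermediates go to `scratch/`, tables to `results/`):

```bash
python analysis/01_simulate_scenario.py
python analysis/02_annotate_exons.py
python analysis/05_call_feedback_loops.py
```

The default scenario plants 20 negative feedback loops (10 poison, 10
essential, |ΔΨ effect| = 0.3, junction depth 200) among 200 genes, with
20 self-binding but effect-free RBPs as false-positive bait. Script 02
prints the classifier round-trip:

```
          quantity  count
          cassette    200
            poison     10
essential_cassette     10
         gwn_genes     20
```

and script 05 the integrated calls (abridged):

```
           exon_id       rbp         loop_class  dpsi_nmd  dpsi_kd  nearest_peak_nt
chr2:17860-17950:+ RBP_G0010    poison-negative   0.27578 -0.36681            412.0
chr1:37464-37585:+ RBP_G0019 essential-negative  -0.31738  0.33402            422.0
...
recovery vs planted truth: sensitivity 100% (20/20), loop-class accuracy 100%,
false calls 0.0% of 20 called
```

Reading the first row: the cassette exon at chr2:17860–17950 gains
inclusion when NMD is off (ΔΨ = +0.28, its inclusion isoform is no longer
degraded) and loses inclusion when its own RBP is depleted (ΔΨ = −0.37,
the RBP was activating it), with a cognate binding peak 412 nt away —
the signature of a poison-exon negative feedback loop.

`analysis/06_worked_statistics.py` reproduces the reference proportion
tests and enrichment expectations from published count tables, e.g. the
self-binding comparison 35/55 vs 24/60 → one-sided p = 0.0045 (unpooled
two-sample proportion test) and the expected chance overlap 863·39/8243 =
4.08.

## Layout

    src/asnmd/        annotation, splice_quant, peaks, stats, integrate,
                      synthetic_data, pipeline
    analysis/         numbered narrative drivers (simulate → annotate →
                      quantify → peaks → integrate → statistics)
    tests/            pytest suite with independent brute-force oracles
    scripts/          acceptance script
    results/          small output tables ; scratch/ holds bulky intermediates
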