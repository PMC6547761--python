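# Methods

`asnmd` detects candidate autoregulatory feedback loops in which an
RNA-binding protein (RBP) controls its own expression through alternative
splicing coupled to nonsense-mediated decay (AS-NMD). This note documents
the models, parameters, numerical choices and the synthetic study design;
every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Exon and transcript classification

All coordinates are 0-based half-open internally; GTF input is converted
from 1-based closed on read, BED output is written natively.

**NMD labelling (50-nt rule).** A coding transcript is an NMD target if
its stop codon ends strictly more than 50 nt upstream — in
spliced-transcript nucleotides — of the last exon–exon junction.
Single-exon transcripts are never NMD. When the annotation carries an
explicit `nonsense_mediated_decay` biotype tag, the tag takes precedence
and the source (`tag` vs `rule`) is recorded, so disagreements between
the two are visible in the per-transcript output. A gene with at least
one NMD isoform is a GWN (gene with NMD), otherwise GWO.

**Cassette exons.** Exon [x, y) is a cassette exon of its gene if introns
[a, x), [y, b) and the skipping intron [a, b) are all annotated in at
least one transcript of the gene. All qualifying (a, b) contexts are
found; the table reports the tightest one. The implementation is checked
for exact agreement against a brute-force enumeration over all intron
triples on randomized gene structures.

**Poison exons.** A cassette exon is poison if it contains a stop codon
of an annotated NMD isoform. "Contains" is any overlap of at least 1 nt:
the definitional wording gives no boundary rule, and the permissive
reading keeps a stop codon that straddles the exon edge — which still
terminates translation inside the exon — in scope.

**Essential exons.** For each internal CDS exon of each coding
transcript, the exon's nucleotides are spliced out, the modified
transcript is translated from the original start codon, and the exon is
essential if the first in-frame stop ends strictly more than 50 nt
upstream of at least one remaining junction. Codons containing N are
treated as non-stop (conservative on ambiguous sequence). An exon is
reported essential if it is essential in at least one transcript. The
classifier is held to exact agreement with an independent
delete–splice–translate oracle on hundreds of randomized transcripts.

**Frame class and relative position.** Exon length mod 3 separates
frame-preserving (3n) from frameshifting (3n+1, 3n+2) exons — skipping a
frameshifting exon almost certainly creates a premature stop downstream.
Relative position maps the exon midpoint, in spliced-transcript
coordinates, linearly onto [0%, 100%] between the midpoints of the first
and last exons; the table reports it against the longest transcript
containing the exon.

## Inclusion quantification and differential statistics

**PSI.** For a cassette exon, `inc` is the summed count of junction reads
on the two flanking introns and `exc` the summed count on introns that
span the exon; the inclusion rate is

    psi = inc / (inc + 2 * exc).

The factor 2 makes the estimator unbiased: every included molecule
produces two inclusion junctions while every skipped molecule produces
one exclusion junction, so a read supports inclusion with probability
2·phi/(1 + phi) when the true inclusion fraction is phi, and
inc/(inc + 2·exc) inverts exactly that map. Estimates with denominator
inc + 2·exc below 20 reads are unreliable and discarded. Bioreplicate
tables are pooled (counts summed) before quantification. The same
bookkeeping extends to alternative 5'/3' splice sites via pairs of
junctions sharing exactly one boundary, with the competing junction's
reads as exclusion support.

**Expression-confound correction.** Knocking down an RBP changes the
expression of its own transcript (and many others), and inclusion
estimates drift with local read depth. Using the psi denominator as a
depth proxy, an ordinary least-squares model

    dpsi_i = beta0 + beta1 * log10(FC_i) + e_i

is fit over exons with dpsi != 0, where FC is the denominator fold change
between knockdown and control, and each dpsi is replaced by its residual
(exons with dpsi = 0 keep 0). The default FC uses inc + 2·exc — the same
variable the significance binning uses; inc + exc is selectable. Two
caveats are documented deliberately: (i) per-contrast slope estimates on
a few hundred exons are noisy (standard error ~0.01); the dedicated
calibration study below sizes the problem properly; (ii) the
denominator-based proxy is mechanically anti-correlated with dpsi — for
fixed transcript output, higher inclusion means fewer denominator
counts (2T/(1+phi)) — which slightly biases the fitted slope downward at
low depth. Residualization removes whatever linear trend is present
either way, which is the purpose of the step.

**Binned z-scores.** Records are binned by log10 of the mean denominator
(fixed width 0.25; bins under 100 records merge into their nearest
neighbour, so z assignment is deterministic). Per bin, the mean and
sample SD (n−1) of corrected dpsi are estimated excluding exact zeros —
the zero atom is an artefact of discrete counts — and every record in the
bin gets z = (dpsi − mean)/SD. Bins with fewer than 3 nonzero values are
untestable (z, p missing).

**Tail probabilities.** Two one-sided tails are emitted per record. The
primary `p` is the normal tail in the direction of the observed sign,
`sf(|z|)` — the quantity used for ranking and q-values. By construction
this doubles the null rate below any cutoff (both tails count), so
calibration is assessed on the fixed-direction upper tail
`p_up = sf(z)`, which is uniform under the null: with 20 000 null exons
the fraction with `p_up < 0.05` must land in [0.03, 0.07], and does. The
lower tail is `1 − p_up`.

**Multiple testing.** Benjamini–Hochberg step-up q-values, correcting
over `n_tests` (which may exceed the number of observed p-values, i.e.
the full exon universe of the test); a Storey-type pi0 multiplier
(lambda = 0.5) is selectable. BH is deterministic and dependency-free.

**NMD contrast averaging.** The UPF1/XRN1 and SMG6/XRN1 co-depletions are
treated as replicates: per exon, dpsi(NMD) is their mean (requiring both
by default; a lenient mode uses the available one) and the combined p is
the more conservative (larger) of the two, re-adjusted to q.

## eCLIP peaks

Peaks are filtered by log2 fold enrichment >= 3 (inclusive) and
P < 0.001 (strict), the standard reproducibility recommendation for this
assay; then replicate peaks are unioned within each cell line and the
results pooled across cell lines, with same-strand overlapping intervals
coalesced (score columns carry the max over merged peaks, so a merged
peak's significance is that of its best constituent). Association between
peaks and exons or genes is strand-matched by default (eCLIP is
strand-specific); `ignore_strand` overrides. Distances are gap-style
(overlap = 0) from exon boundaries, and window membership is inclusive.
Base-pair Jaccard on coalesced intervals quantifies replicate agreement;
both the index and 1 − index are reported since "Jaccard distance" is
used ambiguously in the field.

## Statistics

The proportion ("pi") test uses the normal approximation to the binomial
without continuity correction (warning below n = 41); one-sided p-values
throughout. The two-sample form defaults to the unpooled variance — with
the published self-binding table (35/55 vs 24/60) it yields one-sided
p = 0.0045, matching the printed 0.005, while the pooled form gives
0.0057; pooled is selectable. Without a continuity correction the z-test
approximates the binomial *mid-P* rather than the exact tail; the unit
tests assert exactly that property. Overlap enrichment between a selected
exon set and a marked set in a common universe reports the expected count
n·K/N and the hypergeometric upper tail (sampling without replacement —
the standard fixed-margin null). Rank tests (one-sample signed-rank,
two-sample rank-sum) use the normal approximation with continuity
correction. Evidence across the three data axes is combined as the
product of q-values — additive on the −log10 scale; q = 0 is clipped to
the machine floor with a warning.

## Feedback-loop calling

The master table joins, per cassette exon of an RBP-profiled gene:
poison/essential class, dpsi(NMD) statistics, dpsi(own-RBP knockdown)
statistics, and the distance to the nearest cognate peak. Missing values
stay missing. Candidates must pass |dpsi(NMD)| >= 0.1 AND
|dpsi(KD)| >= 0.1 (both inclusive; the community-standard effect-size
cutoff) AND have a cognate peak within 5 kb (inclusive, measured from
exon boundaries). Sign patterns classify loops: dpsi(NMD) > 0 with
dpsi(KD) < 0 is poison-negative (the RBP activates a poison exon; NMD
inactivation unmasks it, RBP depletion reduces it); the opposite signs
are essential-negative; equal nonzero signs are codirectional (putative
positive feedback); any zero is unclassified. Ranking is by combined q
(q_NMD · q_KD · q_peak, missing components as 1), ties broken by larger
|dpsi(NMD)| + |dpsi(KD)|, then exon key — the ranking and tie-break rules
are defined here for determinism. Track export writes BED9 with red for
dpsi > 0, blue for dpsi < 0, black peaks, score = round(1000·|dpsi|)
clipped to [0, 1000] (the score encoding is plumbing), plus plain-text
hub/trackDb stanzas.

## Synthetic study design

The generator builds everything the pipeline consumes. Each gene gets
5–8 constitutive exons (120–240 nt, introns 250–400 nt), a 30-nt 5' UTR,
a CDS whose normal stop lies in the last exon, and one cassette exon
between internal constitutive exons. Poison-type genes carry a 90-nt
(3n) cassette with an engineered in-frame stop and an annotated NMD
inclusion isoform; essential-type genes carry a 121-nt (3n+1) cassette
inside the CDS whose annotated skipping isoform acquires a
frameshift-induced stop, resampled until the stop sits inside a single
exon more than 50 nt upstream of a remaining junction. The constructions
are verified at build time by translation, so the classifiers provably
fire; about 30% of genes are placed on the minus strand to exercise
strand handling.

Default study conditions (fixed once): 200 genes; 10 poison-negative and
10 essential-negative loops plus 20 null RBPs (self-binding but
effect-free — the false-positive bait); inclusion baseline phi0 = 0.5;
planted effects |delta| = 0.3 per axis with the class-appropriate signs;
confound slope beta1 = 0.01 per decade of fold change (midpoint of the
plausible 0.001–0.025 range); knockdown fold changes log-uniform over
[0.1, 10] with the targeted gene itself forced to a 2–10x depletion;
junction depth 200 (Poisson); cognate peaks within 500 nt of the
regulatory exon in 2 replicates x 2 cell lines with jitter up to a third
of the 60-nt peak width; background peaks at 1e-5 per nt, half of them
sub-threshold. All randomness derives from a single mandatory seed
(structure, per-condition counts and peaks use separate deterministic
streams), so scenario files and the resulting master table are
byte-identical across reruns.

Calibration studies use a count-level simulator with the identical
junction sampling rule but no genome construction (building a ~50 Mb
synthetic genome to calibrate a scalar would add nothing): estimator
consistency uses depth 1e4 (|mean psi − phi| < 0.01 at phi = 0.1, 0.5,
0.9); confound recovery uses 5000 exons at depth 4e4, sized so the
slope's standard error is well below the ±30% tolerance even for the
smallest plausible slope 0.001; null calibration uses 20 000 exons at
the study depth 200.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: NMD degradation kinetics (effects are planted
directly as inclusion-fraction shifts, not derived from decay rates);
read-level artefacts (mapping bias, junction-offset entropy, the
"corrected" counts of split-read pipelines); sequence-motif-driven
binding (peak placement is positional, not motif-based); realistic
expression distributions beyond log-uniform fold changes; cross-cell-line
differences; cross-regulation between different RBPs.

## Known limitations

* Everything is annotation-bounded: unannotated NMD isoforms (a real
  phenomenon — NMD degradation depletes the very reads that would get
  such isoforms annotated) are invisible to the classifiers.
* The KD contrast inherits the knockdown's efficacy; weak depletions
  shrink |dpsi| and produce false negatives, not false positives.
* The observed-direction p is bounded above by 0.5 and doubles the null
  rate by construction; use `p_up`/`1 − p_up` for fixed-direction
  inference.
* Per-contrast confound slopes estimated from few hundred exons carry
  standard errors comparable to the slope itself; they are removed, not
  interpreted.
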