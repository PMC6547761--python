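"""Synthetic AS-NMD scenarios: annotation, genome, junction counts, peaks.

The generator builds fully specified toy datasets with the statistical
structure the analysis assumes, so that every pipeline stage is testable
without external downloads:

* gene models with a productive isoform and, for planted feedback-loop
  genes, an NMD isoform whose structure makes the exon classifiers fire by
  construction — a poison exon carries an engineered in-frame stop codon
  more than 50 nt upstream of the last junction of the inclusion isoform;
  an essential exon has a frameshifting length so that the annotated
  skipping isoform acquires a premature stop more than 50 nt upstream of a
  remaining junction;
* junction counts whose inclusion fraction ``phi`` shifts by planted,
  signed effect sizes per condition, plus an expression confound: in
  knockdown conditions ``phi`` drifts by ``beta1 * log10(FC)`` of the
  gene's fold change, mirroring the regression model the analysis fits;
* replicate eCLIP peaks near the regulatory exons of self-binding RBP
  genes (two replicates in each of two cell lines, jittered so replicate
  agreement is partial), plus uniform background peaks of which a
  configured fraction fails the enrichment filter.

Read sampling rule: an included molecule contributes two inclusion
junctions and a skipped molecule one exclusion junction, so a junction
read supports inclusion with probability ``2*phi / (1 + phi)``; this is
exactly the bookkeeping that makes ``psi = inc / (inc + 2*exc)`` an
unbiased estimator of ``phi``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import exon_key, first_stop_codon, reverse_complement
from .splice_quant import compute_psi, delta_psi

NUCLEOTIDES = np.array(list("ACGT"))
_ALL_CODONS = sorted(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)
NONSTOP_CODONS = np.array([c for c in _ALL_CODONS if c not in {"TAA", "TAG", "TGA"}])

GENE_CLASSES = ("poison_loop", "essential_loop", "codirectional", "null_rbp", "background")

CONDITION_CONTROL = "control"
CONDITION_UPF1 = "upf1_xrn1"
CONDITION_SMG6 = "smg6_xrn1"


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario (seed is mandatory)."""

    seed: int
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (5, 8)
    n_poison_loops: int = 10
    n_essential_loops: int = 10
    n_codirectional: int = 0
    n_null_rbps: int = 20
    phi0: float = 0.5
    delta_nmd: float = 0.3
    delta_kd: float = 0.3
    beta1: float = 0.01
    log10_fc_range: tuple[float, float] = (-1.0, 1.0)
    kd_target_log10_fc_range: tuple[float, float] = (-1.0, -0.3)
    depth: float = 200.0
    peak_distance: int = 500
    peak_width: int = 60
    background_peak_rate: float = 1e-5
    subthreshold_peak_fraction: float = 0.5
    cell_lines: tuple[str, ...] = ("K562", "HepG2")
    replicates: tuple[str, ...] = ("rep1", "rep2")
    exon_len_range: tuple[int, int] = (120, 240)
    intron_len_range: tuple[int, int] = (250, 400)
    intergenic_nt: int = 500
    minus_strand_fraction: float = 0.3
    n_chromosomes: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        n_special = (
            self.n_poison_loops + self.n_essential_loops
            + self.n_codirectional + self.n_null_rbps
        )
        if n_special > self.n_genes:
            raise ValueError("more special genes than genes")
        if self.exons_per_gene[0] < 5:
            raise ValueError("need at least 5 exons per gene for internal cassettes")
        if not 0.01 <= self.phi0 <= 0.99:
            raise ValueError("phi0 outside [0.01, 0.99]")


@dataclass
class Scenario:
    """A built scenario: genome + annotation + junction layout + truth."""

    config: ScenarioConfig
    genome: dict[str, str]
    gtf_lines: list[str]
    junctions: pd.DataFrame  # gene_id, chrom, start, end, strand, kind
    truth: pd.DataFrame
    rbp_by_gene: dict[str, str]

    @property
    def conditions(self) -> list[str]:
        kd = [f"kd:{g}" for g in sorted(self.rbp_by_gene)]
        return [CONDITION_CONTROL, CONDITION_UPF1, CONDITION_SMG6] + kd

    def contrast_conditions(self) -> dict[str, str]:
        """contrast_id -> KD condition (all against the shared control)."""
        out = {"nmd_upf1": CONDITION_UPF1, "nmd_smg6": CONDITION_SMG6}
        for g, rbp in sorted(self.rbp_by_gene.items()):
            out[f"kd_{rbp}"] = f"kd:{g}"
        return out


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCLEOTIDES[rng.integers(0, 4, size=n)])


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(NONSTOP_CODONS[rng.integers(0, len(NONSTOP_CODONS), size=n)])


def _spliced_to_genomic(
    exon_ivs: list[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Map a spliced interval [lo, hi) onto ordered local exon intervals."""
    out, off = [], 0
    for s, e in exon_ivs:
        length = e - s
        a, b = max(lo, off), min(hi, off + length)
        if a < b:
            out.append((s + (a - off), s + (b - off)))
        off += length
    if sum(e - s for s, e in out) != hi - lo:
        raise ValueError("spliced interval does not fit the exon chain")
    return out


@dataclass
class _GeneDesign:
    gene_id: str
    gene_class: str
    strand: str
    seq: str  # local forward (transcript-direction) gene sequence
    exon_ivs: list[tuple[int, int]]  # local forward, includes cassette
    cassette_index: int
    transcripts: list[dict]  # feature bundles in local forward coords
    junctions: list[tuple[int, int, str]]  # local forward (start, end, kind)
    phi0: float
    delta_nmd: float
    delta_kd: float
    is_rbp: bool

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def cassette_iv(self) -> tuple[int, int]:
        return self.exon_ivs[self.cassette_index]


def _signed_deltas(gene_class: str, cfg: ScenarioConfig) -> tuple[float, float]:
    if gene_class == "poison_loop":
        return cfg.delta_nmd, -cfg.delta_kd
    if gene_class == "essential_loop":
        return -cfg.delta_nmd, cfg.delta_kd
    if gene_class == "codirectional":
        return -cfg.delta_nmd, -cfg.delta_kd
    return 0.0, 0.0


def _build_gene(gene_id: str, gene_class: str, cfg: ScenarioConfig,
                rng: np.random.Generator) -> _GeneDesign:
    """Design one gene in local forward coordinates (5'->3' of the gene)."""
    lo, hi = cfg.exons_per_gene
    n_ex = int(rng.integers(lo, hi + 1))
    lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n_ex)
    lens = [int(v) for v in lens]
    k = int(rng.integers(2, n_ex - 1))  # cassette sits after exon k (1-based)
    strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
    utr5 = 30
    c_len = 121 if gene_class == "essential_loop" else 90
    p_spliced = sum(lens[:k])  # insertion point in the constitutive chain

    if gene_class == "essential_loop":
        design = _design_essential(gene_id, lens, k, c_len, utr5, rng)
    else:
        design = _design_inclusion_optional(
            gene_id, lens, k, c_len, utr5, rng,
            with_ptc=gene_class in {"poison_loop", "codirectional"},
        )
    incl_seq, incl_lens, cds_start, tx_specs = design

    # genomic layout: exon pieces separated by random introns
    pieces, off = [], 0
    for L in incl_lens:
        pieces.append(incl_seq[off : off + L])
        off += L
    parts, exon_ivs, pos = [], [], 0
    ilens = rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1,
                         size=len(pieces) - 1)
    for i, piece in enumerate(pieces):
        exon_ivs.append((pos, pos + len(piece)))
        parts.append(piece)
        if i < len(pieces) - 1:
            parts.append(_rand_nt(rng, int(ilens[i])))
            pos += len(piece) + int(ilens[i])
        else:
            pos += len(piece)
    gene_seq = "".join(parts)

    # junctions in local forward coordinates
    junctions = []
    for i in range(len(exon_ivs) - 1):
        kind = "inc1" if i == k - 1 else ("inc2" if i == k else "const")
        junctions.append((exon_ivs[i][1], exon_ivs[i + 1][0], kind))
    junctions.append((exon_ivs[k - 1][1], exon_ivs[k + 1][0], "skip"))

    # transcripts: map spliced CDS/stop to local genomic intervals
    transcripts = []
    for spec in tx_specs:
        ex = ([iv for i, iv in enumerate(exon_ivs) if i != k]
              if spec["skips_cassette"] else list(exon_ivs))
        cds_lo, cds_hi = spec["cds_spliced"]
        stop_lo, stop_hi = spec["stop_spliced"]
        transcripts.append(
            {
                "transcript_id": spec["transcript_id"],
                "biotype": spec["biotype"],
                "exons": ex,
                "cds": _spliced_to_genomic(ex, cds_lo, cds_hi),
                "stop_codon": _spliced_to_genomic(ex, stop_lo, stop_hi),
            }
        )

    d_nmd, d_kd = _signed_deltas(gene_class, cfg)
    return _GeneDesign(
        gene_id=gene_id,
        gene_class=gene_class,
        strand=strand,
        seq=gene_seq,
        exon_ivs=exon_ivs,
        cassette_index=k,
        transcripts=transcripts,
        junctions=junctions,
        phi0=cfg.phi0,
        delta_nmd=d_nmd,
        delta_kd=d_kd,
        is_rbp=gene_class in {"poison_loop", "essential_loop", "codirectional", "null_rbp"},
    )


def _design_inclusion_optional(gene_id, lens, k, c_len, utr5, rng,
                               with_ptc=False, max_tries=200):
    """Genes whose productive isoform skips the cassette (poison/null/codir).

    The constitutive chain E1..En carries the CDS with its normal stop in
    the last exon; the cassette is inserted between exons k and k+1. With
    ``with_ptc`` the cassette carries an engineered in-frame stop codon.
    """
    total = sum(lens)
    p = sum(lens[:k])
    cds_start = utr5
    last_start = total - lens[-1]
    z = last_start + 10 + ((cds_start - last_start - 10) % 3)  # stop start, in frame
    n_codons = (z - cds_start) // 3
    for attempt in range(max_tries):
        chain = (
            _rand_nt(rng, utr5)
            + _rand_codons(rng, n_codons)
            + "TAA"
            + _rand_nt(rng, total - z - 3)
        )
        assert len(chain) == total
        # cassette content
        frame = (p - cds_start) % 3
        c0 = (3 - frame) % 3  # first in-frame codon boundary inside the cassette
        cassette = _rand_codons(rng, (c_len + 2) // 3 + 1)[:c_len]
        ptc_offset = None
        if with_ptc:
            ptc_offset = c0 + 9
            cassette = cassette[:ptc_offset] + "TAA" + cassette[ptc_offset + 3 :]
        incl = chain[:p] + cassette + chain[p:]
        if with_ptc:
            if first_stop_codon(incl, cds_start) != p + ptc_offset:
                continue
        else:
            if first_stop_codon(incl, cds_start) != z + c_len:
                continue
        if first_stop_codon(chain, cds_start) != z:
            continue
        incl_lens = lens[:k] + [c_len] + lens[k:]
        tx = [
            {
                "transcript_id": f"{gene_id}.T1",
                "biotype": "protein_coding",
                "skips_cassette": True,
                "cds_spliced": (cds_start, z),
                "stop_spliced": (z, z + 3),
            }
        ]
        if with_ptc:
            ptc = p + ptc_offset
            tx.append(
                {
                    "transcript_id": f"{gene_id}.T2",
                    "biotype": "nonsense_mediated_decay",
                    "skips_cassette": False,
                    "cds_spliced": (cds_start, ptc),
                    "stop_spliced": (ptc, ptc + 3),
                }
            )
        else:
            tx.append(
                {
                    "transcript_id": f"{gene_id}.T2",
                    "biotype": "protein_coding",
                    "skips_cassette": False,
                    "cds_spliced": (cds_start, z + c_len),
                    "stop_spliced": (z + c_len, z + c_len + 3),
                }
            )
        return incl, incl_lens, cds_start, tx
    raise ValueError(f"could not realize gene {gene_id} after {max_tries} tries")


def _design_essential(gene_id, lens, k, c_len, utr5, rng, max_tries=200):
    """Genes whose productive isoform includes a frameshifting cassette.

    The inclusion chain E1..Ek C E(k+1)..En carries the CDS (normal stop in
    the last exon). Skipping the 3n+1 cassette shifts the downstream frame;
    the sequence is resampled until the first shifted-frame stop falls
    within a single exon more than 50 nt upstream of a remaining junction.
    """
    incl_lens = lens[:k] + [c_len] + lens[k:]
    total = sum(incl_lens)
    p = sum(lens[:k])
    cds_start = utr5
    last_start = total - lens[-1]
    z = last_start + 10 + ((cds_start - last_start - 10) % 3)
    n_codons = (z - cds_start) // 3
    skip_cum = np.cumsum(lens)
    skip_junctions = [int(c) for c in skip_cum[:-1]]
    for attempt in range(max_tries):
        incl = (
            _rand_nt(rng, utr5)
            + _rand_codons(rng, n_codons)
            + "TAA"
            + _rand_nt(rng, total - z - 3)
        )
        if first_stop_codon(incl, cds_start) != z:
            continue
        skip = incl[:p] + incl[p + c_len :]
        t = first_stop_codon(skip, cds_start)
        if t is None or t < p - 2:
            continue
        if not any(j - (t + 3) > 50 for j in skip_junctions):
            continue
        # the premature stop must sit inside a single exon of the skip chain
        starts = np.concatenate([[0], skip_cum[:-1]])
        in_one = any(s <= t and t + 3 <= e for s, e in zip(starts, skip_cum))
        if not in_one:
            continue
        tx = [
            {
                "transcript_id": f"{gene_id}.T1",
                "biotype": "protein_coding",
                "skips_cassette": False,
                "cds_spliced": (cds_start, z),
                "stop_spliced": (z, z + 3),
            },
            {
                "transcript_id": f"{gene_id}.T2",
                "biotype": "nonsense_mediated_decay",
                "skips_cassette": True,
                "cds_spliced": (cds_start, t),
                "stop_spliced": (t, t + 3),
            },
        ]
        return incl, incl_lens, cds_start, tx
    raise ValueError(f"could not realize gene {gene_id} after {max_tries} tries")


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def _flip(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return length - iv[1], length - iv[0]


def _gtf_attrs(gene_id: str, transcript_id: str | None = None,
               biotype: str | None = None) -> str:
    out = f'gene_id "{gene_id}"; gene_name "{gene_id}";'
    if transcript_id:
        out += f' transcript_id "{transcript_id}";'
    if biotype:
        out += f' transcript_type "{biotype}";'
    return out


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Deterministically build genome, annotation, junction layout and truth."""
    rng = np.random.default_rng([config.seed, 0])
    classes = (
        ["poison_loop"] * config.n_poison_loops
        + ["essential_loop"] * config.n_essential_loops
        + ["codirectional"] * config.n_codirectional
        + ["null_rbp"] * config.n_null_rbps
    )
    classes += ["background"] * (config.n_genes - len(classes))
    designs = []
    for i, gene_class in enumerate(classes):
        gene_id = f"G{i + 1:04d}"
        designs.append(_build_gene(gene_id, gene_class, config, rng))

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_names}
    gtf_lines: list[str] = []
    junction_rows = []
    truth_rows = []
    rbp_by_gene: dict[str, str] = {}

    for i, d in enumerate(designs):
        chrom = chrom_names[i % len(chrom_names)]
        pad = _rand_nt(rng, config.intergenic_nt)
        chrom_parts[chrom].append(pad)
        chrom_pos[chrom] += len(pad)
        offset = chrom_pos[chrom]
        block = d.seq if d.strand == "+" else reverse_complement(d.seq)
        chrom_parts[chrom].append(block)
        chrom_pos[chrom] += len(block)

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            s, e = iv if d.strand == "+" else _flip(iv, d.length)
            return offset + s, offset + e

        g_start, g_end = offset, offset + d.length
        gtf_lines.append(
            "\t".join(
                [chrom, "synthetic", "gene", str(g_start + 1), str(g_end), ".",
                 d.strand, ".", _gtf_attrs(d.gene_id)]
            )
        )
        for t in d.transcripts:
            ex = sorted(to_genomic(iv) for iv in t["exons"])
            cds = sorted(to_genomic(iv) for iv in t["cds"])
            stop = sorted(to_genomic(iv) for iv in t["stop_codon"])
            attrs = _gtf_attrs(d.gene_id, t["transcript_id"], t["biotype"])
            gtf_lines.append(
                "\t".join(
                    [chrom, "synthetic", "transcript", str(ex[0][0] + 1),
                     str(ex[-1][1]), ".", d.strand, ".", attrs]
                )
            )
            for kind, ivs in (("exon", ex), ("CDS", cds), ("stop_codon", stop)):
                for s, e in ivs:
                    gtf_lines.append(
                        "\t".join(
                            [chrom, "synthetic", kind, str(s + 1), str(e), ".",
                             d.strand, ".", attrs]
                        )
                    )
        for s, e, kind in d.junctions:
            gs, ge = to_genomic((s, e))
            junction_rows.append(
                {"gene_id": d.gene_id, "chrom": chrom, "start": gs, "end": ge,
                 "strand": d.strand, "kind": kind}
            )
        cs, ce = to_genomic(d.cassette_iv)
        rbp = f"RBP_{d.gene_id}" if d.is_rbp else ""
        if d.is_rbp:
            rbp_by_gene[d.gene_id] = rbp
        truth_rows.append(
            {
                "gene_id": d.gene_id,
                "chrom": chrom,
                "strand": d.strand,
                "gene_start": g_start,
                "gene_end": g_end,
                "gene_class": d.gene_class,
                "is_rbp": d.is_rbp,
                "rbp": rbp,
                "exon_id": exon_key(chrom, cs, ce, d.strand),
                "exon_start": cs,
                "exon_end": ce,
                "phi0": d.phi0,
                "delta_nmd": d.delta_nmd,
                "delta_kd": d.delta_kd,
                "self_binding": d.is_rbp,
            }
        )
    for chrom in chrom_names:
        chrom_parts[chrom].append(_rand_nt(rng, config.intergenic_nt))
    genome = {c: "".join(chrom_parts[c]) for c in chrom_names}
    return Scenario(
        config=config,
        genome=genome,
        gtf_lines=gtf_lines,
        junctions=pd.DataFrame(junction_rows),
        truth=pd.DataFrame(truth_rows),
        rbp_by_gene=rbp_by_gene,
    )


# ---------------------------------------------------------------------------
# junction-count simulation
# ---------------------------------------------------------------------------

def sample_inclusion_counts(
    phi: float, total: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Split ``total`` junction reads of a cassette exon into (inc1, inc2, exc).

    Each read supports inclusion with probability 2*phi/(1+phi); inclusion
    reads split evenly between the two flanking junctions.
    """
    inc = int(rng.binomial(total, 2 * phi / (1 + phi))) if total else 0
    inc1 = int(rng.binomial(inc, 0.5)) if inc else 0
    return inc1, inc - inc1, total - inc


def _condition_effects(scenario: Scenario, condition: str) -> pd.Series:
    t = scenario.truth.set_index("gene_id")
    if condition in (CONDITION_UPF1, CONDITION_SMG6):
        return t["delta_nmd"]
    if condition.startswith("kd:"):
        gene = condition.split(":", 1)[1]
        if gene not in t.index:
            raise ValueError(f"unknown KD gene {gene!r}")
        delta = pd.Series(0.0, index=t.index)
        delta.loc[gene] = t.loc[gene, "delta_kd"]
        return delta
    if condition == CONDITION_CONTROL:
        return pd.Series(0.0, index=t.index)
    raise ValueError(f"unknown condition {condition!r}")


def simulate_junction_counts(
    scenario: Scenario, condition: str, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a junction-count table for one condition.

    Per gene a fold change FC is sampled (1 in the control; log-uniform in
    ``log10_fc_range`` otherwise; the knocked-down gene itself is forced
    into ``kd_target_log10_fc_range``), the cassette inclusion fraction is
    ``clip(phi0 + delta + beta1*log10(FC), 0.01, 0.99)``, total cassette
    junction depth is Poisson(depth * FC), and constitutive junctions get
    independent Poisson(depth * FC) counts.
    """
    cfg = scenario.config
    if rng is None:
        idx = scenario.conditions.index(condition)
        rng = np.random.default_rng([cfg.seed, 1, idx])
    deltas = _condition_effects(scenario, condition)
    kd_gene = condition.split(":", 1)[1] if condition.startswith("kd:") else None
    rows = []
    for gene_id, grp in scenario.junctions.groupby("gene_id", sort=True):
        if condition == CONDITION_CONTROL:
            log10_fc = 0.0
        elif gene_id == kd_gene:
            log10_fc = float(rng.uniform(*cfg.kd_target_log10_fc_range))
        else:
            log10_fc = float(rng.uniform(*cfg.log10_fc_range))
        fc = 10.0 ** log10_fc
        phi = float(np.clip(cfg.phi0 + deltas.loc[gene_id] + cfg.beta1 * log10_fc,
                            0.01, 0.99))
        total = int(rng.poisson(cfg.depth * fc))
        inc1, inc2, exc = sample_inclusion_counts(phi, total, rng)
        by_kind = {"inc1": inc1, "inc2": inc2, "skip": exc}
        for r in grp.itertuples(index=False):
            count = by_kind.get(r.kind)
            if count is None:
                count = int(rng.poisson(cfg.depth * fc))
            rows.append(
                {"chrom": r.chrom, "intron_start": int(r.start),
                 "intron_end": int(r.end), "strand": r.strand, "count": count}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["chrom", "intron_start", "intron_end", "strand"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# eCLIP peak simulation
# ---------------------------------------------------------------------------

def simulate_peaks(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Raw (pre-filter) replicate peaks for every RBP in the scenario.

    Self-binding genes receive a cognate peak near their regulatory exon in
    every replicate of both cell lines (replicate positions jittered by up
    to a third of the peak width); background peaks land uniformly at
    ``background_peak_rate`` per nucleotide, a configured fraction of them
    with sub-threshold scores.
    """
    cfg = scenario.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    genome_len = {c: len(s) for c, s in scenario.genome.items()}
    chroms = sorted(genome_len)
    lens = np.array([genome_len[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    truth = scenario.truth.set_index("gene_id")
    rows = []
    for gene_id in sorted(scenario.rbp_by_gene):
        info = truth.loc[gene_id]
        rbp = scenario.rbp_by_gene[gene_id]
        w = cfg.peak_width
        max_gap = max(1, cfg.peak_distance - w)
        gap = int(rng.integers(0, max_gap + 1))
        if info["strand"] == "+":
            anchor = int(info["exon_end"]) + gap
        else:
            anchor = int(info["exon_start"]) - gap - w
        for cell in cfg.cell_lines:
            for rep in cfg.replicates:
                jitter = int(rng.integers(-(w // 3), w // 3 + 1))
                s = max(0, anchor + jitter)
                if info["self_binding"]:
                    rows.append(
                        {"rbp": rbp, "cell_line": cell, "replicate": rep,
                         "chrom": info["chrom"], "start": s, "end": s + w,
                         "strand": info["strand"],
                         "log2_enrichment": float(rng.uniform(3.5, 8.0)),
                         "neg_log10_p": float(rng.uniform(4.0, 10.0)),
                         "neg_log10_q": float(rng.uniform(3.0, 8.0)),
                         "kind": "cognate"}
                    )
                n_bg = int(rng.poisson(cfg.background_peak_rate * lens.sum()))
                for _ in range(n_bg):
                    chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                    start = int(rng.integers(0, genome_len[chrom] - w))
                    sub = rng.random() < cfg.subthreshold_peak_fraction
                    rows.append(
                        {"rbp": rbp, "cell_line": cell, "replicate": rep,
                         "chrom": chrom, "start": start, "end": start + w,
                         "strand": "+" if rng.random() < 0.5 else "-",
                         "log2_enrichment": float(rng.uniform(0.5, 2.9)) if sub
                         else float(rng.uniform(3.5, 8.0)),
                         "neg_log10_p": float(rng.uniform(0.5, 2.9)) if sub
                         else float(rng.uniform(4.0, 10.0)),
                         "neg_log10_q": float(rng.uniform(0.2, 2.0)) if sub
                         else float(rng.uniform(3.0, 8.0)),
                         "kind": "background"}
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count-level simulators (calibration-scale studies without a genome)
# ---------------------------------------------------------------------------

def simulate_psi_table(
    n_exons: int,
    depth: float,
    phi0: float,
    beta1: float,
    log10_fc_range: tuple[float, float],
    rng: np.random.Generator,
    delta: np.ndarray | float = 0.0,
) -> pd.DataFrame:
    """Direct KD-vs-control inc/exc draws for ``n_exons`` cassette exons.

    Uses the identical junction sampling rule as the full scenario but
    skips genome/annotation construction; suited to calibration studies at
    sizes where building sequences would be pointless. Returns a frame with
    the columns `quantify_exons` produces.
    """
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (n_exons,))
    log10_fc = rng.uniform(*log10_fc_range, size=n_exons)
    rows = []
    for i in range(n_exons):
        phi_c = float(np.clip(phi0, 0.01, 0.99))
        phi_k = float(np.clip(phi0 + delta[i] + beta1 * log10_fc[i], 0.01, 0.99))
        t_c = int(rng.poisson(depth))
        t_k = int(rng.poisson(depth * 10.0 ** log10_fc[i]))
        i1c, i2c, ec = sample_inclusion_counts(phi_c, t_c, rng)
        i1k, i2k, ek = sample_inclusion_counts(phi_k, t_k, rng)
        inc_c, inc_k = i1c + i2c, i1k + i2k
        den_c, den_k = inc_c + 2 * ec, inc_k + 2 * ek
        psi_c = compute_psi(inc_c, ec)
        psi_k = compute_psi(inc_k, ek)
        rows.append(
            {
                "exon_id": f"E{i + 1:06d}",
                "gene_id": f"G{i + 1:06d}",
                "inc_kd": inc_k, "exc_kd": ek, "inc_ctrl": inc_c, "exc_ctrl": ec,
                "psi_kd": psi_k, "psi_ctrl": psi_c,
                "dpsi_raw": delta_psi(psi_k, psi_c),
                "log10_fc": np.log10(den_k / den_c) if den_k and den_c else np.nan,
                "mean_count": (den_k + den_c) / 2.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writing a scenario to disk
# ---------------------------------------------------------------------------

def write_scenario(scenario: Scenario, out_dir: str, force: bool = False) -> dict:
    """Write GTF, FASTA, per-sample junction TSVs, peaks, truth and manifest."""
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    os.makedirs(out_dir, exist_ok=True)
    counts_dir = os.path.join(out_dir, "counts")
    peaks_dir = os.path.join(out_dir, "peaks")
    os.makedirs(counts_dir, exist_ok=True)
    os.makedirs(peaks_dir, exist_ok=True)
    cfg = scenario.config

    with open(os.path.join(out_dir, "annotation.gtf"), "w") as fh:
        fh.write("\n".join(scenario.gtf_lines) + "\n")
    with open(os.path.join(out_dir, "genome.fa"), "w") as fh:
        for chrom in sorted(scenario.genome):
            fh.write(f">{chrom}\n")
            seq = scenario.genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    sheet_rows = []
    for condition in scenario.conditions:
        sample_id = condition.replace(":", "_")
        table = simulate_junction_counts(scenario, condition)
        table.to_csv(os.path.join(counts_dir, f"{sample_id}.tsv"), sep="\t", index=False)
        if condition == CONDITION_CONTROL:
            role, contrast = "control", ""
        elif condition.startswith("kd:"):
            gene = condition.split(":", 1)[1]
            role, contrast = "kd", f"kd_{scenario.rbp_by_gene[gene]}"
        else:
            role, contrast = "kd", f"nmd_{condition.split('_')[0]}"
        sheet_rows.append(
            {"sample_id": sample_id, "condition": condition, "role": role,
             "contrast_id": contrast}
        )
    pd.DataFrame(sheet_rows).to_csv(
        os.path.join(out_dir, "sample_sheet.tsv"), sep="\t", index=False
    )

    all_peaks = simulate_peaks(scenario)
    manifest_rows = []
    for (rbp, cell, rep), grp in all_peaks.groupby(["rbp", "cell_line", "replicate"],
                                                   sort=True):
        fname = f"{rbp}_{cell}_{rep}.narrowPeak"
        np_df = pd.DataFrame(
            {
                0: grp["chrom"], 1: grp["start"], 2: grp["end"],
                3: [f"{rbp}_{i}" for i in range(len(grp))],
                4: 0, 5: grp["strand"],
                6: grp["log2_enrichment"].round(4),
                7: grp["neg_log10_p"].round(4),
                8: grp["neg_log10_q"].round(4),
                9: -1,
            }
        )
        np_df.to_csv(os.path.join(peaks_dir, fname), sep="\t", index=False, header=False)
        manifest_rows.append(
            {"rbp": rbp, "cell_line": cell, "replicate": rep,
             "path": os.path.join("peaks", fname)}
        )
    pd.DataFrame(manifest_rows).to_csv(
        os.path.join(out_dir, "peaks_manifest.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        sorted(scenario.rbp_by_gene.items(), key=lambda kv: kv[1]),
        columns=["gene_id", "rbp"],
    )[["rbp", "gene_id"]].to_csv(
        os.path.join(out_dir, "rbp_map.tsv"), sep="\t", index=False
    )
    scenario.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    manifest = {"config": dataclasses.asdict(cfg), "seed": cfg.seed,
                "n_samples": len(sheet_rows), "n_peak_files": len(manifest_rows)}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
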