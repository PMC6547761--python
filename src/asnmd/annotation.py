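"""Transcript annotation parsing and AS-NMD exon classification.

Coordinates are 0-based half-open everywhere inside the package. GTF input
(1-based closed, GENCODE attribute dialect) is converted on read; BED output
is native 0-based half-open.

The classifiers implement the standard operational definitions used in
AS-NMD work on GENCODE-style annotations:

* a transcript is an NMD target if its stop codon ends strictly more than
  50 nt upstream (in spliced-transcript nucleotides) of the last exon-exon
  junction (the "50-nt rule"); an explicit ``nonsense_mediated_decay``
  biotype tag takes precedence when present;
* an exon [x, y) is a *cassette* exon if introns [a, x), [y, b) and the
  skipping intron [a, b) are all annotated in at least one transcript of
  the gene;
* a cassette exon is *poison* if it contains (overlaps by >= 1 nt) the stop
  codon of an annotated NMD transcript;
* an exon is *essential* in a coding transcript if splicing its sequence
  out of the transcript and translating from the original start codon puts
  the first in-frame stop strictly more than 50 nt upstream of at least one
  remaining exon-exon junction.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

NMD_BIOTYPE = "nonsense_mediated_decay"
PTC_RULE_NT = 50
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Uppercase nucleotide access by (chrom, start, end, strand).

    Minus-strand requests return the reverse complement. Backed either by a
    faidx-indexed FASTA file or by an in-memory mapping.
    """

    def __init__(self, accessor: Mapping[str, str] | Fasta):
        self._seqs = accessor

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        return cls(Fasta(str(path), as_raw=True, sequence_always_upper=True))

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "GenomeSequence":
        return cls({k: v.upper() for k, v in seqs.items()})

    def __contains__(self, chrom: str) -> bool:
        if isinstance(self._seqs, dict):
            return chrom in self._seqs
        return chrom in self._seqs.keys()

    @property
    def chroms(self) -> list[str]:
        if isinstance(self._seqs, dict):
            return sorted(self._seqs)
        return sorted(self._seqs.keys())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        if not 0 <= start <= end:
            raise ValueError(f"bad interval [{start}, {end})")
        seq = str(self._seqs[chrom][start:end]).upper()
        return reverse_complement(seq) if strand == "-" else seq


@dataclass
class TranscriptModel:
    """One transcript isoform: exon/CDS structure on the genome.

    ``exons`` and ``cds`` are lists of 0-based half-open genomic intervals,
    ordered 5'->3' in transcript orientation (decreasing genomic coordinate
    on the minus strand). ``stop_codon`` holds the genomic interval(s) of
    the annotated stop codon, which may straddle a junction.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    stop_codon: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    nmd: bool | None = None
    nmd_source: str | None = None

    def __post_init__(self) -> None:
        rev = self.strand == "-"
        self.exons = sorted(self.exons, key=lambda iv: iv[0], reverse=rev)
        self.cds = sorted(self.cds, key=lambda iv: iv[0], reverse=rev)
        self.stop_codon = sorted(self.stop_codon, key=lambda iv: iv[0], reverse=rev)
        asc = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(asc, asc[1:]):
            if e1 > s2:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {(s1, e1)} and {(s2, e2)}"
                )

    # -- structure -------------------------------------------------------
    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic-ascending gaps between consecutive exons."""
        asc = self.exons_genomic
        return [(e1, s2) for (_, e1), (s2, _) in zip(asc, asc[1:])]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junction_positions(self) -> list[int]:
        """Exon-exon junction positions in spliced-transcript coordinates."""
        out, pos = [], 0
        for s, e in self.exons[:-1]:
            pos += e - s
            out.append(pos)
        return out

    def genomic_to_spliced(self, pos: int) -> int:
        """Spliced coordinate of a genomic base that lies inside an exon."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - pos - 1)
            offset += e - s
        raise ValueError(f"genomic position {pos} not exonic in {self.transcript_id}")

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        return "".join(
            genome.fetch(self.chrom, s, e, self.strand) for s, e in self.exons
        )

    def cds_start_spliced(self) -> int:
        """Spliced coordinate of the first base of the start codon."""
        if not self.cds:
            raise ValueError(f"{self.transcript_id} has no CDS")
        s, e = self.cds[0]
        return self.genomic_to_spliced(s if self.strand == "+" else e - 1)

    def stop_end_spliced(self, genome: GenomeSequence | None = None) -> int:
        """Spliced coordinate one past the stop codon (or CDS end fallback)."""
        if self.stop_codon:
            last = [self.genomic_to_spliced(p) for s, e in self.stop_codon for p in (s, e - 1)]
            return max(last) + 1
        if not self.cds:
            raise ValueError(f"{self.transcript_id} has no CDS")
        if genome is not None:
            start = self.cds_start_spliced()
            seq = self.spliced_sequence(genome)
            stop = first_stop_codon(seq, start)
            if stop is not None:
                return stop + 3
        warnings.warn(
            f"{self.transcript_id}: no stop codon found; applying 50-nt rule to CDS end"
        )
        s, e = self.cds[-1]
        return self.genomic_to_spliced(e - 1 if self.strand == "+" else s) + 1


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for t in self.transcripts for s, _ in t.exons]
        ends = [e for t in self.transcripts for _, e in t.exons]
        return (min(starts), max(ends)) if starts else (0, 0)

    @property
    def gwn(self) -> bool:
        return any(t.nmd for t in self.transcripts)

    def all_exons(self) -> list[tuple[int, int]]:
        return sorted({iv for t in self.transcripts for iv in t.exons})

    def all_introns(self) -> set[tuple[int, int]]:
        return {iv for t in self.transcripts for iv in t.introns()}


def first_stop_codon(seq: str, start: int) -> int | None:
    """Position of the first in-frame stop codon at/after ``start``.

    Codons containing N (or any non-ACGT base) are treated as non-stop.
    """
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


# ---------------------------------------------------------------------------
# transcript-level classification
# ---------------------------------------------------------------------------

def label_nmd(transcript: TranscriptModel, genome: GenomeSequence | None = None) -> bool:
    """Apply the 50-nt rule (annotation biotype tag takes precedence).

    Sets ``transcript.nmd`` / ``transcript.nmd_source`` and returns the label.
    Transcripts without CDS are labelled False with source ``no_cds``.
    """
    if transcript.biotype == NMD_BIOTYPE:
        transcript.nmd, transcript.nmd_source = True, "tag"
        return True
    if not transcript.cds:
        transcript.nmd, transcript.nmd_source = False, "no_cds"
        return False
    junctions = transcript.junction_positions()
    if not junctions:
        transcript.nmd, transcript.nmd_source = False, "rule"
        return False
    stop_end = transcript.stop_end_spliced(genome)
    transcript.nmd = (junctions[-1] - stop_end) > PTC_RULE_NT
    transcript.nmd_source = "rule"
    return transcript.nmd


def classify_gwn(gene: GeneModel) -> str:
    """GWN iff the gene has >= 1 NMD transcript isoform."""
    if not gene.transcripts:
        warnings.warn(f"{gene.gene_id}: no transcripts; classified GWO")
        return "GWO"
    return "GWN" if gene.gwn else "GWO"


# ---------------------------------------------------------------------------
# exon-level classification
# ---------------------------------------------------------------------------

def find_cassette_exons(gene: GeneModel) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Map each cassette exon [x, y) to its list of (a, b) skipping contexts.

    Exon [x, y) qualifies if introns [a, x), [y, b) and [a, b) are all
    annotated in transcripts of the gene.
    """
    introns = gene.all_introns()
    by_end: dict[int, list[int]] = defaultdict(list)
    by_start: dict[int, list[int]] = defaultdict(list)
    for a, b in introns:
        by_end[b].append(a)
        by_start[a].append(b)
    out: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for x, y in gene.all_exons():
        contexts = sorted(
            (a, b)
            for a in by_end.get(x, [])
            for b in by_start.get(y, [])
            if a < x and b > y and (a, b) in introns
        )
        if contexts:
            out[(x, y)] = contexts
    return out


def classify_poison(exon: tuple[int, int], gene: GeneModel) -> bool:
    """True iff an NMD transcript's stop codon overlaps the exon by >= 1 nt."""
    x, y = exon
    for t in gene.transcripts:
        if not t.nmd:
            continue
        for s, e in t.stop_codon:
            if s < y and e > x:
                return True
    return False


def classify_essential(
    exon: tuple[int, int], transcript: TranscriptModel, genome: GenomeSequence
) -> bool:
    """Does splicing this exon out of the transcript create an NMD target?

    The exon's nucleotides are removed, the remaining exons are spliced, and
    translation proceeds from the original start codon. The transcript is
    ruined (exon "essential") iff the first in-frame stop ends strictly more
    than 50 nt upstream of at least one remaining exon-exon junction.
    """
    if exon not in transcript.exons:
        raise ValueError(f"exon {exon} not in transcript {transcript.transcript_id}")
    if not transcript.cds:
        raise ValueError(f"{transcript.transcript_id} has no CDS")
    idx = transcript.exons.index(exon)
    kept = [iv for i, iv in enumerate(transcript.exons) if i != idx]
    if len(kept) < 2:
        return False
    modified = TranscriptModel(
        transcript_id=transcript.transcript_id + ":skip",
        gene_id=transcript.gene_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        exons=kept,
    )
    start_genomic = (
        transcript.cds[0][0] if transcript.strand == "+" else transcript.cds[0][1] - 1
    )
    try:
        start = modified.genomic_to_spliced(start_genomic)
    except ValueError as err:
        raise ValueError(
            f"exon {exon} removal deletes the start codon of {transcript.transcript_id}"
        ) from err
    seq = modified.spliced_sequence(genome)
    stop = first_stop_codon(seq, start)
    if stop is None:
        warnings.warn(
            f"{transcript.transcript_id}: no in-frame stop after removing exon {exon}"
        )
        return False
    stop_end = stop + 3
    return any(j - stop_end > PTC_RULE_NT for j in modified.junction_positions())


def frame_class(exon: tuple[int, int]) -> str:
    """Length mod 3: frame-preserving (3n) vs frameshifting (3n+1, 3n+2)."""
    r = (exon[1] - exon[0]) % 3
    return {0: "3n", 1: "3n+1", 2: "3n+2"}[r]


def relative_position(exon: tuple[int, int], transcript: TranscriptModel) -> float:
    """Exon midpoint in the transcript mapped linearly to [0, 100] percent.

    Midpoints are taken in spliced-transcript coordinates; the 5'-most exon
    maps to 0% and the 3'-most to 100%. Single-exon transcripts: 50%.
    """
    if exon not in transcript.exons:
        raise ValueError(f"exon {exon} not in transcript {transcript.transcript_id}")
    if len(transcript.exons) == 1:
        return 50.0
    mids, pos = [], 0.0
    for s, e in transcript.exons:
        mids.append(pos + (e - s) / 2.0)
        pos += e - s
    m = mids[transcript.exons.index(exon)]
    return 100.0 * (m - mids[0]) / (mids[-1] - mids[0])


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

def _validate_gtf(gtf_path: str) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as err:
                raise ValueError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from err
            if start < 1 or end < start:
                raise ValueError(f"malformed GTF line {lineno}: bad interval {start}-{end}")
            if 'gene_id "' not in fields[8]:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id attribute")


def parse_annotation(gtf_path: str, fasta_path: str | None = None) -> list[GeneModel]:
    """Read a GENCODE-dialect GTF (+ optional FASTA) into GeneModels.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Transcripts are NMD-labelled on the way out (tag first, 50-nt rule
    otherwise). Genes are returned sorted by (chrom, span start, gene_id).
    """
    _validate_gtf(gtf_path)
    genome = GenomeSequence.from_fasta(fasta_path) if fasta_path else None
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for tf in db.children(gf, featuretype="transcript", order_by="start"):
            exons = [
                (f.start - 1, f.end)
                for f in db.children(tf, featuretype="exon", order_by="start")
            ]
            cds = [
                (f.start - 1, f.end)
                for f in db.children(tf, featuretype="CDS", order_by="start")
            ]
            stops = [
                (f.start - 1, f.end)
                for f in db.children(tf, featuretype="stop_codon", order_by="start")
            ]
            if genome is not None and gf.seqid not in genome:
                raise ValueError(
                    f"transcript {tf.id}: chromosome {gf.seqid!r} absent from FASTA"
                )
            biotype = tf.attributes.get("transcript_type", ["protein_coding"])[0]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tf.attributes["transcript_id"][0],
                    gene_id=gf.attributes["gene_id"][0],
                    chrom=gf.seqid,
                    strand=tf.strand,
                    exons=exons,
                    cds=cds,
                    stop_codon=stops,
                    biotype=biotype,
                )
            )
        gene = GeneModel(
            gene_id=gf.attributes["gene_id"][0],
            chrom=gf.seqid,
            strand=gf.strand,
            transcripts=sorted(transcripts, key=lambda t: t.transcript_id),
        )
        for t in gene.transcripts:
            label_nmd(t, genome)
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# gene -> exon classification table
# ---------------------------------------------------------------------------

def exon_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def _exon_internal_to_cds(exon: tuple[int, int], t: TranscriptModel) -> bool:
    """Exon fully inside the CDS and not carrying the start or stop codon."""
    if not t.cds:
        return False
    cds_lo = min(s for s, _ in t.cds)
    cds_hi = max(e for _, e in t.cds)
    x, y = exon
    if not (cds_lo <= x and y <= cds_hi):
        return False
    idx = t.exons.index(exon)
    return 0 < idx < len(t.exons) - 1


def annotate_exons(genes: Iterable[GeneModel], genome: GenomeSequence) -> pd.DataFrame:
    """Classify every distinct exon of every gene.

    Returns one row per exon: cassette status with the tightest (a, b)
    skipping context, poison and essential flags, frame class, and relative
    position (computed in the longest transcript containing the exon).
    """
    rows = []
    for gene in genes:
        cassette = find_cassette_exons(gene)
        for x, y in gene.all_exons():
            is_cassette = (x, y) in cassette
            a, b = (np.nan, np.nan)
            if is_cassette:
                a, b = min(cassette[(x, y)], key=lambda ab: (ab[1] - ab[0]))
            poison = is_cassette and classify_poison((x, y), gene)
            essential = False
            for t in gene.transcripts:
                if (x, y) in t.exons and _exon_internal_to_cds((x, y), t):
                    if classify_essential((x, y), t, genome):
                        essential = True
                        break
            hosts = [t for t in gene.transcripts if (x, y) in t.exons]
            host = max(hosts, key=lambda t: (t.spliced_length, t.transcript_id))
            rows.append(
                {
                    "exon_id": exon_key(gene.chrom, x, y, gene.strand),
                    "chrom": gene.chrom,
                    "start": x,
                    "end": y,
                    "strand": gene.strand,
                    "gene_id": gene.gene_id,
                    "gwn": gene.gwn,
                    "cassette": is_cassette,
                    "a": a,
                    "b": b,
                    "poison": poison,
                    "essential": essential,
                    "frame_class": frame_class((x, y)),
                    "relative_position_pct": relative_position((x, y), host),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "start", "end"], ignore_index=True) if len(df) else df


def transcript_nmd_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-transcript NMD labels with the source that fired (tag vs rule)."""
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": g.gene_id,
            "biotype": t.biotype,
            "nmd": bool(t.nmd),
            "nmd_source": t.nmd_source,
            "gene_class": classify_gwn(g),
        }
        for g in genes
        for t in g.transcripts
    ]
    return pd.DataFrame(rows)
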