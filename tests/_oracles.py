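"""Independent brute-force oracles used to validate the classifiers.

These deliberately re-derive results by exhaustive enumeration or direct
string manipulation, without sharing code paths with the package.
"""

from __future__ import annotations

import math

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def cassette_oracle(exons: list[tuple[int, int]], introns: set[tuple[int, int]]):
    """Cassette exons by exhaustive enumeration over all intron triples."""
    out = set()
    for x, y in exons:
        for i1 in introns:
            for i2 in introns:
                for i3 in introns:
                    if (
                        i1[1] == x
                        and i2[0] == y
                        and i3 == (i1[0], i2[1])
                        and i1[0] < x
                        and i2[1] > y
                    ):
                        out.add((x, y))
    return out


def essential_oracle(
    exon: tuple[int, int],
    exons: list[tuple[int, int]],
    cds_start_genomic: int,
    strand: str,
    chrom_seq: str,
) -> bool:
    """Direct re-derivation: delete the exon, splice, translate, measure.

    Works on a per-base coordinate list so the mapping logic is independent
    of the package's interval arithmetic.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    kept = [iv for iv in exons if iv != exon]
    bases: list[tuple[int, str]] = []
    for s, e in sorted(kept):
        for pos in range(s, e):
            bases.append((pos, chrom_seq[pos]))
    if strand == "-":
        bases = [(pos, comp[nt]) for pos, nt in reversed(bases)]
    coords = [pos for pos, _ in bases]
    seq = "".join(nt for _, nt in bases)
    if cds_start_genomic not in coords:
        raise ValueError("start codon removed")
    start = coords.index(cds_start_genomic)
    stop = None
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOPS:
            stop = i
            break
    if stop is None:
        return False
    # junction positions: spliced index where the genomic coordinate jumps
    junctions = [
        i + 1
        for i in range(len(coords) - 1)
        if abs(coords[i + 1] - coords[i]) != 1
    ]
    return any(j - (stop + 3) > 50 for j in junctions)


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for the hypergeometric by direct summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


def random_gene_structure(rng: np.random.Generator):
    """Random exon/intron structure: several transcripts over a shared exon grid."""
    n_sites = int(rng.integers(4, 9))
    bounds = np.sort(rng.choice(np.arange(100, 5000, 50), size=2 * n_sites, replace=False))
    exon_pool = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_sites)]
    transcripts = []
    for _ in range(int(rng.integers(2, 5))):
        keep = [iv for iv in exon_pool if rng.random() < 0.7]
        if len(keep) >= 2:
            transcripts.append(keep)
    if not transcripts:
        transcripts = [exon_pool]
    introns = set()
    for tx in transcripts:
        for (s1, e1), (s2, e2) in zip(tx, tx[1:]):
            introns.add((e1, s2))
    exons = sorted({iv for tx in transcripts for iv in tx})
    return exons, introns, transcripts


def random_coding_transcript(rng: np.random.Generator):
    """A random multi-exon coding transcript with random sequence.

    Returns (exons ascending, strand, cds_start_genomic, chrom_seq,
    internal exon candidates). Stops occur naturally in the random
    sequence, so essentiality of a removed exon varies.
    """
    n_ex = int(rng.integers(3, 7))
    lens = rng.integers(30, 200, size=n_ex)
    gaps = rng.integers(50, 300, size=n_ex)
    exons, pos = [], int(gaps[0])
    for L, g in zip(lens, gaps):
        exons.append((pos, pos + int(L)))
        pos += int(L) + int(g)
    chrom_len = pos + 100
    chrom_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=chrom_len))
    strand = "+" if rng.random() < 0.5 else "-"
    ordered = exons if strand == "+" else exons[::-1]
    # start codon a short way into the first exon (transcript orientation)
    s, e = ordered[0]
    offset = int(rng.integers(0, min(20, e - s - 3)))
    cds_start = s + offset if strand == "+" else e - 1 - offset
    internal = ordered[1:-1]
    return exons, strand, cds_start, chrom_seq, internal
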