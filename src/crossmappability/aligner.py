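"""All-placements k-mer alignment under a Hamming-distance budget.

A k-mer "maps" at every genomic position, on either strand, where the
Hamming distance between the k-mer (forward on '+', reverse complement
on '-') and the genome substring is at most ``max_mismatches``. No
indels. An N on either side never matches anything, including another N.
A hit's coordinate is always its leftmost genomic position.

The production path (:func:`align_all`) uses pigeonhole seeding: a k-mer
within m mismatches of a genome window must contain at least one of m+1
disjoint blocks exactly; each block is looked up in an exact q-gram hash
of the genome and candidates are verified by Hamming count. The naive
full scan (:func:`brute_force_oracle`) is kept as an independent test
oracle and is never used by the production path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome import GenomeSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One placement of a k-mer: (chrom, leftmost 0-based start, strand, mismatches)."""

    chrom: str
    start: int
    strand: str
    mismatches: int

    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


def _hamming_within(a: str, b: str, limit: int) -> Optional[int]:
    """Mismatch count if <= limit else None; N on either side mismatches."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return None
    return mm


class GenomeIndex:
    """Exact q-gram position index over a genome, cached per q.

    Maps each q-length substring (q-grams containing N are unindexable)
    to its list of (chrom, position) occurrences on the forward strand.
    """

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self._cache: Dict[int, Dict[str, list]] = {}

    def seeds(self, q: int) -> Dict[str, list]:
        if q < 1:
            raise ValueError("seed length must be >= 1")
        if q not in self._cache:
            index: Dict[str, list] = {}
            for chrom in self.genome.chrom_names:
                seq = self.genome.sequence(chrom)
                for pos in range(len(seq) - q + 1):
                    gram = seq[pos : pos + q]
                    if "N" in gram:
                        continue
                    index.setdefault(gram, []).append((chrom, pos))
            self._cache[q] = index
        return self._cache[q]


def _exhaustive_orientation(
    seq: str, strand: str, genome: GenomeSequence, max_mismatches: int
) -> List[AlignmentHit]:
    # fallback for degenerate queries (N-containing k-mer, m >= k)
    k = len(seq)
    hits: List[AlignmentHit] = []
    for chrom in genome.chrom_names:
        g = genome.sequence(chrom)
        for start in range(len(g) - k + 1):
            mm = _hamming_within(seq, g[start : start + k], max_mismatches)
            if mm is not None:
                hits.append(AlignmentHit(chrom, start, strand, mm))
    return hits


def align_all(
    kmer_sequence: str,
    genome: GenomeSequence,
    max_mismatches: int,
    index: Optional[GenomeIndex] = None,
) -> List[AlignmentHit]:
    """All genomic placements of the k-mer within the mismatch budget, both strands."""
    k = len(kmer_sequence)
    if k == 0:
        raise ValueError("empty k-mer")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    kmer_sequence = kmer_sequence.upper()
    if index is None:
        index = GenomeIndex(genome)

    hits: List[AlignmentHit] = []
    for seq, strand in ((kmer_sequence, "+"), (revcomp(kmer_sequence), "-")):
        if max_mismatches >= k or "N" in seq:
            # every N is a forced mismatch; remaining budget may still allow hits
            if seq.count("N") <= max_mismatches:
                hits.extend(_exhaustive_orientation(seq, strand, genome, max_mismatches))
            continue
        q = k // (max_mismatches + 1)
        seed_index = index.seeds(q)
        candidates = set()
        for i in range(max_mismatches + 1):
            block = seq[i * q : (i + 1) * q]
            for chrom, pos in seed_index.get(block, ()):
                start = pos - i * q
                if start >= 0 and start + k <= genome.length(chrom):
                    candidates.add((chrom, start))
        for chrom, start in candidates:
            window = genome.sequence(chrom)[start : start + k]
            mm = _hamming_within(seq, window, max_mismatches)
            if mm is not None:
                hits.append(AlignmentHit(chrom, start, strand, mm))
    return sorted(hits)


_GENOME_ENC = np.full(256, 7, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _GENOME_ENC[ord(_c)] = _i
_GENOME_ENC[ord("N")] = 4  # genome N: matches nothing

_KMER_ENC = _GENOME_ENC.copy()
_KMER_ENC[ord("N")] = 5  # k-mer N: matches nothing, not even genome N


def brute_force_oracle(
    kmer_sequence: str,
    genome: GenomeSequence,
    max_mismatches: int,
    _guard_bp: int = 1_000_000,
) -> List[AlignmentHit]:
    """Naive full scan over every offset on both strands (test oracle).

    Guarded to genomes of at most 1 Mb total.
    """
    if genome.total_length() > _guard_bp:
        raise ValueError("brute-force oracle guard: genome exceeds 1 Mb")
    k = len(kmer_sequence)
    if k == 0:
        raise ValueError("empty k-mer")
    kmer_sequence = kmer_sequence.upper()
    hits: List[AlignmentHit] = []
    for seq, strand in ((kmer_sequence, "+"), (revcomp(kmer_sequence), "-")):
        query = _KMER_ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
        for chrom in genome.chrom_names:
            g = _GENOME_ENC[
                np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
            ]
            if len(g) < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(g, k)
            mism = (windows != query).sum(axis=1)
            for start in np.nonzero(mism <= max_mismatches)[0]:
                hits.append(AlignmentHit(chrom, int(start), strand, int(mism[start])))
    return sorted(hits)


def count_placements(
    kmer_sequence: str,
    genome: GenomeSequence,
    max_mismatches: int,
    index: Optional[GenomeIndex] = None,
) -> int:
    """C_k: the number of distinct (chrom, start, strand) placements of the k-mer."""
    return len(align_all(kmer_sequence, genome, max_mismatches, index=index))
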