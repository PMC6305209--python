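"""Directed cross-mappability: the published resource and its computation.

crossmap(A, B) is the number of Gene A's k-mers with at least one
alignment (within the mismatch budget) whose leftmost coordinate starts
inside Gene B's collapsed exon or UTR intervals. A k-mer hitting B at
several positions counts once toward B, and one k-mer may count toward
several target genes. Records with count 0 are never stored.

Two computation shortcuts follow from the definition and are proven
output-equivalent to the full computation in the test suite: genes with
mappability 1 need not be scanned (every k-mer is genome-unique, so its
only hit is its origin), and within a gene only k-mers with mappability
< 1 can cross-map.

Genes too short to yield any k-mer of either class (all exons shorter
than k_exon and all UTRs shorter than k_utr) have undetermined
mappability, and cross-mappability to or from them is undetermined: they
participate neither as sources nor as targets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

from .aligner import AlignmentHit, GenomeIndex, align_all
from .annotation import GeneModel
from .genome import GenomeSequence
from .kmers import DEFAULT_K_EXON, DEFAULT_K_UTR, enumerate_kmers
from .mappability import gene_mappability, kmer_mappability, region_mappability


@dataclass(frozen=True, order=True)
class CrossmapRecord:
    gene_a: str  # source
    gene_b: str  # target
    count: int

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("self-pairs are excluded from the resource")
        if self.count < 1:
            raise ValueError("records with count < 1 are not stored")


class CrossmapResource:
    """Directed (gene_a -> gene_b) k-mer counts with O(1) pair lookup."""

    def __init__(self, counts: Optional[Dict[Tuple[str, str], int]] = None):
        self._counts: Dict[Tuple[str, str], int] = {}
        if counts:
            for (a, b), c in counts.items():
                if c < 0:
                    raise ValueError("counts must be >= 0")
                if c > 0:
                    if a == b:
                        raise ValueError("self-pairs are excluded")
                    self._counts[(a, b)] = int(c)

    def get(self, gene_a: str, gene_b: str) -> int:
        """crossmap(A, B); absent pairs read as 0."""
        return self._counts.get((gene_a, gene_b), 0)

    def records(self) -> List[CrossmapRecord]:
        return [
            CrossmapRecord(a, b, c)
            for (a, b), c in sorted(self._counts.items())
        ]

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CrossmapResource) and self._counts == other._counts

    def __repr__(self) -> str:  # pragma: no cover
        return f"CrossmapResource({len(self)} records)"

    def as_dict(self) -> Dict[Tuple[str, str], int]:
        return dict(self._counts)


def is_crossmappable(
    resource: CrossmapResource, gene_a: str, gene_b: str, direction: str = "either"
) -> bool:
    """Whether the pair is cross-mappable (count > 0) in the requested direction."""
    if direction == "a_to_b":
        return resource.get(gene_a, gene_b) > 0
    if direction == "either":
        return resource.get(gene_a, gene_b) > 0 or resource.get(gene_b, gene_a) > 0
    raise ValueError(f"direction must be 'a_to_b' or 'either', got {direction!r}")


def gene_is_determined(model: GeneModel, k_exon: int, k_utr: int) -> bool:
    """A gene is determined iff some exon >= k_exon bp or some UTR >= k_utr bp."""
    return (
        model.exon_regions.max_interval_length() >= k_exon
        or model.utr_regions.max_interval_length() >= k_utr
    )


def _target_lookup(models: Iterable[GeneModel]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for s, e in m.all_regions():
            tree[s:e] = m.gene_id
    return trees


def compute_crossmap(
    models: Iterable[GeneModel],
    genome: GenomeSequence,
    k_exon: int = DEFAULT_K_EXON,
    k_utr: int = DEFAULT_K_UTR,
    max_mismatches: int = 2,
    use_shortcuts: bool = True,
    index: Optional[GenomeIndex] = None,
    aligner: Callable[..., List[AlignmentHit]] = align_all,
) -> CrossmapResource:
    """Genome-wide directed cross-mappability counts.

    Membership is tested on the hit's leftmost coordinate only (half-open
    containment in the target's exon/UTR intervals), regardless of strand.
    Hits back inside the source gene's own intervals never contribute.
    ``use_shortcuts=False`` runs the unoptimised computation; the output
    is identical.
    """
    models = list(models)
    if index is None:
        index = GenomeIndex(genome)
    determined = [m for m in models if gene_is_determined(m, k_exon, k_utr)]
    trees = _target_lookup(determined)

    counts: Dict[Tuple[str, str], int] = {}
    for model in determined:
        kmers = list(enumerate_kmers(model, genome, k_exon=k_exon, k_utr=k_utr))
        hit_lists = [
            aligner(km.sequence, genome, max_mismatches, index=index)
            if aligner is align_all
            else aligner(km.sequence, genome, max_mismatches)
            for km in kmers
        ]
        if use_shortcuts:
            by_class = {"exon": [], "utr": []}
            for km, hits in zip(kmers, hit_lists):
                by_class[km.region_class].append(kmer_mappability(len(hits)))
            gmap = gene_mappability(
                region_mappability(by_class["exon"]),
                region_mappability(by_class["utr"]),
                model.exon_regions.total_length(),
                model.utr_regions.total_length(),
            )
            if gmap == 1.0:
                continue  # no k-mer can map elsewhere
        tree = None
        for km, hits in zip(kmers, hit_lists):
            if use_shortcuts and len(hits) <= 1:
                continue  # unique k-mer: only hit is its origin
            targets = set()
            for hit in hits:
                chrom_tree = trees.get(hit.chrom)
                if chrom_tree is None:
                    continue
                for iv in chrom_tree.at(hit.start):
                    if iv.data != model.gene_id:
                        targets.add(iv.data)
            for target in targets:
                key = (model.gene_id, target)
                counts[key] = counts.get(key, 0) + 1
    return CrossmapResource(counts)


def write_resource(resource: CrossmapResource, path: str | os.PathLike) -> None:
    """Three-column TSV (gene_a, gene_b, count), sorted, no count-0 rows."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcount\n")
        for rec in resource.records():
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.count}\n")


def read_resource(path: str | os.PathLike) -> CrossmapResource:
    counts: Dict[Tuple[str, str], int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_a", "gene_b", "count"]:
            raise ValueError(f"unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 3 columns")
            a, b, raw = fields
            try:
                c = int(raw)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer count {raw!r}") from None
            if c <= 0:
                raise ValueError(f"line {lineno}: count must be >= 1")
            if (a, b) in counts:
                raise ValueError(f"line {lineno}: duplicate pair ({a}, {b})")
            counts[(a, b)] = c
    return CrossmapResource(counts)
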