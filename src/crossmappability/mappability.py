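"""Per-k-mer, per-region and per-gene mappability.

A k-mer's mappability is 1/C_k, where C_k is its number of genomic
placements within the mismatch budget (1 means genome-unique). A gene's
exon- and UTR-mappability are the arithmetic means over the k-mers of
each region class, and gene mappability is their average weighted by the
total collapsed lengths of the two region classes. A component is
undetermined (None / "NA") when the gene yields no k-mer of that class;
a gene whose exons are all shorter than k_exon and whose UTRs are all
shorter than k_utr has undetermined mappability altogether.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

from .aligner import GenomeIndex, count_placements
from .annotation import GeneModel
from .genome import GenomeSequence
from .kmers import DEFAULT_K_EXON, DEFAULT_K_UTR, enumerate_kmers


def kmer_mappability(c_k: int) -> float:
    """1/C_k; C_k must be a positive integer (a genomic k-mer always self-maps)."""
    if c_k <= 0:
        raise ValueError(f"C_k must be >= 1, got {c_k}")
    return 1.0 / c_k


def region_mappability(kmer_mappabilities: Sequence[float]) -> Optional[float]:
    """Mean k-mer mappability of a region class; None (undetermined) if no k-mers."""
    if len(kmer_mappabilities) == 0:
        return None
    return float(sum(kmer_mappabilities)) / len(kmer_mappabilities)


def gene_mappability(
    exon_map: Optional[float],
    utr_map: Optional[float],
    exon_len: int,
    utr_len: int,
) -> Optional[float]:
    """Length-weighted average of the defined region components.

    An undetermined component is excluded together with its weight; if
    both are undetermined the gene's mappability is undetermined.
    """
    if exon_len < 0 or utr_len < 0:
        raise ValueError("region lengths must be >= 0")
    parts = [
        (m, ln)
        for m, ln in ((exon_map, exon_len), (utr_map, utr_len))
        if m is not None
    ]
    if not parts:
        return None
    total = sum(ln for _, ln in parts)
    if total == 0:
        raise ValueError("defined mappability components with zero total length")
    return sum(m * ln for m, ln in parts) / total


@dataclass(frozen=True)
class MappabilityRecord:
    gene_id: str
    exon_mappability: Optional[float]
    utr_mappability: Optional[float]
    gene_mappability: Optional[float]
    exon_len: int
    utr_len: int


def compute_gene_mappability(
    models: Iterable[GeneModel],
    genome: GenomeSequence,
    k_exon: int = DEFAULT_K_EXON,
    k_utr: int = DEFAULT_K_UTR,
    max_mismatches: int = 2,
    index: Optional[GenomeIndex] = None,
) -> List[MappabilityRecord]:
    """Mappability of every gene, rows ordered by gene_id."""
    if index is None:
        index = GenomeIndex(genome)
    records = []
    for model in sorted(models, key=lambda m: m.gene_id):
        by_class = {"exon": [], "utr": []}
        for km in enumerate_kmers(model, genome, k_exon=k_exon, k_utr=k_utr):
            c_k = count_placements(km.sequence, genome, max_mismatches, index=index)
            by_class[km.region_class].append(kmer_mappability(c_k))
        exon_map = region_mappability(by_class["exon"])
        utr_map = region_mappability(by_class["utr"])
        records.append(
            MappabilityRecord(
                gene_id=model.gene_id,
                exon_mappability=exon_map,
                utr_mappability=utr_map,
                gene_mappability=gene_mappability(
                    exon_map,
                    utr_map,
                    model.exon_regions.total_length(),
                    model.utr_regions.total_length(),
                ),
                exon_len=model.exon_regions.total_length(),
                utr_len=model.utr_regions.total_length(),
            )
        )
    return records


def write_mappability_tsv(records: Sequence[MappabilityRecord], path: str | os.PathLike) -> None:
    """TSV with NA for undetermined values, one row per gene, sorted by gene_id."""

    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else f"{x:.10g}"

    with open(path, "w") as fh:
        fh.write("gene_id\texon_mappability\tutr_mappability\tgene_mappability\n")
        for rec in sorted(records, key=lambda r: r.gene_id):
            fh.write(
                f"{rec.gene_id}\t{fmt(rec.exon_mappability)}\t"
                f"{fmt(rec.utr_mappability)}\t{fmt(rec.gene_mappability)}\n"
            )
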