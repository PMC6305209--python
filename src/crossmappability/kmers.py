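"""Positional k-mer enumeration from collapsed gene regions.

k-mers are the proxy for RNA-seq reads: 75-mers are drawn from exonic
regions and 36-mers from UTRs by default (UTRs are typically shorter
than exons). A k-mer never spans two disjoint intervals, and k-mers
containing N are skipped (they cannot map exactly anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Optional

from .annotation import GeneModel
from .genome import GenomeSequence

DEFAULT_K_EXON = 75
DEFAULT_K_UTR = 36


@dataclass(frozen=True)
class KmerInstance:
    """One positional k-mer from a gene region."""

    gene_id: str
    region_class: str  # "exon" or "utr"
    chrom: str
    start: int
    k: int
    sequence: str


def enumerate_kmers(
    model: GeneModel,
    genome: GenomeSequence,
    k_exon: int = DEFAULT_K_EXON,
    k_utr: int = DEFAULT_K_UTR,
    skip_log: Optional[Dict[str, int]] = None,
) -> Iterator[KmerInstance]:
    """Yield every k-mer at every start offset of every collapsed region.

    A region of length L yields max(0, L - k + 1) k-mers for its class's k.
    N-containing k-mers are dropped and counted in ``skip_log`` if given.
    """
    if k_exon < 1 or k_utr < 1:
        raise ValueError("k must be >= 1")
    for region_class, regions, k in (
        ("exon", model.exon_regions, k_exon),
        ("utr", model.utr_regions, k_utr),
    ):
        for rstart, rend in regions:
            seq = genome.fetch(model.chrom, rstart, rend)
            for off in range(rend - rstart - k + 1):
                sub = seq[off : off + k]
                if "N" in sub:
                    if skip_log is not None:
                        skip_log[model.gene_id] = skip_log.get(model.gene_id, 0) + 1
                    continue
                yield KmerInstance(
                    gene_id=model.gene_id,
                    region_class=region_class,
                    chrom=model.chrom,
                    start=rstart + off,
                    k=k,
                    sequence=sub,
                )
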