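"""Collapsed gene models from Gencode-style GTF annotation.

Each gene is reduced to the union of its exon intervals and the union of
its UTR intervals across all transcripts (the "collapsed gene model").
By default UTR bases are subtracted from the exon intervals so that every
base belongs to exactly one region class; GTF encodes UTRs as a subset of
exons, and k-mers are drawn per region class, so without the subtraction
UTR bases would seed both 75-mers and 36-mers. The alternative behaviour
is preserved behind ``utr_subtraction=False``.

Coordinates are converted from GTF's 1-based inclusive convention to
0-based half-open on ingest.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import gffutils

from .genome import GenomeSequence
from .intervals import IntervalSet

logger = logging.getLogger(__name__)

#: GTF feature types treated as UTR annotation (Gencode v19 uses "UTR").
UTR_FEATURES = {"UTR", "five_prime_UTR", "three_prime_UTR", "five_prime_utr", "three_prime_utr"}


@dataclass(frozen=True)
class GeneModel:
    """A gene's collapsed exon/UTR intervals — the unit cross-mappability is defined over."""

    gene_id: str
    chrom: str
    strand: str
    gene_type: str
    exon_regions: IntervalSet
    utr_regions: IntervalSet

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        """[min, max) over all exon and UTR intervals."""
        return self.exon_regions.union(self.utr_regions).span()

    @property
    def tss(self) -> int:
        """Transcription start site: span start on '+', span end - 1 on '-'."""
        s, e = self.span
        return s if self.strand == "+" else e - 1

    def all_regions(self) -> IntervalSet:
        return self.exon_regions.union(self.utr_regions)


def build_gene_models(
    gtf_path: str | os.PathLike,
    genome: Optional[GenomeSequence] = None,
    utr_subtraction: bool = True,
) -> List[GeneModel]:
    """Parse a Gencode-dialect GTF into one collapsed GeneModel per gene_id.

    Exon and UTR intervals are merged across all transcripts of a gene;
    with ``utr_subtraction`` (default) UTR intervals are removed from the
    exon intervals. Genes with no exon features are skipped with a warning.
    If ``genome`` is given, intervals are validated against chromosome bounds.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: Dict[str, list] = {}
    utrs: Dict[str, list] = {}
    meta: Dict[str, tuple] = {}  # gene_id -> (chrom, strand, gene_type)
    order: list[str] = []

    for feat in db.all_features():
        if feat.featuretype != "exon" and feat.featuretype not in UTR_FEATURES:
            continue
        if "gene_id" not in feat.attributes:
            raise ValueError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} lacks gene_id"
            )
        gid = feat.attributes["gene_id"][0]
        gtype = feat.attributes.get("gene_type", ["unknown"])[0]
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> 0-based half-open
        if genome is not None:
            if feat.seqid not in genome:
                raise ValueError(f"{gid}: unknown chromosome {feat.seqid}")
            if not (0 <= start < end <= genome.length(feat.seqid)):
                raise ValueError(
                    f"{gid}: feature [{start},{end}) outside {feat.seqid} bounds"
                )
        if gid not in meta:
            meta[gid] = (feat.seqid, feat.strand, gtype)
            order.append(gid)
        elif meta[gid][0] != feat.seqid:
            raise ValueError(f"{gid}: features on multiple chromosomes")
        if feat.featuretype == "exon":
            exons.setdefault(gid, []).append((start, end))
        else:
            utrs.setdefault(gid, []).append((start, end))

    models: List[GeneModel] = []
    for gid in order:
        chrom, strand, gtype = meta[gid]
        if gid not in exons:
            logger.warning("gene %s has no exon features; skipped", gid)
            continue
        exon_set = IntervalSet(exons[gid])
        utr_set = IntervalSet(utrs.get(gid, []))
        if utr_subtraction:
            # each base belongs to exactly one region class
            exon_set = exon_set.subtract(utr_set)
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                gene_type=gtype,
                exon_regions=exon_set,
                utr_regions=utr_set,
            )
        )
    return models


def genes_near_position(
    models: Iterable[GeneModel], chrom: str, pos: int, window_bp: int
) -> Set[str]:
    """gene_ids whose TSS lies within ±window_bp of pos on chrom (inclusive)."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    return {
        m.gene_id
        for m in models
        if m.chrom == chrom and abs(m.tss - pos) <= window_bp
    }


def spans_overlap(model_a: GeneModel, model_b: GeneModel) -> bool:
    """True iff the two genes are on the same chromosome and their spans intersect."""
    if model_a.chrom != model_b.chrom:
        return False
    (a0, a1), (b0, b1) = model_a.span, model_b.span
    return a0 < b1 and b0 < a1
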