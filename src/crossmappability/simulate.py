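"""Synthetic genomes, annotations, genotypes and expression with planted truth.

The generator emulates the mechanism behind cross-mapping artifacts: a
"source" gene whose exonic sequence is partially duplicated (at a
controlled Hamming distance) inside a pseudogene-like "target" gene on
another chromosome. Reads (k-mers) from the source then also align into
the target, so a fraction of the source's expression signal leaks into
the target's measured expression, and a true cis-acting variant on the
source shows up as a spurious inter-chromosomal (trans) association with
the target.

Every planted duplication's expected cross-mappability is recorded in a
truth table computed at build time by an independent naive route (the
brute-force alignment oracle plus plain interval loops), never by the
production aligner.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aligner import brute_force_oracle
from .annotation import GeneModel
from .genome import GenomeSequence, write_fasta
from .intervals import IntervalSet

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneSpec:
    """Layout of one synthetic single-transcript gene."""

    gene_id: str
    chrom: str
    start: int
    exon_lengths: Tuple[int, ...]
    intron_lengths: Tuple[int, ...] = ()
    utr5_len: int = 0  # leading UTR, carved out of the first exon's end-flank
    utr3_len: int = 0
    strand: str = "+"
    gene_type: str = "protein_coding"

    def total_span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass(frozen=True)
class DuplicationSpec:
    """A pseudogene-like copy of part of a source gene inside a target gene."""

    source_gene: str
    target_gene: str
    segment_length: int
    hamming_distance: int = 0
    substitution_positions: Optional[Tuple[int, ...]] = None
    source_region: str = "exon"  # "exon" or "utr"
    target_region: str = "exon"

    def __post_init__(self):
        if self.source_region not in ("exon", "utr") or self.target_region not in ("exon", "utr"):
            raise ValueError("region classes must be 'exon' or 'utr'")
        if self.hamming_distance < 0 or self.segment_length < 1:
            raise ValueError("invalid duplication spec")
        if self.substitution_positions is not None:
            pos = self.substitution_positions
            if len(set(pos)) != len(pos) or len(pos) != self.hamming_distance:
                raise ValueError("substitution positions must be distinct and match distance")
            if any(p < 0 or p >= self.segment_length for p in pos):
                raise ValueError("substitution positions outside segment")


@dataclass(frozen=True)
class CisEffect:
    variant_id: str
    chrom: str
    pos: int
    source_gene: str
    beta: float


@dataclass
class TruthTable:
    """Planted ground truth: oracle crossmap counts, cis effects, contamination."""

    crossmap: Dict[int, Dict[Tuple[str, str], int]] = field(default_factory=dict)
    eqtls: List[CisEffect] = field(default_factory=list)
    alphas: Dict[Tuple[str, str], float] = field(default_factory=dict)
    duplications: List[DuplicationSpec] = field(default_factory=list)

    def crossmap_count(self, gene_a: str, gene_b: str, max_mismatches: int) -> int:
        return self.crossmap.get(max_mismatches, {}).get((gene_a, gene_b), 0)


def oracle_crossmap(
    models: Sequence[GeneModel],
    genome: GenomeSequence,
    k_exon: int,
    k_utr: int,
    max_mismatches: int,
) -> Dict[Tuple[str, str], int]:
    """Naive reference crossmap: brute-force oracle hits + plain loops.

    Deliberately independent of the production aligner and counting code.
    """
    determined = [
        m
        for m in models
        if m.exon_regions.max_interval_length() >= k_exon
        or m.utr_regions.max_interval_length() >= k_utr
    ]
    counts: Dict[Tuple[str, str], int] = {}
    for src in determined:
        kmer_seqs = []
        for regions, k in ((src.exon_regions, k_exon), (src.utr_regions, k_utr)):
            for s, e in regions:
                for off in range(e - s - k + 1):
                    sub = genome.fetch(src.chrom, s + off, s + off + k)
                    if "N" not in sub:
                        kmer_seqs.append(sub)
        for seq in kmer_seqs:
            targets = set()
            for hit in brute_force_oracle(seq, genome, max_mismatches):
                for tgt in determined:
                    if tgt.gene_id == src.gene_id or tgt.chrom != hit.chrom:
                        continue
                    for s, e in list(tgt.exon_regions) + list(tgt.utr_regions):
                        if s <= hit.start < e:
                            targets.add(tgt.gene_id)
            for tgt_id in targets:
                counts[(src.gene_id, tgt_id)] = counts.get((src.gene_id, tgt_id), 0) + 1
    return counts


def _build_models(gene_specs: Sequence[GeneSpec]) -> List[GeneModel]:
    models = []
    for gs in gene_specs:
        if gs.intron_lengths and len(gs.intron_lengths) != len(gs.exon_lengths) - 1:
            raise ValueError(f"{gs.gene_id}: need one intron fewer than exons")
        exons = []
        pos = gs.start
        introns = list(gs.intron_lengths) + [0]
        for elen, ilen in zip(gs.exon_lengths, introns):
            exons.append((pos, pos + elen))
            pos += elen + ilen
        exon_set = IntervalSet(exons)
        utr_ivs = []
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        if gs.utr5_len:
            if gs.utr5_len >= first_e - first_s:
                raise ValueError(f"{gs.gene_id}: UTR5 longer than first exon")
            utr_ivs.append((first_s, first_s + gs.utr5_len))
        if gs.utr3_len:
            if gs.utr3_len >= last_e - last_s:
                raise ValueError(f"{gs.gene_id}: UTR3 longer than last exon")
            utr_ivs.append((last_e - gs.utr3_len, last_e))
        utr_set = IntervalSet(utr_ivs)
        models.append(
            GeneModel(
                gene_id=gs.gene_id,
                chrom=gs.chrom,
                strand=gs.strand,
                gene_type=gs.gene_type,
                exon_regions=exon_set.subtract(utr_set),
                utr_regions=utr_set,
            )
        )
    return models


def write_gtf(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write Gencode-dialect GTF (gene/transcript/exon/UTR features, 1-based)."""

    def attrs(m: GeneModel, extra: str = "") -> str:
        return (
            f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1"; '
            f'gene_type "{m.gene_type}";{extra}'
        )

    with open(path, "w") as fh:
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.chrom}\tsynthetic\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs(m)}\n"
            )
            fh.write(
                f"{m.chrom}\tsynthetic\ttranscript\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs(m)}\n"
            )
            # GTF annotates UTR bases inside exons; re-emit the pre-subtraction union
            for iv_s, iv_e in m.all_regions():
                fh.write(
                    f"{m.chrom}\tsynthetic\texon\t{iv_s + 1}\t{iv_e}\t.\t{m.strand}\t.\t{attrs(m)}\n"
                )
            for iv_s, iv_e in m.utr_regions:
                fh.write(
                    f"{m.chrom}\tsynthetic\tUTR\t{iv_s + 1}\t{iv_e}\t.\t{m.strand}\t.\t{attrs(m)}\n"
                )
    return None


def _substitute(base: str) -> str:
    return _BASES[(_BASES.index(base) + 1) % 4]


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    gene_specs: Sequence[GeneSpec],
    duplication_specs: Sequence[DuplicationSpec] = (),
    seed: int = 0,
    k_exon: int = 75,
    k_utr: int = 36,
    mismatch_budgets: Sequence[int] = (2,),
    outdir: Optional[str | os.PathLike] = None,
    max_regenerations: int = 5,
) -> Tuple[GenomeSequence, List[GeneModel], TruthTable]:
    """Random genome with planted duplications and oracle-verified truth.

    Base sequence is i.i.d. uniform over ACGT. Each duplication copies the
    leading ``segment_length`` bases of the source gene's exonic sequence
    into the start of the target gene's first exon, planting the requested
    substitutions. Truth crossmap counts are computed with the brute-force
    oracle for every mismatch budget. If random sequence accidentally
    creates cross-mappability outside the planted pairs, the genome is
    regenerated under the next seed (exact truth tables by construction).
    Deterministic under ``seed``. Writes FASTA + GTF when ``outdir`` given.
    """
    models = _build_models(gene_specs)
    model_by_id = {m.gene_id: m for m in models}

    spans_by_chrom: Dict[str, list] = {}
    for m in models:
        if m.chrom not in {f"chr{i + 1}" for i in range(n_chroms)}:
            raise ValueError(f"{m.gene_id}: chromosome {m.chrom} not generated")
        s, e = m.span
        if e > chrom_length:
            raise ValueError(f"{m.gene_id}: gene extends past chromosome end")
        for os_, oe in spans_by_chrom.get(m.chrom, []):
            if s < oe and os_ < e:
                raise ValueError(f"overlapping gene spans on {m.chrom}")
        spans_by_chrom.setdefault(m.chrom, []).append((s, e))

    allowed = set()
    for dup in duplication_specs:
        allowed.add((dup.source_gene, dup.target_gene))
        allowed.add((dup.target_gene, dup.source_gene))

    attempt_seed = seed
    for _ in range(max_regenerations):
        rng = np.random.default_rng(attempt_seed)
        seqs = {
            f"chr{i + 1}": rng.integers(0, 4, size=chrom_length)
            for i in range(n_chroms)
        }
        arrays = {c: np.array(list(_BASES))[v] for c, v in seqs.items()}

        for dup in duplication_specs:
            src = model_by_id[dup.source_gene]
            tgt = model_by_id[dup.target_gene]
            src_bases = _gene_region_bases(src, dup.source_region)
            tgt_bases = _gene_region_bases(tgt, dup.target_region)
            if dup.segment_length > len(src_bases) or dup.segment_length > len(tgt_bases):
                raise ValueError(
                    f"duplication {dup.source_gene}->{dup.target_gene}: segment too long"
                )
            segment = [
                str(arrays[src.chrom][p]) for p in src_bases[: dup.segment_length]
            ]
            sub_pos = dup.substitution_positions
            if sub_pos is None and dup.hamming_distance > 0:
                step = dup.segment_length // dup.hamming_distance
                sub_pos = tuple(
                    min(i * step + step // 2, dup.segment_length - 1)
                    for i in range(dup.hamming_distance)
                )
            for p in sub_pos or ():
                segment[p] = _substitute(segment[p])
            for off, p in enumerate(tgt_bases[: dup.segment_length]):
                arrays[tgt.chrom][p] = segment[off]

        genome = GenomeSequence({c: "".join(a) for c, a in arrays.items()})
        truth = TruthTable(duplications=list(duplication_specs))
        collision = False
        for m_budget in mismatch_budgets:
            counts = oracle_crossmap(models, genome, k_exon, k_utr, m_budget)
            if any(pair not in allowed for pair in counts):
                collision = True
                break
            truth.crossmap[m_budget] = counts
        if not collision:
            if outdir is not None:
                os.makedirs(outdir, exist_ok=True)
                write_fasta(genome, os.path.join(outdir, "genome.fa"))
                write_gtf(models, os.path.join(outdir, "annotation.gtf"))
                write_truth_tsv(truth, os.path.join(outdir, "truth_crossmap.tsv"))
            return genome, models, truth
        attempt_seed += 104729  # jump to an unrelated stream and retry
    raise RuntimeError("could not generate a collision-free genome")


def _gene_region_bases(model: GeneModel, region_class: str = "exon") -> List[int]:
    """Genomic positions of the gene's bases of one region class, in order."""
    regions = model.exon_regions if region_class == "exon" else model.utr_regions
    out: List[int] = []
    for s, e in regions:
        out.extend(range(s, e))
    return out


def write_truth_tsv(truth: TruthTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("max_mismatches\tgene_a\tgene_b\tcount\n")
        for m_budget in sorted(truth.crossmap):
            for (a, b), c in sorted(truth.crossmap[m_budget].items()):
                fh.write(f"{m_budget}\t{a}\t{b}\t{c}\n")


# ---------------------------------------------------------------------------
# expression / genotypes
# ---------------------------------------------------------------------------

def simulate_expression(
    models: Sequence[GeneModel],
    truth: TruthTable,
    n_samples: int,
    alpha_map: Optional[Mapping[Tuple[str, str], float]] = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x samples expression with planted contamination.

    Every gene gets independent standard-normal expression; each
    contaminated target's expression is alpha * source + N(0, noise_sd).
    """
    if alpha_map is None:
        alpha_map = truth.alphas
    rng = np.random.default_rng(seed)
    gene_ids = [m.gene_id for m in models]
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    expr = pd.DataFrame(
        rng.standard_normal((len(gene_ids), n_samples)),
        index=gene_ids,
        columns=sample_ids,
    )
    for (src, tgt), alpha in alpha_map.items():
        if not (0 <= alpha < 1):
            raise ValueError("contamination fraction must be in [0, 1)")
        noise = rng.standard_normal(n_samples) * noise_sd
        expr.loc[tgt] = alpha * expr.loc[src].to_numpy() + noise
    return expr


def simulate_genotypes_and_cis(
    models: Sequence[GeneModel],
    truth: TruthTable,
    n_samples: int,
    maf: float = 0.3,
    beta_cis: float = 1.0,
    seed: int = 0,
    alpha_map: Optional[Mapping[Tuple[str, str], float]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cis variants on duplication sources, plus the expression additions.

    One variant per duplication source gene, dosage ~ Binomial(2, maf),
    placed on the source's chromosome 1 kb upstream of its TSS (clipped to
    the chromosome). Returns (variant_info, genotypes, additions): the
    source gene's expression gains beta_cis * dosage, and each
    contaminated target inherits alpha * beta_cis * dosage.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if alpha_map is None:
        alpha_map = truth.alphas
    rng = np.random.default_rng(seed)
    model_by_id = {m.gene_id: m for m in models}
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    sources = sorted({dup.source_gene for dup in truth.duplications})
    if not sources:
        sources = sorted({src for (src, _tgt) in alpha_map})

    info_rows, geno_rows, add = [], [], {}
    truth.eqtls.clear()
    for src_id in sources:
        model = model_by_id[src_id]
        pos = max(0, model.tss - 1000)
        variant_id = f"var_{src_id}"
        dosage = rng.binomial(2, maf, size=n_samples).astype(float)
        info_rows.append(dict(variant_id=variant_id, chrom=model.chrom, pos=pos,
                              maf=maf))
        geno_rows.append(pd.Series(dosage, index=sample_ids, name=variant_id))
        add[src_id] = add.get(src_id, 0.0) + beta_cis * dosage
        for (s, t), alpha in alpha_map.items():
            if s == src_id:
                add[t] = add.get(t, 0.0) + alpha * beta_cis * dosage
        truth.eqtls.append(CisEffect(variant_id, model.chrom, pos, src_id, beta_cis))

    variant_info = pd.DataFrame(info_rows, columns=["variant_id", "chrom", "pos", "maf"])
    genotypes = pd.DataFrame(geno_rows)
    additions = pd.DataFrame(
        0.0, index=[m.gene_id for m in models], columns=sample_ids
    )
    for gid, delta in add.items():
        additions.loc[gid] = delta
    return variant_info, genotypes, additions


@dataclass
class SimulatedStudy:
    genome: GenomeSequence
    models: List[GeneModel]
    truth: TruthTable
    expression: pd.DataFrame  # genes x samples, contamination + cis effects applied
    variant_info: pd.DataFrame
    genotypes: pd.DataFrame  # variants x samples


def default_gene_specs(
    n_chroms: int = 3,
    genes_per_chrom: int = 2,
    exon_length: int = 300,
    utr_length: int = 60,
    gap: int = 500,
) -> List[GeneSpec]:
    """A simple layout: single-exon genes with terminal UTRs, evenly spaced.

    Genes are assigned round-robin across chromosomes, so consecutive
    gene ids lie on different chromosomes whenever n_chroms >= 2.
    """
    specs = []
    next_pos = {f"chr{i + 1}": gap for i in range(n_chroms)}
    for g in range(n_chroms * genes_per_chrom):
        chrom = f"chr{g % n_chroms + 1}"
        specs.append(
            GeneSpec(
                gene_id=f"gene{g:03d}",
                chrom=chrom,
                start=next_pos[chrom],
                exon_lengths=(exon_length,),
                utr5_len=utr_length,
                utr3_len=utr_length,
            )
        )
        next_pos[chrom] += exon_length + gap
    return specs


def simulate_study(
    n_samples: int = 500,
    alpha: float = 0.5,
    beta_cis: float = 1.0,
    noise_sd: float = 1.0,
    maf: float = 0.3,
    n_duplicated_pairs: int = 1,
    segment_length: int = 100,
    hamming_distance: int = 0,
    n_chroms: int = 3,
    chrom_length: int = 4000,
    genes_per_chrom: int = 2,
    mismatch_budgets: Sequence[int] = (2,),
    seed: int = 0,
    k_exon: int = 75,
    k_utr: int = 36,
) -> SimulatedStudy:
    """End-to-end contaminated study under the default conditions.

    Duplication pairs use distinct (source, target) genes on different
    chromosomes so the source's cis variant is inter-chromosomal with
    respect to the target.
    """
    if n_chroms < 2:
        raise ValueError("need >= 2 chromosomes for inter-chromosomal pairs")
    specs = default_gene_specs(n_chroms, genes_per_chrom)
    if 2 * n_duplicated_pairs > len(specs):
        raise ValueError("not enough genes for the requested duplications")
    dups = []
    for i in range(n_duplicated_pairs):
        src, tgt = specs[2 * i], specs[2 * i + 1]
        dups.append(
            DuplicationSpec(src.gene_id, tgt.gene_id, segment_length, hamming_distance)
        )
    genome, models, truth = generate_genome(
        n_chroms,
        chrom_length,
        specs,
        dups,
        seed=seed,
        k_exon=k_exon,
        k_utr=k_utr,
        mismatch_budgets=mismatch_budgets,
    )
    truth.alphas = {(d.source_gene, d.target_gene): alpha for d in dups}
    expr = simulate_expression(models, truth, n_samples, noise_sd=noise_sd, seed=seed + 1)
    variant_info, genotypes, additions = simulate_genotypes_and_cis(
        models, truth, n_samples, maf=maf, beta_cis=beta_cis, seed=seed + 2
    )
    expr = expr + additions
    return SimulatedStudy(genome, models, truth, expr, variant_info, genotypes)


def read_config(path: str | os.PathLike) -> Dict[str, str]:
    """Flat key = value text config; '#' starts a comment."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out
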