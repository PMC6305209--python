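"""Reference genome access.

Sequences are held in memory as uppercase strings over the alphabet
{A, C, G, T, N}. IUPAC ambiguity codes other than N are mapped to N
(logged), since an ambiguous reference base cannot anchor an exact
k-mer match.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC codes valid in FASTA but unusable for exact matching.
_AMBIGUOUS = set("RYSWKMBDHVU")


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase ACGTN string."""

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        clean: Dict[str, str] = {}
        for name, seq in sequences.items():
            if len(seq) < 1:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                if not bad <= _AMBIGUOUS:
                    raise ValueError(
                        f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                    )
                logger.warning(
                    "chromosome %s: mapping ambiguity codes %s to N", name, sorted(bad)
                )
                seq = "".join(c if c in _VALID else "N" for c in seq)
            clean[name] = seq
        self._seqs = clean

    @property
    def chrom_names(self) -> List[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring at [start, end); out-of-bounds lookups are errors."""
        seq = self.sequence(chrom)
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"coordinates [{start}, {end}) outside {chrom} [0, {len(seq)})"
            )
        return seq[start:end]

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs


def load_genome(fasta_path: str | os.PathLike) -> GenomeSequence:
    """Read a (multi-record) FASTA into a GenomeSequence.

    Duplicate record names, empty records and missing files are errors.
    """
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(str(fasta_path))
    try:
        fa = Fasta(
            str(fasta_path),
            as_raw=True,
            sequence_always_upper=True,
            rebuild=True,
            duplicate_action="stop",
        )
    except Exception as exc:  # pyfaidx raises several index error types
        raise ValueError(f"invalid FASTA {fasta_path}: {exc}") from exc
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fasta_dict(seqs: Dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    write_fasta(GenomeSequence(dict(seqs)), path, width)
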