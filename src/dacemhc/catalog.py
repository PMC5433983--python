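"""Allele catalogs for the MHC class II beta exon-2 amplicon.

An :class:`AlleleCatalog` holds the distinct nucleotide sequences observed
(or simulated) for a single amplified locus, together with the exon/intron
annotation needed by the codon-level statistics.  The amplicon modelled here
is a 236-bp segment: 207 bp of exon 2 followed by 29 bp of the downstream
intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

#: default exon interval (0-based, half-open) in amplicon coordinates
DEFAULT_EXON_SPAN = (0, 207)


class CatalogError(ValueError):
    """Raised when an allele catalog violates its structural invariants."""


@dataclass(frozen=True)
class AlleleCatalog:
    """A set of distinct allele sequences for one amplicon.

    Parameters
    ----------
    alleles
        ``(allele_id, sequence)`` pairs.  IDs must be unique and sequences
        must be distinct uppercase A/C/G/T strings.
    exon_span
        Half-open ``(start, end)`` interval of the coding portion, in
        amplicon coordinates.
    frame_offset
        Codon frame of the exon's first base (0, 1 or 2).  Trailing bases
        that do not complete a codon are ignored by codon-level analyses.
    """

    alleles: tuple[tuple[str, str], ...]
    exon_span: tuple[int, int] = DEFAULT_EXON_SPAN
    frame_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple((a, s.upper()) for a, s in self.alleles))
        ids = [a for a, _ in self.alleles]
        if len(set(ids)) != len(ids):
            raise CatalogError("allele ids must be unique")
        seqs = [s for _, s in self.alleles]
        if len(set(seqs)) != len(seqs):
            raise CatalogError("allele sequences must be distinct")
        for aid, s in self.alleles:
            if not set(s) <= VALID_BASES:
                raise CatalogError(f"allele {aid} contains non-ACGT characters")
        start, end = self.exon_span
        if not (0 <= start < end):
            raise CatalogError("exon_span must be a non-empty half-open interval")
        if self.frame_offset not in (0, 1, 2):
            raise CatalogError("frame_offset must be 0, 1 or 2")

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.alleles)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.alleles)

    def sequence(self, allele_id: str) -> str:
        for aid, s in self.alleles:
            if aid == allele_id:
                return s
        raise KeyError(allele_id)

    @property
    def is_aligned(self) -> bool:
        """True when all sequences share one length (gap-free alignment)."""
        return len({len(s) for s in self.sequences}) == 1

    @property
    def length(self) -> int:
        if not self.is_aligned:
            raise CatalogError("catalog sequences are not all the same length")
        return len(self.alleles[0][1])

    # -- codon-level views ----------------------------------------------

    @property
    def exon_codon_span(self) -> tuple[int, int]:
        """Exon interval trimmed to whole codons after the frame offset."""
        start, end = self.exon_span
        start += self.frame_offset
        n_codons = (end - start) // 3
        return start, start + 3 * n_codons

    def exon_codon_sequences(self) -> tuple[str, ...]:
        """Exon-only, in-frame sequences (whole codons)."""
        s, e = self.exon_codon_span
        return tuple(seq[s:e] for seq in self.sequences)

    # -- IO ---------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=aid,
                      description=f"exon={self.exon_span[0]}:{self.exon_span[1]} "
                                  f"frame={self.frame_offset}")
            for aid, s in self.alleles
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path,
                   exon_span: tuple[int, int] | None = None,
                   frame_offset: int | None = None) -> "AlleleCatalog":
        """Read a catalog written by :meth:`to_fasta`.

        Exon annotation is recovered from the record descriptions when
        present; explicit arguments override it.
        """
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise CatalogError(f"no sequences in {path}")
        span, frame = DEFAULT_EXON_SPAN, 0
        for token in records[0].description.split():
            if token.startswith("exon="):
                a, b = token[5:].split(":")
                span = (int(a), int(b))
            elif token.startswith("frame="):
                frame = int(token[6:])
        if exon_span is not None:
            span = exon_span
        if frame_offset is not None:
            frame = frame_offset
        return cls(tuple((r.id, str(r.seq).upper()) for r in records),
                   exon_span=span, frame_offset=frame)


def pairwise_differences(catalog: AlleleCatalog) -> "np.ndarray":
    """Matrix of raw nucleotide difference counts between catalog alleles.

    Equal-length sequences are compared column-wise; for a
    length-heterogeneous catalog (indel-bearing alleles) the count falls
    back to the global-alignment edit distance, which coincides with the
    column count on gap-free alignments.
    """
    import numpy as np

    n = len(catalog)
    d = np.zeros((n, n), dtype=float)
    if catalog.is_aligned:
        arr = np.array([list(s) for s in catalog.sequences])
        for i in range(n):
            d[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
    else:
        import edlib

        seqs = catalog.sequences
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = edlib.align(seqs[i], seqs[j],
                                      task="distance")["editDistance"]
    return d + d.T
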