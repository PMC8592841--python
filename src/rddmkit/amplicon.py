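"""Primer-trimmed amplicon references with annotated cytosine sites.

Bisulfite amplicon sequencing (BSAS) interrogates every cytosine on one
strand of a short PCR amplicon.  Each cytosine is classified by its
sequence context — CG, CHG or CHH, where H is A, C or T — read 5'->3' on
the assayed strand from the two bases immediately downstream of the
cytosine.  Contexts matter because in plants the three are written and
maintained by different methyltransferase pathways; CHH methylation in
particular is the hallmark of RNA-directed DNA methylation (RdDM).

Coordinates are 0-based internally; all serialized output is 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Strand",
    "Context",
    "CytosineSite",
    "Amplicon",
    "annotate_sites",
    "read_amplicons_fasta",
    "write_site_table",
]

_DNA_ALPHABET = frozenset("ACGTN")
_H_BASES = frozenset("ACT")


class Strand(str, enum.Enum):
    """Which strand of the amplicon the bisulfite assay reads out."""

    FORWARD = "forward"
    REVERSE = "reverse"


class Context(str, enum.Enum):
    """Cytosine sequence context on the assayed strand (H is A, C or T)."""

    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class CytosineSite:
    """A single assayable cytosine.

    position is a 0-based offset into the amplicon sequence (the given,
    forward-orientation string, regardless of assayed strand).  context is
    derived solely from the two downstream bases on the assayed strand;
    sites with fewer than two downstream bases, or with an N anywhere in
    the trinucleotide, get UNDEFINED.
    """

    position: int
    context: Context


@dataclass(frozen=True)
class Amplicon:
    """A primer-trimmed amplicon reference with its annotated cytosine sites.

    One Amplicon declares exactly one assayed strand: BSAS amplifies one
    bisulfite-converted strand, so assaying both strands of a locus takes
    two Amplicon entries.
    """

    name: str
    sequence: str
    assayed_strand: Strand
    sites: tuple[CytosineSite, ...] = field(default=())

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"amplicon {self.name!r}: non-DNA characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)
        if not self.sites:
            object.__setattr__(
                self, "sites", tuple(annotate_sites(seq, self.assayed_strand))
            )
        assayed_base = "C" if self.assayed_strand is Strand.FORWARD else "G"
        last = -1
        for site in self.sites:
            if site.position <= last:
                raise ValueError(f"amplicon {self.name!r}: sites not strictly increasing")
            if seq[site.position] != assayed_base:
                raise ValueError(
                    f"amplicon {self.name!r}: site at {site.position} is not "
                    f"{assayed_base} on the assayed strand"
                )
            last = site.position

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_positions(self) -> list[int]:
        return [s.position for s in self.sites]

    def contexts(self) -> list[Context]:
        return [s.context for s in self.sites]


def _context_from_downstream(b1: str, b2: str) -> Context:
    if b1 == "N" or b2 == "N":
        return Context.UNDEFINED
    if b1 == "G":
        return Context.CG
    if b1 in _H_BASES and b2 == "G":
        return Context.CHG
    if b1 in _H_BASES and b2 in _H_BASES:
        return Context.CHH
    return Context.UNDEFINED


def annotate_sites(sequence: str, assayed_strand: Union[Strand, str]) -> list[CytosineSite]:
    """Annotate every cytosine on the assayed strand with its context.

    Forward strand: a site is every C in ``sequence``; the downstream bases
    are the next two characters.  Reverse strand: a site is every G (a C on
    the reverse complement); downstream on that strand runs leftward in
    forward coordinates, with bases complemented.

    Boundary cytosines with fewer than two downstream bases get context
    UNDEFINED — they still carry methylation information per read and are
    assayed, but are excluded from context-stratified summaries.
    """
    strand = Strand(assayed_strand)
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)!r}")

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    sites: list[CytosineSite] = []
    if strand is Strand.FORWARD:
        for i, base in enumerate(seq):
            if base != "C":
                continue
            if i + 2 >= len(seq):
                # fewer than two downstream bases: context unresolvable
                sites.append(CytosineSite(i, Context.UNDEFINED))
                continue
            sites.append(
                CytosineSite(i, _context_from_downstream(seq[i + 1], seq[i + 2]))
            )
    else:
        for i, base in enumerate(seq):
            if base != "G":
                continue
            # downstream on the reverse strand = positions i-1, i-2, complemented
            if i - 2 < 0:
                sites.append(CytosineSite(i, Context.UNDEFINED))
                continue
            sites.append(
                CytosineSite(
                    i, _context_from_downstream(comp[seq[i - 1]], comp[seq[i - 2]])
                )
            )
    return sites


def read_amplicons_fasta(
    path: Union[str, Path], assayed_strand: Union[Strand, str] = Strand.FORWARD
) -> list[Amplicon]:
    """Read primer-trimmed references from FASTA; one Amplicon per record.

    A per-record strand can be declared in the FASTA description as
    ``strand=forward`` / ``strand=reverse``; otherwise ``assayed_strand``
    applies to every record.
    """
    default = Strand(assayed_strand)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        strand = default
        for token in rec.description.split():
            if token.startswith("strand="):
                strand = Strand(token.split("=", 1)[1])
        out.append(Amplicon(rec.id, str(rec.seq).upper(), strand))
    return out


def write_site_table(amplicons: Iterable[Amplicon], handle: TextIO) -> None:
    """Write the annotated site table as TSV (1-based positions)."""
    handle.write("amplicon\tposition\tstrand\tcontext\n")
    for amp in amplicons:
        strand_sym = "+" if amp.assayed_strand is Strand.FORWARD else "-"
        for site in amp.sites:
            handle.write(
                f"{amp.name}\t{site.position + 1}\t{strand_sym}\t{site.context.value}\n"
            )


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())
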