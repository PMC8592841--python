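"""Small RNA size-class profiling and Pol V-dependence classification.

Small RNA libraries are reduced to per-size-class (18-28 nt) read counts
against a target sequence, normalized to reads per million (RPM)
genome-mapped reads.  Mapping at transgene/amplicon scale is exact
substring matching on either strand — the zero-mismatch semantics of
``bowtie -v 0`` — with a read counted once per target regardless of how
many positions or strands it hits.

Two classifiers operate downstream: per-size AGO4-IP/mock enrichment
ratios (NA when the mock class has no mapped reads), and the siRNA-locus
Pol V-dependence rule — testable only at >= 10 raw wild-type reads,
dependent when the mutant loses >= 2-fold accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SIZE_RANGE",
    "SmallRNALibrary",
    "SizeClassProfile",
    "SiRNALocus",
    "map_exact",
    "size_class_rpm",
    "ip_enrichment",
    "classify_sirna_dependence",
    "read_small_rna",
    "read_size_count_table",
    "heatmap_matrix",
]

SIZE_MIN = 18
SIZE_MAX = 28
SIZE_RANGE = range(SIZE_MIN, SIZE_MAX + 1)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SmallRNALibrary:
    """A filtered small RNA library: 18-28 nt reads plus the normalization total.

    genome_mapped_total is the library's count of genome-matching reads —
    the depth-normalization denominator — which is larger than the number
    of target-mapped reads kept here.
    """

    name: str
    reads: list[str]
    genome_mapped_total: int

    def __post_init__(self) -> None:
        self.reads = [r.upper() for r in self.reads if SIZE_MIN <= len(r) <= SIZE_MAX]
        if self.genome_mapped_total <= 0:
            raise ValueError("genome_mapped_total must be positive")


@dataclass(frozen=True)
class SizeClassProfile:
    """Per-size raw counts and RPM for one library against one target."""

    target: str
    sample: str
    raw_counts: dict[int, int]
    rpm: dict[int, float]
    genome_mapped_total: int

    def total_rpm(self) -> float:
        return sum(self.rpm.values())


@dataclass(frozen=True)
class SiRNALocus:
    """A 23-24-nt siRNA locus with its Pol V-dependence classification."""

    locus: str
    wt_raw: int
    wt_rpm: float
    mut_rpm: float
    classification: str  # dependent | independent | not_testable


def map_exact(
    reads: Sequence[str], target: str, target_name: str = "target"
) -> tuple[list[bool], dict[int, int]]:
    """Zero-mismatch mapping of small RNAs to a target sequence.

    A read maps iff it occurs verbatim as a substring of the target or of
    its reverse complement; multiple hit positions or both-strand hits
    still count the read once.  Returns the per-read mapped flags and the
    per-size raw counts over 18-28 nt.
    """
    target = target.upper()
    rc = _revcomp(target)
    flags: list[bool] = []
    counts = {size: 0 for size in SIZE_RANGE}
    for read in reads:
        r = read.upper()
        hit = bool(r) and (r in target or r in rc)
        flags.append(hit)
        if hit and SIZE_MIN <= len(r) <= SIZE_MAX:
            counts[len(r)] += 1
    return flags, counts


def size_class_rpm(
    raw_counts: Mapping[int, int],
    genome_mapped_total: int,
    target: str = "target",
    sample: str = "sample",
) -> SizeClassProfile:
    """Reads-per-million normalization of per-size counts."""
    if genome_mapped_total <= 0:
        raise ValueError("genome_mapped_total must be positive")
    counts = {size: int(raw_counts.get(size, 0)) for size in SIZE_RANGE}
    rpm = {size: c * 1e6 / genome_mapped_total for size, c in counts.items()}
    return SizeClassProfile(target, sample, counts, rpm, genome_mapped_total)


def profile_library(
    library: SmallRNALibrary, target: str, target_name: str = "target"
) -> SizeClassProfile:
    """Map a library to a target and normalize — the common composition."""
    _, counts = map_exact(library.reads, target, target_name)
    return size_class_rpm(
        counts, library.genome_mapped_total, target_name, library.name
    )


def ip_enrichment(
    ip: SizeClassProfile, mock: SizeClassProfile
) -> dict[int, float]:
    """Per-size IP/mock RPM ratio; NaN where the mock class has no reads.

    NaN (serialized "NA") marks a ratio that cannot be formed because of
    absent mock reads — distinct from a genuine 0.0 when the IP is empty
    but the mock is not.
    """
    if ip.target != mock.target:
        raise ValueError(f"profiles for different targets: {ip.target} vs {mock.target}")
    out: dict[int, float] = {}
    for size in SIZE_RANGE:
        m = mock.rpm[size]
        i = ip.rpm[size]
        out[size] = math.nan if m == 0.0 else i / m
    return out


def classify_sirna_dependence(
    loci: Iterable[tuple[str, int, float, float]],
    min_raw_reads: int = 10,
    fold: float = 2.0,
) -> list[SiRNALocus]:
    """Classify siRNA loci as Pol V-dependent / -independent.

    Input tuples: (locus, wt_raw, wt_rpm, mut_rpm); RPM values should be
    replicate-averaged.  A locus is not_testable below ``min_raw_reads``
    raw wild-type reads; dependent when the mutant accumulates at most
    wt/fold; independent otherwise.
    """
    out = []
    for locus, wt_raw, wt_rpm, mut_rpm in loci:
        if wt_raw < 0 or wt_rpm < 0 or mut_rpm < 0:
            raise ValueError(f"{locus}: negative counts")
        if wt_raw < min_raw_reads:
            cls = "not_testable"
        elif mut_rpm <= wt_rpm / fold:
            cls = "dependent"
        else:
            cls = "independent"
        out.append(SiRNALocus(locus, wt_raw, wt_rpm, mut_rpm, cls))
    return out


# -- I/O ---------------------------------------------------------------------


def read_small_rna(path: Union[str, Path]) -> list[str]:
    """Read small RNA sequences from FASTA or FASTQ (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def read_size_count_table(path: Union[str, Path]) -> pd.DataFrame:
    """Per-size count TSV: sample, size, raw_count, genome_mapped_total."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "size", "raw_count", "genome_mapped_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = df[(df["size"] < SIZE_MIN) | (df["size"] > SIZE_MAX)]
    if len(bad):
        raise ValueError(f"sizes outside {SIZE_MIN}-{SIZE_MAX}: {sorted(bad['size'])}")
    return df


def heatmap_matrix(profiles: Sequence[SizeClassProfile]) -> pd.DataFrame:
    """RPM matrix, rows = sizes 18-28, columns = samples (heatmap layout)."""
    data = {p.sample: [p.rpm[s] for s in SIZE_RANGE] for p in profiles}
    return pd.DataFrame(data, index=list(SIZE_RANGE))


def write_enrichment_tsv(
    enrichments: Mapping[str, Mapping[int, float]], handle: TextIO
) -> None:
    """Enrichment TSV, NA for unformable ratios."""
    handle.write("target\tsize\tenrichment\n")
    for target, ratios in enrichments.items():
        for size in SIZE_RANGE:
            v = ratios.get(size, math.nan)
            s = "NA" if (v is None or (isinstance(v, float) and math.isnan(v))) else f"{v:.6g}"
            handle.write(f"{target}\t{size}\t{s}\n")
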