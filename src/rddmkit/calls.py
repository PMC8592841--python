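"""Per-read methylation calling for bisulfite amplicon reads.

Sodium bisulfite converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine is protected.  On the assayed forward strand a
read therefore shows C at a methylated site and T at an unmethylated
one; on a reverse-strand amplicon the same information appears as G
(methylated) versus A (unmethylated) in forward coordinates.  Alignment
must treat the converted base as a match, not a mismatch — otherwise
heavily unmethylated reads would be rejected wholesale.

Each mapped read is reduced to an ordered vector of calls over the
amplicon's cytosine sites: M (methylated), U (unmethylated) or AMBIG
(gap, unexpected base, low quality or unaligned).  AMBIG never counts
toward methylated or total coverage, matching standard bisulfite
callers' handling of non-C/T bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .amplicon import Amplicon, Context, Strand

__all__ = [
    "ReadMethylationVector",
    "SiteCountRecord",
    "align_and_call",
    "call_reads",
    "aggregate_site_counts",
    "read_allc_table",
    "write_allc_table",
    "write_call_matrix",
    "read_fastq",
]

CALL_M = "M"
CALL_U = "U"
CALL_AMBIG = "AMBIG"

DEFAULT_MIN_READ_LENGTH = 50
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_BAND = 10
DEFAULT_MIN_QUALITY = 20


@dataclass(frozen=True)
class ReadMethylationVector:
    """One read reduced to per-site methylation calls over an amplicon."""

    read_id: str
    amplicon_name: str
    calls: tuple[str, ...]

    @property
    def n_assayed(self) -> int:
        return sum(1 for c in self.calls if c != CALL_AMBIG)

    @property
    def n_methylated(self) -> int:
        return sum(1 for c in self.calls if c == CALL_M)


@dataclass(frozen=True)
class SiteCountRecord:
    """Aggregate methylated / total read counts at one cytosine (1-based)."""

    amplicon: str
    position: int
    strand: str
    context: Context
    mc_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.mc_count <= self.total_count):
            raise ValueError(
                f"{self.amplicon}:{self.position}: mc_count {self.mc_count} "
                f"outside [0, total_count={self.total_count}]"
            )


# -- alignment ---------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _bisulfite_matrix(assayed_strand: Strand) -> substitution_matrices.Array:
    """Asymmetric scoring: converted bases count as matches.

    Rows index the reference base, columns the read base.  Forward strand:
    read T against reference C is a match (unmethylated, converted); read C
    against reference C is a match (methylated).  Reverse strand amplicons
    show conversion as G->A in forward coordinates, so read A against
    reference G is the converted match.
    """
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = 0.0
            else:
                m[a, b] = 1.0 if a == b else -1.0
    if assayed_strand is Strand.FORWARD:
        m["C", "T"] = 1.0
    else:
        m["G", "A"] = 1.0
    return m


def _make_aligner(assayed_strand: Strand) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _bisulfite_matrix(assayed_strand)
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    # free end-gaps on the amplicon: a read may cover a sub-interval, so the
    # amplicon overhang (gap columns in the query row at the ends) is free
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def _site_call(ref_base: str, read_base: str, assayed_strand: Strand) -> str:
    if assayed_strand is Strand.FORWARD:
        # ref_base is C at every site
        if read_base == "C":
            return CALL_M
        if read_base == "T":
            return CALL_U
        return CALL_AMBIG
    if read_base == "G":
        return CALL_M
    if read_base == "A":
        return CALL_U
    return CALL_AMBIG


def _calls_from_mapping(
    read_seq: str,
    quals: Optional[Sequence[int]],
    amplicon: Amplicon,
    tpos_to_qpos: np.ndarray,
    min_quality: Optional[int],
) -> tuple[list[str], int, int]:
    """Per-site calls plus (mismatches, aligned positions) over non-site bases."""
    strand = amplicon.assayed_strand
    seq = amplicon.sequence
    site_set = set(amplicon.site_positions)
    mismatches = 0
    aligned_nonsite = 0
    for t in range(len(seq)):
        q = tpos_to_qpos[t]
        if q < 0 or t in site_set:
            continue
        ref_base = seq[t]
        read_base = read_seq[q]
        if ref_base == "N" or read_base == "N":
            continue
        aligned_nonsite += 1
        ok = read_base == ref_base
        if not ok and strand is Strand.FORWARD and ref_base == "C":
            ok = read_base == "T"  # unreachable: every forward C is a site
        if not ok and strand is Strand.REVERSE and ref_base == "G":
            ok = read_base == "A"
        if not ok:
            mismatches += 1
    calls = []
    for site in amplicon.sites:
        q = tpos_to_qpos[site.position]
        if q < 0:
            calls.append(CALL_AMBIG)
            continue
        if min_quality is not None and quals is not None and quals[q] < min_quality:
            calls.append(CALL_AMBIG)
            continue
        calls.append(_site_call(seq[site.position], read_seq[q], strand))
    return calls, mismatches, aligned_nonsite


def _alignment_map(alignment, target_len: int) -> np.ndarray:
    """target position -> query position (or -1 at target gaps / overhangs)."""
    mapping = np.full(target_len, -1, dtype=np.int64)
    t_blocks, q_blocks = alignment.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        mapping[ts:te] = np.arange(qs, qe)
    return mapping


def align_and_call(
    read: str,
    amplicon: Amplicon,
    qualities: Optional[Sequence[int]] = None,
    read_id: str = "read",
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    band: int = DEFAULT_BAND,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    min_quality: Optional[int] = DEFAULT_MIN_QUALITY,
) -> Optional[ReadMethylationVector]:
    """Align one read to an amplicon and call methylation at every site.

    The read is tried in both orientations (as-is and reverse-complement)
    with bisulfite-aware semi-global affine alignment; the better-scoring
    orientation is kept and a tie rejects the read as ambiguous.  Reads
    whose mismatch fraction over aligned non-site bases exceeds
    ``max_mismatch_frac``, and alignments whose implied diagonal offset
    exceeds ``band`` anywhere, are rejected (None).

    Returns None for unmapped/rejected reads; raises on invalid input.
    """
    if not read:
        raise ValueError("empty read")
    if not amplicon.sites:
        raise ValueError(f"amplicon {amplicon.name!r} has no annotated sites")
    read = read.upper()
    if len(read) < min_read_length:
        return None

    aligner = _make_aligner(amplicon.assayed_strand)
    candidates = []
    for oriented, oq in ((read, qualities), (_revcomp(read), None if qualities is None else list(reversed(qualities)))):
        aln = aligner.align(amplicon.sequence, oriented)
        best = aln[0]
        candidates.append((best.score, oriented, oq, best))
    (s0, r0, q0, a0), (s1, r1, q1, a1) = candidates
    if s0 == s1:
        return None  # orientation ambiguous
    score, oriented, oq, best = candidates[0] if s0 > s1 else candidates[1]

    mapping = _alignment_map(best, len(amplicon.sequence))
    aligned = np.nonzero(mapping >= 0)[0]
    if aligned.size == 0:
        return None
    offsets = aligned - mapping[aligned]
    if np.ptp(offsets) > band:
        return None
    calls, mismatches, aligned_nonsite = _calls_from_mapping(
        oriented, oq, amplicon, mapping, min_quality
    )
    if aligned_nonsite > 0 and mismatches / aligned_nonsite > max_mismatch_frac:
        return None
    return ReadMethylationVector(read_id, amplicon.name, tuple(calls))


# -- vectorized fast path ----------------------------------------------------


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """(n_reads, length) uint8 array of ASCII codes; sequences equal length."""
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def _call_full_length_batch(
    reads: Sequence[str],
    ids: Sequence[str],
    amplicon: Amplicon,
    max_mismatch_frac: float,
) -> list[Optional[ReadMethylationVector]]:
    """Gap-free calling for reads exactly the amplicon's length.

    Semantics match align_and_call for alignments without indels: both
    orientations are scored positionally with bisulfite-aware matching,
    the better orientation kept (tie -> reject), the non-site mismatch
    fraction enforced, and per-site calls made by the same base rules.
    """
    seq = amplicon.sequence
    n = len(seq)
    ref = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    fwd = _encode(reads)
    rc = _encode([_revcomp(r) for r in reads])

    strand = amplicon.assayed_strand
    conv_from = ord("C") if strand is Strand.FORWARD else ord("G")
    conv_to = ord("T") if strand is Strand.FORWARD else ord("A")

    def score(mat: np.ndarray) -> np.ndarray:
        match = mat == ref
        bis = (ref == conv_from) & (mat == conv_to)
        anyn = (mat == ord("N")) | (ref == ord("N"))
        return np.where(anyn, 0, np.where(match | bis, 1, -1)).sum(axis=1)

    s_fwd, s_rc = score(fwd), score(rc)
    use_rc = s_rc > s_fwd
    tie = s_rc == s_fwd
    chosen = np.where(use_rc[:, None], rc, fwd)

    site_pos = np.asarray(amplicon.site_positions)
    nonsite = np.ones(n, dtype=bool)
    nonsite[site_pos] = False
    nonsite &= ref != ord("N")

    ns_ref = ref[nonsite]
    ns = chosen[:, nonsite]
    informative = ns != ord("N")
    mm = (ns != ns_ref) & informative
    if strand is Strand.REVERSE:
        mm &= ~((ns_ref == ord("G")) & (ns == ord("A")))
    denom = informative.sum(axis=1)
    frac = np.where(denom > 0, mm.sum(axis=1) / np.maximum(denom, 1), 0.0)
    reject = tie | (frac > max_mismatch_frac)

    at_sites = chosen[:, site_pos]
    m_code = ord("C") if strand is Strand.FORWARD else ord("G")
    u_code = ord("T") if strand is Strand.FORWARD else ord("A")
    call_codes = np.where(
        at_sites == m_code, 0, np.where(at_sites == u_code, 1, 2)
    )

    lut = (CALL_M, CALL_U, CALL_AMBIG)
    out: list[Optional[ReadMethylationVector]] = []
    for i, rid in enumerate(ids):
        if reject[i]:
            out.append(None)
            continue
        out.append(
            ReadMethylationVector(
                rid, amplicon.name, tuple(lut[c] for c in call_codes[i])
            )
        )
    return out


def call_reads(
    reads: Iterable[tuple[str, str, Optional[Sequence[int]]]],
    amplicon: Amplicon,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    band: int = DEFAULT_BAND,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    min_quality: Optional[int] = DEFAULT_MIN_QUALITY,
) -> list[ReadMethylationVector]:
    """Call a collection of (read_id, sequence, qualities) against one amplicon.

    Full-length reads with no quality filtering requested go through a
    vectorized gap-free path; everything else through the pairwise aligner.
    Unmapped/rejected reads are dropped.
    """
    batch_reads: list[str] = []
    batch_ids: list[str] = []
    results: list[ReadMethylationVector] = []
    amp_len = len(amplicon.sequence)
    for read_id, seq, quals in reads:
        seq = seq.upper()
        if len(seq) < min_read_length:
            continue
        if quals is not None and (min_quality is None or min(quals) >= min_quality):
            # no base can fail the threshold; qualities are irrelevant
            quals = None
        if len(seq) == amp_len and quals is None:
            batch_ids.append(read_id)
            batch_reads.append(seq)
        else:
            vec = align_and_call(
                seq,
                amplicon,
                qualities=quals,
                read_id=read_id,
                max_mismatch_frac=max_mismatch_frac,
                band=band,
                min_read_length=min_read_length,
                min_quality=min_quality,
            )
            if vec is not None:
                results.append(vec)
    if batch_reads:
        for vec in _call_full_length_batch(
            batch_reads, batch_ids, amplicon, max_mismatch_frac
        ):
            if vec is not None:
                results.append(vec)
    return results


# -- aggregation and allC I/O ------------------------------------------------


def _collapse_context(trinuc: str) -> Context:
    """Collapse a trinucleotide context string to CG / CHG / CHH."""
    t = trinuc.upper()
    if len(t) >= 2 and t[0] == "C":
        if t[1] == "G":
            return Context.CG
        if len(t) >= 3 and t[2] == "G":
            return Context.CHG
        return Context.CHH
    if t in {"CG", "CHG", "CHH"}:
        return Context(t)
    return Context.UNDEFINED


def aggregate_site_counts(
    vectors: Sequence[ReadMethylationVector], amplicon: Amplicon
) -> list[SiteCountRecord]:
    """Pool per-read calls into per-site methylated / total counts.

    AMBIG calls contribute to neither count.  Positions serialize 1-based.
    """
    names = {v.amplicon_name for v in vectors}
    if names and names != {amplicon.name}:
        raise ValueError(f"vectors from mixed amplicons: {sorted(names)}")
    n_sites = len(amplicon.sites)
    mc = np.zeros(n_sites, dtype=np.int64)
    total = np.zeros(n_sites, dtype=np.int64)
    for v in vectors:
        if len(v.calls) != n_sites:
            raise ValueError(
                f"read {v.read_id}: {len(v.calls)} calls for {n_sites} sites"
            )
        for j, c in enumerate(v.calls):
            if c == CALL_M:
                mc[j] += 1
                total[j] += 1
            elif c == CALL_U:
                total[j] += 1
    strand_sym = "+" if amplicon.assayed_strand is Strand.FORWARD else "-"
    return [
        SiteCountRecord(
            amplicon.name,
            site.position + 1,
            strand_sym,
            site.context,
            int(mc[j]),
            int(total[j]),
        )
        for j, site in enumerate(amplicon.sites)
    ]


def read_allc_table(path: Union[str, Path]) -> list[SiteCountRecord]:
    """Parse an allC-style per-cytosine TSV.

    Columns: sequence name, 1-based position, strand, trinucleotide
    context, methylated-read count, total-read count[, binomial flag].
    Trinucleotides are collapsed to CG / CHG / CHH by the H rule.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("chrom", "amplicon", "chr"):  # header
                continue
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected >=6 fields, got {len(fields)}")
            try:
                pos = int(fields[1])
                mc = int(fields[4])
                total = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if mc > total:
                raise ValueError(
                    f"line {lineno}: mc_count {mc} exceeds total_count {total}"
                )
            records.append(
                SiteCountRecord(
                    fields[0], pos, fields[2], _collapse_context(fields[3]), mc, total
                )
            )
    return records


def write_allc_table(
    records: Iterable[SiteCountRecord],
    handle: TextIO,
    amplicon: Optional[Amplicon] = None,
) -> None:
    """Write allC-style TSV; the binomial-call flag column is carried as 1."""
    trinucs = {}
    if amplicon is not None:
        seq = amplicon.sequence
        for site in amplicon.sites:
            i = site.position
            if amplicon.assayed_strand is Strand.FORWARD:
                tri = seq[i : i + 3]
            else:
                tri = _revcomp(seq[max(0, i - 2) : i + 1])
            trinucs[i + 1] = tri.ljust(3, "N")
    for rec in records:
        tri = trinucs.get(rec.position, rec.context.value)
        handle.write(
            f"{rec.amplicon}\t{rec.position}\t{rec.strand}\t{tri}\t"
            f"{rec.mc_count}\t{rec.total_count}\t1\n"
        )


def write_call_matrix(
    vectors: Iterable[ReadMethylationVector], amplicon: Amplicon, handle: TextIO
) -> None:
    """Per-read call matrix TSV: read_id then one M/U/. column per site."""
    header = ["read_id"] + [str(s.position + 1) for s in amplicon.sites]
    handle.write("\t".join(header) + "\n")
    sym = {CALL_M: "M", CALL_U: "U", CALL_AMBIG: "."}
    for v in vectors:
        handle.write(v.read_id + "\t" + "\t".join(sym[c] for c in v.calls) + "\n")


def read_fastq(
    path: Union[str, Path]
) -> Iterator[tuple[str, str, Optional[list[int]]]]:
    """Yield (read_id, sequence, qualities) from FASTQ, gzipped or plain."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), rec.letter_annotations.get("phred_quality")
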