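"""Synthetic data generators with known ground truth.

The bisulfite generator models an amplicon library as a two-component
mixture.  A fraction pi of molecules are RdDM-methylated: their
cytosines are methylated at context-specific rates (m_cg, m_chg, m_chh)
with first-order Markov persistence rho along consecutive sites, so
methylated sites cluster into runs the way de novo RdDM writes them
(rho = 0 recovers i.i.d. sites, rho -> 1 fully blocky molecules).  The
remaining 1 - pi molecules are unmethylated; their only "methylation" is
sodium-bisulfite non-conversion at rate epsilon (< 1% in practice) —
sporadic, spatially independent false positives.  Every unmethylated
site, on either component, escapes conversion with probability epsilon,
because non-conversion is a property of the chemistry, not of the
molecule class.

Markov transitions are P(M | prev M) = m + rho*(1-m) and
P(M | prev U) = (1-rho)*m, which preserve the per-site marginal m
exactly when the rate is constant along the read; with context-varying
rates the marginal is a rho-weighted average of upstream rates.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, TextIO, Union

import numpy as np

from .amplicon import Amplicon, Context, Strand
from .chip import QPCRMeasurement, QPCRRole

__all__ = [
    "BisulfiteSimConfig",
    "BisulfiteGroundTruth",
    "simulate_bisulfite_reads",
    "simulate_small_rna_library",
    "simulate_qpcr",
    "simulate_enrichment_table",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BisulfiteSimConfig:
    """Parameters of the two-component bisulfite amplicon model.

    Defaults describe a wild-type-like library: most molecules carry
    dense RdDM methylation (high CG, intermediate CHG/CHH rates, strong
    clustering) over a sub-percent non-conversion floor.
    """

    amplicon: Amplicon
    n_reads: int = 1000
    pi: float = 0.8            # fraction of RdDM-methylated molecules
    m_cg: float = 0.85
    m_chg: float = 0.65
    m_chh: float = 0.45
    rho: float = 0.5           # Markov persistence of the methylated state
    epsilon: float = 0.005     # bisulfite non-conversion rate
    seq_error: float = 0.001   # per-base uniform miscall rate
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("pi", "m_cg", "m_chg", "m_chh", "rho", "epsilon", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")

    def context_rate(self, context: Context) -> float:
        if context is Context.CG:
            return self.m_cg
        if context is Context.CHG:
            return self.m_chg
        # CHH and boundary/UNDEFINED sites use the CHH rate
        return self.m_chh

    def expected_call_rate(self, context: Context) -> float:
        """Closed-form expected fraction of M among M/U calls at a context.

        P(site emits the methylated base) = pi*m + (1 - pi*m)*epsilon:
        a site reads methylated if its molecule methylated it, or if it is
        unmethylated (on either component) and escaped conversion.
        Sequencing error shuffles the emitted base uniformly; the call
        rate conditions on the read base being one of the two callable
        bases.  Exact for context-homogeneous rates; with mixed rates the
        Markov chain perturbs per-site marginals near context switches.
        """
        m = self.context_rate(context)
        p_mbase = self.pi * m + (1.0 - self.pi * m) * self.epsilon
        e = self.seq_error
        p_call_m = p_mbase * (1 - e) + (1 - p_mbase) * (e / 3)
        p_call_u = (1 - p_mbase) * (1 - e) + p_mbase * (e / 3)
        return p_call_m / (p_call_m + p_call_u)

    def metadata(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "pi": self.pi,
            "m_cg": self.m_cg,
            "m_chg": self.m_chg,
            "m_chh": self.m_chh,
            "rho": self.rho,
            "epsilon": self.epsilon,
            "seq_error": self.seq_error,
            "seed": self.seed,
            "expected_call_rate": {
                ctx.value: self.expected_call_rate(ctx)
                for ctx in (Context.CG, Context.CHG, Context.CHH)
            },
        }


@dataclass(frozen=True)
class BisulfiteGroundTruth:
    """Per-read component labels and true per-site methylation states."""

    config_metadata: dict
    is_rddm: np.ndarray          # (n_reads,) bool
    true_methylation: np.ndarray  # (n_reads, n_sites) bool

    def to_json(self, handle: TextIO) -> None:
        json.dump(
            {
                "config": self.config_metadata,
                "is_rddm": self.is_rddm.astype(int).tolist(),
                "true_methylation": self.true_methylation.astype(int).tolist(),
            },
            handle,
        )
        handle.write("\n")


def _markov_methylation(
    rng: np.random.Generator, n_reads: int, rates: np.ndarray, rho: float
) -> np.ndarray:
    """(n_reads, n_sites) methylation states with per-site marginal rates."""
    n_sites = rates.size
    states = np.zeros((n_reads, n_sites), dtype=bool)
    if n_sites == 0 or n_reads == 0:
        return states
    u = rng.random((n_reads, n_sites))
    states[:, 0] = u[:, 0] < rates[0]
    for j in range(1, n_sites):
        m = rates[j]
        p = np.where(states[:, j - 1], m + rho * (1.0 - m), (1.0 - rho) * m)
        states[:, j] = u[:, j] < p
    return states


def simulate_bisulfite_reads(
    config: BisulfiteSimConfig,
) -> tuple[list[tuple[str, str, list[int]]], BisulfiteGroundTruth]:
    """Draw a bisulfite amplicon library under the two-component model.

    Returns FASTQ-ready (read_id, sequence, qualities) tuples — reads are
    full amplicon length with constant Q37 — plus the ground truth.
    """
    amp = config.amplicon
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    site_pos = np.asarray(amp.site_positions, dtype=np.int64)
    rates = np.asarray([config.context_rate(s.context) for s in amp.sites])

    is_rddm = rng.random(n) < config.pi
    true_meth = np.zeros((n, len(amp.sites)), dtype=bool)
    n_rddm = int(is_rddm.sum())
    if n_rddm:
        true_meth[is_rddm] = _markov_methylation(rng, n_rddm, rates, config.rho)

    # non-conversion: every unmethylated site reads methylated w.p. epsilon
    escaped = (~true_meth) & (rng.random(true_meth.shape) < config.epsilon)
    reads_methylated_base = true_meth | escaped

    ref = np.frombuffer(amp.sequence.encode("ascii"), dtype=np.uint8)
    mat = np.tile(ref, (n, 1))
    if amp.assayed_strand is Strand.FORWARD:
        m_base, u_base = ord("C"), ord("T")
    else:
        m_base, u_base = ord("G"), ord("A")
    if site_pos.size:
        mat[:, site_pos] = np.where(reads_methylated_base, m_base, u_base)

    if config.seq_error > 0:
        err = rng.random(mat.shape) < config.seq_error
        # uniform substitution to one of the three other bases
        shift = rng.integers(1, 4, size=mat.shape)
        idx = np.searchsorted(_BASES, mat)
        # non-ACGT (N) positions left untouched
        valid = err & (idx < 4) & (_BASES[np.clip(idx, 0, 3)] == mat)
        mat[valid] = _BASES[(idx[valid] + shift[valid]) % 4]

    quals = [37] * len(amp.sequence)
    reads = [
        (f"{amp.name}_read{i}", mat[i].tobytes().decode("ascii"), quals)
        for i in range(n)
    ]
    truth = BisulfiteGroundTruth(config.metadata(), is_rddm, true_meth)
    return reads, truth


def write_fastq(
    reads: Sequence[tuple[str, str, Sequence[int]]], handle: TextIO
) -> None:
    for read_id, seq, quals in reads:
        qual_str = "".join(chr(q + 33) for q in quals)
        handle.write(f"@{read_id}\n{seq}\n+\n{qual_str}\n")


def simulate_small_rna_library(
    source: str,
    size_spectrum: Mapping[int, int],
    background_total: int = 0,
    seed: int = 1,
) -> tuple[list[str], int]:
    """Draw small RNAs as uniform random substrings of a source sequence.

    For each size class the requested number of reads is sampled at
    uniform random start positions on a uniform random strand.  The
    normalization denominator is the sum of the spectrum plus
    ``background_total`` reads mapping elsewhere in the genome.
    """
    rng = np.random.default_rng(seed)
    source = source.upper()
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = source.translate(comp)[::-1]
    reads: list[str] = []
    for size in sorted(size_spectrum):
        count = size_spectrum[size]
        if not 18 <= size <= 28:
            raise ValueError(f"size {size} outside 18-28")
        if count < 0:
            raise ValueError("negative count")
        if len(source) < size:
            raise ValueError(f"source shorter than read size {size}")
        starts = rng.integers(0, len(source) - size + 1, size=count)
        strands = rng.random(count) < 0.5
        for s, minus in zip(starts, strands):
            tpl = rc if minus else source
            reads.append(tpl[s : s + size])
    total = len(reads) + int(background_total)
    return reads, total


def simulate_qpcr(
    true_percent_input: float,
    dilution_factor: float,
    noise_sd: float = 0.0,
    seed: int = 1,
    ct_100: float = 20.0,
    sample: str = "sim",
    target: str = "locus",
) -> tuple[QPCRMeasurement, QPCRMeasurement]:
    """Generate an (IP, diluted-input) Ct pair consistent with a true percent.

    ct_ip = ct_100 + log2(100/percent) + N(0, noise_sd);
    ct_input_diluted = ct_100 + log2(DF) + N(0, noise_sd).
    With no noise, percent_input inverts exactly.  Gaussian Ct noise
    makes the recovered percent log-normal, with a small positive bias
    in its mean — documented, not corrected.
    """
    if not 0.0 < true_percent_input <= 100.0:
        raise ValueError("true_percent_input must be in (0, 100]")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else np.zeros(2)
    ct_ip = ct_100 + math.log2(100.0 / true_percent_input) + noise[0]
    ct_diluted = ct_100 + math.log2(dilution_factor) + noise[1]
    return (
        QPCRMeasurement(sample, target, ct_ip, QPCRRole.IP),
        QPCRMeasurement(
            sample, target, ct_diluted, QPCRRole.INPUT_DILUTED, dilution_factor
        ),
    )


DEFAULT_FE_PARAMS = {
    # (wt_fe range, mut_fe range) per category; well separated from the
    # fe_min=2 / background_max=1.5 decision boundaries
    "fully_dependent": ((3.0, 8.0), (0.2, 1.2)),
    "partially_dependent": ((3.0, 8.0), (2.5, 7.0)),
    "not_occupied": ((0.2, 1.6), (0.2, 1.6)),
}


def simulate_enrichment_table(
    n_loci: int,
    category_mix: Mapping[str, float],
    fe_params: Optional[Mapping[str, tuple[tuple[float, float], tuple[float, float]]]] = None,
    seed: int = 1,
    fe_min: float = 2.0,
    background_max: float = 1.5,
) -> tuple[list[tuple[str, float, float]], list[str]]:
    """Draw (locus, wt_fe, mut_fe) rows with known dependence categories.

    Fold enrichments are uniform within per-category ranges.  Ranges that
    straddle a classification threshold trigger a generation warning —
    labels drawn from such ranges are not guaranteed recoverable.
    Returns the rows and the true category labels.
    """
    if abs(sum(category_mix.values()) - 1.0) > 1e-9:
        raise ValueError("category_mix fractions must sum to 1")
    params = dict(DEFAULT_FE_PARAMS)
    if fe_params:
        params.update(fe_params)
    for cat, frac in category_mix.items():
        if cat not in params:
            raise ValueError(f"unknown category {cat!r}")
        (wt_lo, wt_hi), (mut_lo, mut_hi) = params[cat]
        straddles = (
            (cat == "not_occupied" and wt_hi >= fe_min)
            or (cat != "not_occupied" and wt_lo < fe_min)
            or (cat == "fully_dependent" and mut_hi > background_max)
            or (cat == "partially_dependent" and mut_lo < fe_min)
        )
        if frac > 0 and straddles:
            warnings.warn(
                f"fe_params for {cat!r} straddle a classification threshold",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    cats = list(category_mix)
    counts = np.floor(np.asarray([category_mix[c] for c in cats]) * n_loci).astype(int)
    # distribute the rounding remainder deterministically
    for i in range(n_loci - counts.sum()):
        counts[i % len(counts)] += 1
    rows: list[tuple[str, float, float]] = []
    labels: list[str] = []
    k = 0
    for cat, count in zip(cats, counts):
        (wt_lo, wt_hi), (mut_lo, mut_hi) = params[cat]
        wt = rng.uniform(wt_lo, wt_hi, size=count)
        mut = rng.uniform(mut_lo, mut_hi, size=count)
        for w, m in zip(wt, mut):
            rows.append((f"locus_{k}", float(w), float(m)))
            labels.append(cat)
            k += 1
    return rows, labels
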