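"""ChIP-qPCR percent-input arithmetic and fold-enrichment classification.

Percent input quantifies immunoprecipitated DNA against the pre-IP
chromatin: the diluted input's Ct is first shifted to a virtual 100%
input (each PCR cycle is a doubling, so subtracting log2 of the dilution
factor rescales it), then the IP is expressed as 2^-dCt relative to that
100% reference.  Background from a null-mutant IP — e.g. the antibody's
target protein knocked out — is averaged per PCR target and subtracted.

Fold enrichment (IP/mock) feeds the SUVH2/SUVH9-dependence rule for Pol
V-occupied loci: occupied at >= 2-fold in wild type; fully dependent
when the mutant falls to background, partially dependent when the mutant
itself retains >= 2-fold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "QPCRRole",
    "QPCRMeasurement",
    "LocusEnrichment",
    "DependenceCategory",
    "percent_input",
    "subtract_background",
    "relative_expression",
    "fold_enrichment_from_counts",
    "classify_suvh_dependence",
    "read_qpcr_table",
]

DEFAULT_FE_MIN = 2.0
DEFAULT_BACKGROUND_MAX = 1.5


class QPCRRole(str, enum.Enum):
    INPUT_DILUTED = "input_diluted"
    IP = "ip"
    IGG = "igg"
    GENE_OF_INTEREST = "gene_of_interest"
    HOUSEKEEPING = "housekeeping"


@dataclass(frozen=True)
class QPCRMeasurement:
    sample: str
    target: str
    ct: float
    role: QPCRRole
    dilution_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"{self.sample}/{self.target}: Ct must be finite positive")
        if self.role is QPCRRole.INPUT_DILUTED:
            if self.dilution_factor is None or self.dilution_factor <= 1:
                raise ValueError(
                    f"{self.sample}/{self.target}: diluted input needs dilution_factor > 1"
                )


class DependenceCategory(str, enum.Enum):
    FULLY_DEPENDENT = "fully_dependent"
    PARTIALLY_DEPENDENT = "partially_dependent"
    NOT_OCCUPIED = "not_occupied"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LocusEnrichment:
    locus: str
    wt_fe: float
    mut_fe: float
    category: DependenceCategory


def percent_input(
    ct_ip: float, ct_input_diluted: float, dilution_factor: float
) -> float:
    """Percent input from IP and diluted-input Ct values.

    ct_100 = ct_input_diluted - log2(dilution_factor);
    percent = 100 * 2^-(ct_ip - ct_100).

    A 3% input aliquot has dilution_factor 100/3; an IP whose Ct equals
    the virtual 100%-input Ct reads exactly 100%.
    """
    for name, v in (("ct_ip", ct_ip), ("ct_input_diluted", ct_input_diluted)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    ct_100 = ct_input_diluted - math.log2(dilution_factor)
    return 100.0 * 2.0 ** (-(ct_ip - ct_100))


@dataclass(frozen=True)
class CorrectedPercent:
    target: str
    raw: float
    background_mean: float
    corrected: float   # clipped at 0
    clipped: bool

    @property
    def unclipped(self) -> float:
        return self.raw - self.background_mean


def subtract_background(
    percent_values: Mapping[str, float],
    background_values: Mapping[str, Sequence[float]],
) -> dict[str, CorrectedPercent]:
    """Subtract per-target mean null-mutant background from percent inputs.

    Percent input cannot be negative, so the corrected value clips at 0
    with a flag; the unclipped difference stays available for audit.
    A target with no background measurement is an error naming the target.
    """
    out = {}
    for target, value in percent_values.items():
        if target not in background_values or len(background_values[target]) == 0:
            raise KeyError(f"no background measurements for target {target!r}")
        bg = background_values[target]
        mean_bg = sum(bg) / len(bg)
        diff = value - mean_bg
        out[target] = CorrectedPercent(
            target, value, mean_bg, max(0.0, diff), diff < 0
        )
    return out


def relative_expression(
    ct_goi: float,
    ct_housekeeping: float,
    ct_goi_ref: float,
    ct_housekeeping_ref: float,
) -> float:
    """2^-ddCt relative expression against a housekeeping gene and a
    reference sample: ddCt = (ct_goi - ct_hk) - (ct_goi_ref - ct_hk_ref)."""
    for v in (ct_goi, ct_housekeeping, ct_goi_ref, ct_housekeeping_ref):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_goi - ct_housekeeping) - (ct_goi_ref - ct_housekeeping_ref)
    return 2.0 ** (-ddct)


def fold_enrichment_from_counts(
    ip_reads: float, ip_total: float, mock_reads: float, mock_total: float
) -> float:
    """Fold enrichment = (IP reads / IP library total) / (mock reads / mock total).

    NaN when the mock has no reads at the locus (ratio unformable).
    """
    if min(ip_total, mock_total) <= 0:
        raise ValueError("library totals must be positive")
    if ip_reads < 0 or mock_reads < 0:
        raise ValueError("negative read counts")
    mock_frac = mock_reads / mock_total
    if mock_frac == 0:
        return math.nan
    return (ip_reads / ip_total) / mock_frac


def classify_suvh_dependence(
    loci: Iterable[tuple[str, float, float]],
    fe_min: float = DEFAULT_FE_MIN,
    background_max: float = DEFAULT_BACKGROUND_MAX,
) -> list[LocusEnrichment]:
    """Categorize Pol V-occupied loci by SUVH2/SUVH9 dependence.

    Input tuples (locus, wt_fe, mut_fe) carry replicate-averaged IP/mock
    fold enrichments.  not_occupied when wt_fe < fe_min; with occupancy,
    fully_dependent when mut_fe <= background_max, partially_dependent
    when mut_fe >= fe_min, and an explicit indeterminate bucket for
    background_max < mut_fe < fe_min (a gray zone the thresholds cannot
    resolve — surfacing it beats silently forcing a side).
    """
    if background_max > fe_min:
        raise ValueError("background_max must not exceed fe_min")
    out = []
    for locus, wt_fe, mut_fe in loci:
        if wt_fe < 0 or mut_fe < 0:
            raise ValueError(f"{locus}: negative fold enrichment")
        if wt_fe < fe_min:
            cat = DependenceCategory.NOT_OCCUPIED
        elif mut_fe <= background_max:
            cat = DependenceCategory.FULLY_DEPENDENT
        elif mut_fe >= fe_min:
            cat = DependenceCategory.PARTIALLY_DEPENDENT
        else:
            cat = DependenceCategory.INDETERMINATE
        out.append(LocusEnrichment(locus, wt_fe, mut_fe, cat))
    return out


def read_qpcr_table(path: Union[str, Path]) -> list[QPCRMeasurement]:
    """qPCR CSV/TSV: sample, target, role, ct[, dilution_factor]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "target", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        df_val = getattr(row, "dilution_factor", None)
        if df_val is not None and (isinstance(df_val, float) and math.isnan(df_val)):
            df_val = None
        out.append(
            QPCRMeasurement(
                str(row.sample), str(row.target), float(row.ct),
                QPCRRole(str(row.role)), df_val,
            )
        )
    return out
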