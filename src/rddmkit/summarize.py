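"""Pooled methylation summaries with Wilson confidence intervals.

Methylation per context is the pooled-count estimator 100 * sum(mc) /
sum(total): the confidence interval's number of trials is the sum of
read coverage over all assayed cytosines, so a deeply covered amplicon
gets a proportionally tighter interval.  The alternative — averaging
per-site fractions — is available behind a flag but is not the default.

The non-conversion rate epsilon is estimated the same way from a
biologically unmethylated control amplicon: every methylated call there
is a cytosine that escaped bisulfite conversion.  No correction for
epsilon is applied to reported percentages; epsilon is reported
alongside them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .calls import SiteCountRecord
from .amplicon import Context

__all__ = [
    "ContextSummary",
    "MethylationSummary",
    "ConversionReport",
    "wilson_interval",
    "summarize_methylation",
    "conversion_rate",
    "write_summary_tsv",
    "write_summary_json",
]

DEFAULT_Z = 1.959964  # two-sided 95% normal quantile
EPSILON_CEILING = 0.05  # warn if a "control" locus looks methylated

ALL = "ALL"


def wilson_interval(k: float, n: float, z: float = DEFAULT_Z) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as fractions.

    center  = (p + z^2/2n) / (1 + z^2/n)
    halfwidth = z/(1 + z^2/n) * sqrt(p(1-p)/n + z^2/4n^2)

    The lower bound is exactly 0 at k = 0 and the upper exactly 1 at
    k = n, unlike the Wald interval which degenerates there.  k may be
    non-integral (effective counts from cluster-level rescaling).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if z <= 0:
        raise ValueError("z must be positive")
    p = k / n
    z2n = z * z / n
    denom = 1.0 + z2n
    center = (p + z2n / 2.0) / denom
    half = (z / denom) * math.sqrt(p * (1.0 - p) / n + z2n / (4.0 * n))
    low = max(0.0, center - half)
    high = min(1.0, center + half)
    if k == 0:
        low = 0.0
    if k == n:
        high = 1.0
    return low, high


@dataclass(frozen=True)
class ContextSummary:
    context: str
    mc_total: int
    cov_total: int
    percent: float
    ci_low: float   # percent scale
    ci_high: float  # percent scale


@dataclass(frozen=True)
class MethylationSummary:
    """Per-context pooled methylation for one amplicon."""

    amplicon: str
    contexts: dict[str, ContextSummary]
    z: float = DEFAULT_Z
    estimator: str = "pooled"

    def __getitem__(self, context: str) -> ContextSummary:
        return self.contexts[context]

    def percent(self, context: str = ALL) -> Optional[float]:
        cs = self.contexts.get(context)
        return None if cs is None else cs.percent


@dataclass(frozen=True)
class ConversionReport:
    """Bisulfite conversion efficiency from an unmethylated control locus."""

    control_locus: str
    nonconversion_rate: float
    mc_total: int
    cov_total: int
    warning: Optional[str] = None

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.nonconversion_rate


def _pooled(records: Sequence[SiteCountRecord]) -> tuple[int, int]:
    return sum(r.mc_count for r in records), sum(r.total_count for r in records)


def summarize_methylation(
    records: Sequence[SiteCountRecord],
    z: float = DEFAULT_Z,
    estimator: str = "pooled",
) -> MethylationSummary:
    """Summarize per-cytosine counts into per-context percentages with CIs.

    UNDEFINED-context sites are excluded from every stratum including ALL.
    A context with zero pooled coverage is reported as absent, not as 0%.

    estimator "pooled" (default) uses 100*sum(mc)/sum(total) with the
    Wilson CI on the pooled counts; "per_site" averages per-site fractions
    (CI still computed on the pooled counts, for display only).
    """
    if not records:
        raise ValueError("no records")
    amplicons = {r.amplicon for r in records}
    if len(amplicons) > 1:
        raise ValueError(f"records from multiple amplicons: {sorted(amplicons)}")
    if estimator not in ("pooled", "per_site"):
        raise ValueError(f"unknown estimator {estimator!r}")

    usable = [r for r in records if r.context is not Context.UNDEFINED]
    strata: dict[str, list[SiteCountRecord]] = {
        Context.CG.value: [],
        Context.CHG.value: [],
        Context.CHH.value: [],
        ALL: [],
    }
    for r in usable:
        strata[r.context.value].append(r)
        strata[ALL].append(r)

    contexts: dict[str, ContextSummary] = {}
    for name, recs in strata.items():
        mc, cov = _pooled(recs)
        if cov == 0:
            continue
        if estimator == "pooled":
            pct = 100.0 * mc / cov
        else:
            fracs = [r.mc_count / r.total_count for r in recs if r.total_count > 0]
            pct = 100.0 * sum(fracs) / len(fracs)
        low, high = wilson_interval(mc, cov, z)
        contexts[name] = ContextSummary(name, mc, cov, pct, 100.0 * low, 100.0 * high)
    return MethylationSummary(amplicons.pop(), contexts, z, estimator)


def conversion_rate(
    control_records: Sequence[SiteCountRecord],
    epsilon_ceiling: float = EPSILON_CEILING,
) -> ConversionReport:
    """Estimate the non-conversion rate from an unmethylated control amplicon.

    epsilon = pooled mc/total over all contexts (UNDEFINED included — a
    conversion failure is context-blind).  If epsilon exceeds the
    plausibility ceiling a warning is attached, never an error: the
    control could be genuinely methylated in some genotype, and the
    operator should see that rather than crash.
    """
    if not control_records:
        raise ValueError("no control records")
    mc, cov = _pooled(control_records)
    if cov == 0:
        raise ValueError("control amplicon has zero total coverage")
    eps = mc / cov
    warning = None
    if eps > epsilon_ceiling:
        warning = (
            f"non-conversion rate {eps:.4f} exceeds plausibility ceiling "
            f"{epsilon_ceiling}; control locus may be methylated"
        )
    return ConversionReport(control_records[0].amplicon, eps, mc, cov, warning)


def write_summary_tsv(summaries: Iterable[MethylationSummary], handle: TextIO) -> None:
    handle.write("amplicon\tcontext\tmc\tn\tpercent\tci_low\tci_high\n")
    for s in summaries:
        for name in ("CG", "CHG", "CHH", ALL):
            cs = s.contexts.get(name)
            if cs is None:
                continue
            handle.write(
                f"{s.amplicon}\t{name}\t{cs.mc_total}\t{cs.cov_total}\t"
                f"{cs.percent:.4f}\t{cs.ci_low:.4f}\t{cs.ci_high:.4f}\n"
            )


def write_summary_json(
    summaries: Iterable[MethylationSummary],
    handle: TextIO,
    conversion: Optional[ConversionReport] = None,
) -> None:
    payload: dict = {"amplicons": {}}
    for s in summaries:
        payload["amplicons"][s.amplicon] = {
            "z": s.z,
            "estimator": s.estimator,
            "contexts": {
                name: {
                    "mc": cs.mc_total,
                    "n": cs.cov_total,
                    "percent": cs.percent,
                    "ci_low": cs.ci_low,
                    "ci_high": cs.ci_high,
                }
                for name, cs in s.contexts.items()
            },
        }
    if conversion is not None:
        payload["conversion"] = {
            "control_locus": conversion.control_locus,
            "nonconversion_rate": conversion.nonconversion_rate,
            "conversion_rate": conversion.conversion_rate,
            "mc": conversion.mc_total,
            "n": conversion.cov_total,
            "warning": conversion.warning,
        }
    json.dump(payload, handle, indent=2)
    handle.write("\n")
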