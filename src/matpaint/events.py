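"""Event classification, join-site aggregation, error rate, cohort tests.

Each painted haplotype is classified against the expectation that a somatic
TM exon arises from a *single simple joining event*: the anchor donor's
truncated tm segment joined once to the full-length terminal donor's TM
exon (zero joins for the terminal gene itself, which is already complete in
the germline).  Excess exchanges, third donors, and X->Y->X gene-conversion
signatures measure secondary recombination; 0-fission (exconjugant) and
120-fission (mature) cohorts are compared by Pearson homogeneity
chi-square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .painting import Painting


class EventStatsError(ValueError):
    pass


@dataclass(frozen=True)
class EventRecord:
    haplotype_id: str
    n_exchanges: int
    n_distinct_donors: int
    n_gene_conversions: int
    excess_exchanges: int
    is_single_simple_join: bool
    uses_third_donor: bool
    unclassifiable: bool = False
    multiplicity: int = 1


@dataclass(frozen=True)
class JoinRegionSummary:
    side: str
    intervals: tuple[tuple[int, int], ...]
    aggregate_span: Optional[tuple[int, int]]
    span_length: Optional[int]  # open-interval convention, right - left
    span_length_inclusive: Optional[int]  # counting both flanking sites


@dataclass(frozen=True)
class CohortComparison:
    categories: tuple[str, ...]
    counts_0fission: tuple[int, ...]
    counts_120fission: tuple[int, ...]
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ErrorRateEstimate:
    novel_base_count: int
    total_sequenced_bases: int
    rate: float
    reciprocal: Optional[float]  # bp per novel base; None when no novels


def count_gene_conversions(donor_runs: Sequence[str]) -> int:
    """Count X->Y->X signatures over adjacent segments.

    Two consecutive exchanges between the same two donors count as one gene
    conversion; consecutive exchanges through a third donor (X->Y->Z->X) do
    not.  Overlapping signatures (X->Y->X->Y) each count.
    """
    return sum(
        1
        for i in range(len(donor_runs) - 2)
        if donor_runs[i] == donor_runs[i + 2]
    )


def classify(
    painting: Painting,
    anchor_mt: str,
    terminal_mt: str,
    multiplicity: int = 1,
) -> EventRecord:
    """Classify one painted haplotype.

    The minimum necessary exchange count is 1, except for the terminal gene
    (anchor == terminal donor) which is already complete in the germline
    and needs zero.
    """
    if painting.degenerate:
        return EventRecord(
            haplotype_id=painting.haplotype_id,
            n_exchanges=0,
            n_distinct_donors=0,
            n_gene_conversions=0,
            excess_exchanges=0,
            is_single_simple_join=False,
            uses_third_donor=False,
            unclassifiable=True,
            multiplicity=multiplicity,
        )
    minimum_necessary = 0 if anchor_mt == terminal_mt else 1
    n_exch = painting.n_exchanges
    runs = painting.donor_runs
    n_conv = count_gene_conversions(runs)
    n_distinct = painting.n_distinct_donors
    excess = n_exch - minimum_necessary
    single_simple = excess == 0 and n_distinct <= 2 and n_conv == 0
    return EventRecord(
        haplotype_id=painting.haplotype_id,
        n_exchanges=n_exch,
        n_distinct_donors=n_distinct,
        n_gene_conversions=n_conv,
        excess_exchanges=excess,
        is_single_simple_join=single_simple,
        uses_third_donor=n_distinct > 2,
        multiplicity=multiplicity,
    )


def aggregate_join_region(
    records: Sequence[EventRecord],
    paintings: Sequence[Painting],
    side: str,
) -> JoinRegionSummary:
    """Minimal consensus interval containing every single-simple-join
    switch interval — the aggregate span within which all primary joins
    on one side occurred."""
    by_id = {p.haplotype_id: p for p in paintings}
    intervals = []
    for rec in records:
        if not rec.is_single_simple_join or rec.n_exchanges == 0:
            continue
        p = by_id.get(rec.haplotype_id)
        if p is None or not p.switch_intervals:
            continue
        intervals.append(p.switch_intervals[0])
    if not intervals:
        return JoinRegionSummary(side, (), None, None, None)
    left = min(l for l, _ in intervals)
    right = max(r for _, r in intervals)
    return JoinRegionSummary(
        side=side,
        intervals=tuple(intervals),
        aggregate_span=(left, right),
        span_length=right - left,
        span_length_inclusive=right - left + 1,
    )


def novel_base_rate(
    novel_counts: Sequence[int],
    lengths: Sequence[int],
    multiplicities: Sequence[int],
) -> ErrorRateEstimate:
    """Novel bases per sequenced base pair, weighted per sequenced insert.

    ``novel_counts[i]`` is the number of novel positions in distinct
    haplotype i; each haplotype contributes ``multiplicity`` inserts of
    ``length`` bases.
    """
    total = int(sum(l * m for l, m in zip(lengths, multiplicities)))
    if total <= 0:
        raise EventStatsError("zero total sequenced bases")
    novel = int(sum(c * m for c, m in zip(novel_counts, multiplicities)))
    rate = novel / total
    reciprocal = total / novel if novel > 0 else None
    return ErrorRateEstimate(
        novel_base_count=novel,
        total_sequenced_bases=total,
        rate=rate,
        reciprocal=reciprocal,
    )


def cohort_chi2(
    counts_0fission: dict[str, int] | Sequence[int],
    counts_120fission: dict[str, int] | Sequence[int],
    categories: Optional[Sequence[str]] = None,
) -> CohortComparison:
    """Pearson homogeneity chi-square (no continuity correction) between
    the two cohorts' event-category counts.

    A category with zero total in both cohorts carries no information for
    the test and is dropped with a warning.
    """
    if isinstance(counts_0fission, dict):
        if categories is None:
            categories = sorted(set(counts_0fission) | set(counts_120fission))
        a = [counts_0fission.get(c, 0) for c in categories]
        b = [counts_120fission.get(c, 0) for c in categories]
    else:
        a = list(counts_0fission)
        b = list(counts_120fission)
        if len(a) != len(b):
            raise EventStatsError("cohorts must share the same categories")
        if categories is None:
            categories = [f"cat{i}" for i in range(len(a))]
    keep = [i for i in range(len(a)) if a[i] + b[i] > 0]
    if len(keep) < len(a):
        dropped = [categories[i] for i in range(len(a)) if i not in keep]
        warnings.warn(f"dropping zero-total categories: {dropped}")
    a = [a[i] for i in keep]
    b = [b[i] for i in keep]
    cats = tuple(categories[i] for i in keep)
    if any(x < 0 for x in a + b):
        raise EventStatsError("negative counts")
    table = np.array([a, b])
    if table.sum(axis=1).min() == 0:
        # one cohort entirely empty: no comparison possible
        return CohortComparison(cats, tuple(a), tuple(b), float("nan"), 0, float("nan"))
    if table.shape[1] < 2:
        # a single category: proportions are trivially identical
        return CohortComparison(cats, tuple(a), tuple(b), 0.0, 0, 1.0)
    if np.array_equal(table[0], table[1]):
        # identical vectors: statistic exactly 0, p exactly 1
        return CohortComparison(cats, tuple(a), tuple(b), 0.0, table.shape[1] - 1, 1.0)
    res = stats.chi2_contingency(table, correction=False)
    return CohortComparison(
        categories=cats,
        counts_0fission=tuple(a),
        counts_120fission=tuple(b),
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
    )


def event_category(rec: EventRecord) -> str:
    """Mutually exclusive category used for the cohort comparison."""
    if rec.unclassifiable:
        return "unclassifiable"
    if rec.is_single_simple_join:
        return "single_simple_join"
    if rec.uses_third_donor:
        return "multi_donor"
    return "extra_exchange_or_conversion"


def summarize_cohort(
    records: Sequence[EventRecord], weighted: bool = True
) -> dict[str, float | int | dict[str, int]]:
    """Per-cohort class counts and single-simple-join fractions.

    ``weighted`` counts each haplotype ``multiplicity`` times (per sequenced
    insert, matching the "x N" accounting of the source alignments); the
    unweighted variant counts distinct haplotypes once.
    """
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        w = rec.multiplicity if weighted else 1
        counts[event_category(rec)] = counts.get(event_category(rec), 0) + w
        total += w
    frac = counts.get("single_simple_join", 0) / total if total else math.nan
    return {
        "n": total,
        "category_counts": counts,
        "single_simple_join_fraction": frac,
    }
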