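"""Filtering and aggregation of published cline widths into analysis datasets.

The workflow takes raw :class:`~speclock.records.ClineRecord` rows and the
pair table and produces:

* **dataset A** — one representative width per (hybridizing pair, width
  category), where the eight width categories cross the inference method
  with the marker class/count, and the representative value is a double
  median (per transect first, then across transects);
* **dataset B** — a filtered subset keeping, per pair, a single multi-marker
  width inferred by the *average* method (genome-scale ancestry averages),
  the least method-biased widths available.

Non-diagnostic clines (markers whose alleles are far from fixed between
the lineages, p_min > 0.2 and p_max < 0.8) are excluded first, because
their widths overestimate introgression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

from .records import (
    DISPERSAL_CATEGORIES,
    UNCATEGORIZED,
    AnalysisRow,
    ClineRecord,
    Diagnosticity,
    InferenceMethod,
    LineagePair,
    MarkerGenome,
    ValidationError,
)

__all__ = [
    "assign_dispersal_category",
    "classify_diagnostic",
    "filter_nondiagnostic",
    "assign_width_category",
    "representative_widths",
    "build_dataset_B",
    "build_datasets",
    "Exclusion",
    "WIDTH_CATEGORY_LABELS",
]


def assign_dispersal_category(rate: Optional[float]) -> str:
    """Map a dispersal rate (km/generation) to its bin label A–H.

    Bins are contiguous half-open intervals (lower, upper]; a missing or
    non-positive rate returns the explicit ``uncategorized`` marker.
    """
    if rate is None or not (rate > 0) or math.isnan(rate):
        return UNCATEGORIZED
    for cat in DISPERSAL_CATEGORIES.values():
        if cat.lower_km_gen < rate <= cat.upper_km_gen:
            return cat.label
    return "H"  # rate == inf


def classify_diagnostic(
    p_min: Optional[float],
    p_max: Optional[float],
    rule: str = "and",
    record_id: str = "?",
) -> Diagnosticity:
    """Classify a cline's marker diagnosticity from its tail frequencies.

    A marker is *non-diagnostic* when its cline never approaches parental
    fixation: with the default conjunctive rule, p_min > 0.2 AND
    p_max < 0.8.  ``rule="or"`` switches to the disjunctive reading.
    Missing values give ``UNKNOWN``.
    """
    if p_min is None or p_max is None:
        return Diagnosticity.UNKNOWN
    if p_min > p_max:
        raise ValidationError(f"record {record_id}: p_min={p_min} > p_max={p_max}")
    low, high = p_min > 0.2, p_max < 0.8
    bad = (low and high) if rule == "and" else (low or high)
    return Diagnosticity.NON_DIAGNOSTIC if bad else Diagnosticity.DIAGNOSTIC


@dataclass(frozen=True)
class Exclusion:
    record_id: str
    rule: str


def filter_nondiagnostic(
    records: Sequence[ClineRecord], rule: str = "and"
) -> tuple[list[ClineRecord], list[Exclusion]]:
    """Drop widths based on non-diagnostic markers.

    Single and average widths flagged non-diagnostic are dropped outright.
    A median width is dropped iff a strict majority (> 50%) of the
    single-marker clines on the same pair and transect — its constituent
    clines — are non-diagnostic; with no linked singles it is kept and
    logged as unverifiable.  Returns (survivors, exclusion log); survivors
    plus exclusions partition the input.
    """
    survivors: list[ClineRecord] = []
    log: list[Exclusion] = []

    singles_by_transect: dict[tuple[str, str], list[Diagnosticity]] = {}
    for r in records:
        if r.inference_method is InferenceMethod.SINGLE:
            d = classify_diagnostic(r.p_min, r.p_max, rule, r.record_id)
            singles_by_transect.setdefault((r.pair_id, r.transect_id), []).append(d)

    for r in records:
        d = classify_diagnostic(r.p_min, r.p_max, rule, r.record_id)
        if r.inference_method in (InferenceMethod.SINGLE, InferenceMethod.AVERAGE):
            if d is Diagnosticity.NON_DIAGNOSTIC:
                log.append(Exclusion(r.record_id, "non_diagnostic"))
                continue
        else:  # median
            constituents = singles_by_transect.get((r.pair_id, r.transect_id), [])
            if not constituents:
                warnings.warn(
                    f"median record {r.record_id} has no linked single clines; "
                    "kept as unverifiable"
                )
            else:
                n_bad = sum(c is Diagnosticity.NON_DIAGNOSTIC for c in constituents)
                if n_bad * 2 > len(constituents):  # strict majority; ties keep
                    log.append(Exclusion(r.record_id, "median_majority_non_diagnostic"))
                    continue
        survivors.append(r)
    return survivors, log


#: Category ids 1..8: inference method crossed with marker class/count bins.
WIDTH_CATEGORY_LABELS = {
    1: "single-mitochondrial",
    2: "single-nuclear",
    3: "median 2-10",
    4: "median 11-100",
    5: "median >100",
    6: "average 2-10",
    7: "average 11-100",
    8: "average >100",
}

#: Categories whose widths come from the average (genomic-ancestry) method.
AVERAGE_CATEGORIES = (6, 7, 8)


def _marker_bin(n: int) -> int:
    return 0 if n <= 10 else (1 if n <= 100 else 2)


def assign_width_category(record: ClineRecord) -> int:
    """Assign one of the eight width categories (1..8).

    Singles split by marker genome (mitochondrial vs nuclear; an unknown
    genome falls to nuclear with a warning); median and average widths
    split by marker count bins 2–10, 11–100, > 100.
    """
    if record.inference_method is InferenceMethod.SINGLE:
        if record.marker_genome is MarkerGenome.MITOCHONDRIAL:
            return 1
        if record.marker_genome is MarkerGenome.MIXED:
            warnings.warn(
                f"record {record.record_id}: single width with unknown marker "
                "genome treated as nuclear"
            )
        return 2
    base = 3 if record.inference_method is InferenceMethod.MEDIAN else 6
    return base + _marker_bin(record.n_markers)


def _median(values: Iterable[float]) -> float:
    # statistics.median: even count -> mean of the two central values.
    return float(median(values))


def representative_widths(
    records: Sequence[ClineRecord], pairs: dict[str, LineagePair]
) -> tuple[list[AnalysisRow], list[AnalysisRow]]:
    """Aggregate surviving records into dataset A via the double median.

    Within each (pair, width category): take the median of widths per
    transect first, then the median of the per-transect medians, yielding
    one representative width per pair-category.  Pairs lacking a
    divergence time are emitted to a separate "no-time" list and excluded
    from analysis.  Returns (dataset_A_rows, no_time_rows).
    """
    grouped: dict[tuple[str, int], dict[str, list[ClineRecord]]] = {}
    for r in records:
        cat = assign_width_category(r)
        grouped.setdefault((r.pair_id, cat), {}).setdefault(r.transect_id, []).append(r)

    rows: list[AnalysisRow] = []
    no_time: list[AnalysisRow] = []
    for (pair_id, cat), by_transect in sorted(grouped.items()):
        pair = pairs.get(pair_id)
        if pair is None:
            raise ValidationError(f"records reference unknown pair {pair_id!r}")
        transect_medians = [
            _median([r.width_km for r in recs]) for _, recs in sorted(by_transect.items())
        ]
        width = _median(transect_medians)
        n_max = max(r.n_markers for recs in by_transect.values() for r in recs)
        row = AnalysisRow(
            pair_id=pair_id,
            category_id=str(cat),
            width_km=width,
            divergence_time_ma=pair.divergence_time_ma or float("nan"),
            group=pair.group,
            dispersal_category=pair.dispersal_category or UNCATEGORIZED,
            n_markers_max=n_max,
        )
        (no_time if pair.divergence_time_ma is None else rows).append(row)
    return rows, no_time


def build_dataset_B(dataset_a: Sequence[AnalysisRow]) -> list[AnalysisRow]:
    """Reduce dataset A to one multi-marker average-method width per pair.

    Only the average-method categories qualify.  When a pair has several
    qualifying categories the one with the largest marker count wins;
    exact marker-count ties are resolved by taking the median width across
    the tied categories.
    """
    by_pair: dict[str, list[AnalysisRow]] = {}
    for row in dataset_a:
        if int(row.category_id) in AVERAGE_CATEGORIES and row.n_markers_max >= 2:
            by_pair.setdefault(row.pair_id, []).append(row)

    out: list[AnalysisRow] = []
    for pair_id, rows in sorted(by_pair.items()):
        top = max(r.n_markers_max for r in rows)
        tied = sorted(
            (r for r in rows if r.n_markers_max == top), key=lambda r: int(r.category_id)
        )
        best = tied[0]
        width = best.width_km if len(tied) == 1 else _median([r.width_km for r in tied])
        out.append(
            AnalysisRow(
                pair_id=pair_id,
                category_id="B",
                width_km=width,
                divergence_time_ma=best.divergence_time_ma,
                group=best.group,
                dispersal_category=best.dispersal_category,
                n_markers_max=top,
            )
        )
    return out


def build_datasets(
    records: Sequence[ClineRecord],
    pairs: dict[str, LineagePair],
    diagnostic_rule: str = "and",
) -> tuple[list[AnalysisRow], list[AnalysisRow], list[Exclusion], list[AnalysisRow]]:
    """Run the full workflow: validate, filter, aggregate, subset.

    Returns (dataset_A, dataset_B, exclusion_log, no_time_rows).
    """
    for r in records:
        r.validate()
    for p in pairs.values():
        p.validate()
    survivors, log = filter_nondiagnostic(records, rule=diagnostic_rule)
    dataset_a, no_time = representative_widths(survivors, pairs)
    dataset_b = build_dataset_B(dataset_a)
    return dataset_a, dataset_b, log, no_time
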