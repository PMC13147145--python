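"""Domain types for the hybrid-zone cline-width database.

A *cline* is the sigmoid transition of an allele frequency (or of average
genomic ancestry) along a geographic transect through a hybrid zone; its
width ``w`` (km) measures the geographic extent of introgression between
the two hybridizing lineages.  Published widths come with heterogeneous
metadata — how many markers were used, whether they were mitochondrial or
nuclear, and whether the reported width is a single-locus cline, a median
over many single-locus clines, or a cline fitted to averaged ancestry —
which the downstream filtering and aggregation workflow keys on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class SpeclockError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(SpeclockError):
    """A record or table violates a structural invariant."""


class MarkerGenome(str, Enum):
    MITOCHONDRIAL = "mitochondrial"
    NUCLEAR = "nuclear"
    MIXED = "mixed/unknown"


class InferenceMethod(str, Enum):
    SINGLE = "single"
    MEDIAN = "median"
    AVERAGE = "average"


class Diagnosticity(str, Enum):
    DIAGNOSTIC = "diagnostic"
    NON_DIAGNOSTIC = "non_diagnostic"
    UNKNOWN = "unknown"


#: Taxonomic groups used throughout the analysis.  "Other" pools groups with
#: too few hybrid zones for group-level work.
GROUPS = ("Lissamphibia", "Aves", "Squamata", "Mammalia", "Hexapoda", "Other")


@dataclass(frozen=True)
class DispersalCategory:
    """One of eight per-generation dispersal bins (km/generation).

    The bins tile (0, inf) as contiguous half-open intervals
    ``(lower, upper]``; the representative sigma is the geometric midpoint
    of the interval (open-ended bins extended by the neighbouring
    geometric ratio, sqrt(3)).
    """

    label: str
    lower_km_gen: float
    upper_km_gen: float
    representative_sigma: float


_SQRT3 = math.sqrt(3.0)

#: Dispersal bins A–H.  Bounds quoted in the literature contain small
#: typographic gaps (7.5 vs 7.6 etc.); they are treated as contiguous.
DISPERSAL_CATEGORIES: dict[str, DispersalCategory] = {}
for _label, _lo, _hi in [
    ("A", 0.0, 0.25),
    ("B", 0.25, 0.75),
    ("C", 0.75, 2.5),
    ("D", 2.5, 7.5),
    ("E", 7.5, 25.0),
    ("F", 25.0, 75.0),
    ("G", 75.0, 250.0),
    ("H", 250.0, math.inf),
]:
    if _label == "A":
        _sigma = 0.25 / _SQRT3
    elif _label == "H":
        _sigma = 250.0 * _SQRT3
    else:
        _sigma = math.sqrt(_lo * _hi)
    DISPERSAL_CATEGORIES[_label] = DispersalCategory(_label, _lo, _hi, _sigma)
del _label, _lo, _hi, _sigma

#: Marker used when a dispersal rate is missing or non-positive; never a
#: silent default bin.
UNCATEGORIZED = "uncategorized"


@dataclass(frozen=True)
class ClineRecord:
    """One published cline-width measurement.

    ``p_min``/``p_max`` are the minimum and maximum allele frequencies of
    the fitted cline (usually the parental frequencies); they drive the
    diagnosticity filter.  ``survey_label`` distinguishes repeated surveys
    of the same transect.
    """

    record_id: str
    pair_id: str
    transect_id: str
    width_km: float
    n_markers: int
    marker_genome: MarkerGenome
    inference_method: InferenceMethod
    p_min: Optional[float] = None
    p_max: Optional[float] = None
    survey_label: str = ""

    def validate(self) -> None:
        if not (self.width_km > 0):
            raise ValidationError(f"record {self.record_id}: width_km must be > 0")
        if self.n_markers < 1:
            raise ValidationError(f"record {self.record_id}: n_markers must be >= 1")
        for name, p in (("p_min", self.p_min), ("p_max", self.p_max)):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"record {self.record_id}: {name}={p} outside [0, 1]"
                )
        if self.p_min is not None and self.p_max is not None and self.p_min > self.p_max:
            raise ValidationError(
                f"record {self.record_id}: p_min={self.p_min} > p_max={self.p_max}"
            )
        if self.inference_method is InferenceMethod.SINGLE and self.n_markers != 1:
            raise ValidationError(
                f"record {self.record_id}: single-marker method with "
                f"n_markers={self.n_markers}"
            )
        if (
            self.inference_method in (InferenceMethod.MEDIAN, InferenceMethod.AVERAGE)
            and self.n_markers < 2
        ):
            raise ValidationError(
                f"record {self.record_id}: {self.inference_method.value} method "
                f"requires n_markers >= 2"
            )


@dataclass(frozen=True)
class LineagePair:
    """A hybridizing pair of lineages with its covariates.

    ``divergence_time_ma`` (T) is the age of their split in million years;
    ``dispersal_category`` bins the per-generation dispersal sigma of the
    taxa; ``group`` is the higher taxonomic group.
    """

    pair_id: str
    taxon_a: str
    taxon_b: str
    group: str
    divergence_time_ma: Optional[float] = None
    dispersal_category: Optional[str] = None

    def validate(self) -> None:
        if self.divergence_time_ma is not None and not (self.divergence_time_ma > 0):
            raise ValidationError(
                f"pair {self.pair_id}: divergence_time_ma must be > 0"
            )
        if self.group not in GROUPS:
            raise ValidationError(
                f"pair {self.pair_id}: unknown group {self.group!r}"
            )
        if (
            self.dispersal_category is not None
            and self.dispersal_category != UNCATEGORIZED
            and self.dispersal_category not in DISPERSAL_CATEGORIES
        ):
            raise ValidationError(
                f"pair {self.pair_id}: unknown dispersal category "
                f"{self.dispersal_category!r}"
            )


@dataclass(frozen=True)
class AnalysisRow:
    """One representative cline width per pair (and, for dataset A, per
    width category) — the unit of all correlation/regression work."""

    pair_id: str
    category_id: str  # "1".."8" for dataset A, "B" for dataset B
    width_km: float
    divergence_time_ma: float
    group: str
    dispersal_category: str
    n_markers_max: int
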