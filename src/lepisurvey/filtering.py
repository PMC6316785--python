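"""Cleaning an incidental-occurrence download to the analysis set.

Raw crowd-sourced occurrence exports mix taxa, seasons, places and data
quality.  :func:`filter_records` applies, in a fixed order, the predicate
filters a structured-survey comparison needs — quality flag, butterfly
families, inclusive date window, closed bounding box around the survey
sites, and a coordinate-uncertainty cap — and records a per-stage audit
trail (:class:`FilterReport`).  The individual filters are pure
record-wise predicates, so the final record set does not depend on stage
order, only the report does.

:func:`reconcile_taxonomy` maps platform-specific or misapplied names to
the accepted names used by the structured surveys (e.g. *Paratrytone
melane* → *Poanes melane*; records of *Papilio rumiko* arriving
misclassified as *Zerynthia rumina*).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .survey import OccurrenceRecord

logger = logging.getLogger(__name__)

#: The butterfly families (superfamily Papilionoidea, sensu lato).
BUTTERFLY_FAMILIES = frozenset(
    {
        "Hesperiidae",
        "Papilionidae",
        "Pieridae",
        "Nymphalidae",
        "Lycaenidae",
        "Riodinidae",
    }
)

#: Name corrections needed to align incidental records with survey taxonomy.
DEFAULT_SYNONYMS = {
    "Paratrytone melane": "Poanes melane",
    "Zerynthia rumina": "Papilio rumiko",
}

Bbox = tuple[float, float, float, float]  # (lat_min, lat_max, lon_min, lon_max)


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the occurrence-cleaning pipeline.

    Dates and the bounding box are inclusive (closed) on both ends.
    ``max_uncertainty_m`` defaults to 2,500,000 m — records reporting a
    coordinate uncertainty above 2500 km are useless for a city-scale
    comparison.  Records with *missing* uncertainty are kept (with a
    logged warning) unless ``keep_missing_uncertainty`` is False.
    """

    date_start: _dt.date
    date_end: _dt.date
    bbox: Bbox
    max_uncertainty_m: float = 2_500_000.0
    allowed_families: frozenset[str] = BUTTERFLY_FAMILIES
    synonym_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_SYNONYMS)
    quality_required: str | None = "research"
    keep_missing_uncertainty: bool = True

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ConfigurationError("date_start must be <= date_end")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if lat_min > lat_max or lon_min > lon_max:
            raise ConfigurationError(f"malformed bbox {self.bbox!r}")
        if self.max_uncertainty_m <= 0:
            raise ConfigurationError("max_uncertainty_m must be positive")
        object.__setattr__(self, "allowed_families", frozenset(self.allowed_families))


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_in: int
    n_out: int
    removed: tuple[OccurrenceRecord, ...]


@dataclass
class FilterReport:
    """Ordered audit trail: one entry per filter stage, counts and removals."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, before: Sequence, after: Sequence) -> None:
        removed = tuple(r for r in before if r not in after)
        stage = FilterStage(name, len(before), len(after), removed)
        if self.stages and self.stages[-1].n_out != stage.n_in:
            raise ValidationError("filter stages are not contiguous")
        if stage.n_out > stage.n_in:
            raise ValidationError("a filter stage may not add records")
        self.stages.append(stage)

    @property
    def n_in(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_out(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "records_in": s.n_in,
                    "records_out": s.n_out,
                    "removed": "; ".join(
                        f"{r.raw_name} @ ({r.latitude}, {r.longitude}) {r.event_date}"
                        for r in s.removed
                    ),
                }
                for s in self.stages
            ]
        )


def reconcile_taxonomy(
    records: Sequence[OccurrenceRecord], synonym_map: Mapping[str, str]
) -> list[OccurrenceRecord]:
    """Replace raw names by accepted names where the synonym map applies.

    One-step application: a record's name is looked up once, so the map
    must not chain into a cycle.  Record count is preserved and the
    original name is kept on each renamed record.
    """
    _check_acyclic(synonym_map)
    out = []
    for rec in records:
        accepted = synonym_map.get(rec.raw_name)
        out.append(rec if accepted is None else rec.with_name(accepted))
    return out


def _check_acyclic(synonym_map: Mapping[str, str]) -> None:
    for start in synonym_map:
        seen = {start}
        cur = start
        while cur in synonym_map:
            cur = synonym_map[cur]
            if cur in seen:
                raise ConfigurationError(
                    f"synonym map contains a cycle through {cur!r}"
                )
            seen.add(cur)


def filter_records(
    records: Sequence[OccurrenceRecord], config: FilterConfig
) -> tuple[list[OccurrenceRecord], FilterReport]:
    """Run the cleaning pipeline; return surviving records and the audit trail.

    Stage order: quality flag, family, date window, bounding box,
    coordinate uncertainty.  Every predicate is record-wise, so the
    pipeline is idempotent and the surviving set is order-invariant.
    """
    report = FilterReport()
    current = list(records)

    def apply(name, predicate):
        nonlocal current
        kept = [r for r in current if predicate(r)]
        report.add(name, current, kept)
        current = kept

    if config.quality_required is not None:
        apply("quality", lambda r: r.quality_grade == config.quality_required)
    else:
        report.add("quality", current, current)
    apply("family", lambda r: r.family in config.allowed_families)
    apply(
        "date",
        lambda r: config.date_start <= r.event_date <= config.date_end,
    )
    lat_min, lat_max, lon_min, lon_max = config.bbox
    apply(
        "bbox",
        lambda r: lat_min <= r.latitude <= lat_max
        and lon_min <= r.longitude <= lon_max,
    )

    def uncertainty_ok(r: OccurrenceRecord) -> bool:
        if r.coordinate_uncertainty_m is None:
            if config.keep_missing_uncertainty:
                logger.warning(
                    "record %r has no coordinate uncertainty; keeping", r.raw_name
                )
                return True
            return False
        return r.coordinate_uncertainty_m <= config.max_uncertainty_m

    apply("uncertainty", uncertainty_ok)
    return current, report


def bbox_from_sites(site_coordinates: Sequence[tuple[float, float]]) -> Bbox:
    """Minimal closed axis-aligned box containing the survey sites."""
    distinct = set(site_coordinates)
    if len(distinct) < 2:
        raise ValidationError(
            "need at least two distinct site coordinates to define a box"
        )
    lats = [p[0] for p in site_coordinates]
    lons = [p[1] for p in site_coordinates]
    return (min(lats), max(lats), min(lons), max(lons))
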