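"""Domain types and I/O for structured survey tables and occurrence records.

Two granularities of butterfly data are represented here:

* :class:`SiteSurveyTable` — per-site, per-method species abundances, the
  granularity produced by transect (Pollard) walks and Malaise traps;
* :class:`IncidenceSummary` — a species × source table of site incidence
  (number of sites where the species was seen) for the two structured
  methods, and raw observation counts for incidental records.

The packaged Los Angeles 2015 butterfly summary (30 species across 16
sites, three data sources) ships as a CSV fixture and is loaded with
:func:`load_table1_fixture`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError

METHODS = ("pollard", "malaise")

#: Sources an :class:`IncidenceSummary` knows about. ``pollard`` and
#: ``malaise`` columns hold site incidence; ``inat`` holds observation counts.
SOURCES = ("pollard", "malaise", "inat")

_SOURCE_COLUMNS = {
    "pollard": "pollard_sites",
    "malaise": "malaise_sites",
    "inat": "inat_observations",
}

#: Default column mapping for survey CSVs.
SURVEY_DIALECT = {
    "site_id": "site_id",
    "method": "method",
    "species": "species",
    "family": "family",
    "count": "count",
    "date": "date",
}

#: Default Darwin Core simple-CSV column mapping for occurrence downloads.
DWC_DIALECT = {
    "raw_name": "scientificName",
    "family": "family",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "event_date": "eventDate",
    "coordinate_uncertainty_m": "coordinateUncertaintyInMeters",
    "quality_grade": "qualityGrade",
}


@dataclass(frozen=True, order=True)
class Taxon:
    """A species-level taxon: binomial name plus taxonomic family."""

    family: str
    species: str

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("Taxon.species must be non-empty")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One incidental (presence-only) observation.

    ``raw_name`` carries the working scientific name; after taxonomic
    reconciliation it holds the accepted name and ``original_name`` keeps
    the name as originally reported.  ``coordinate_uncertainty_m`` is
    ``None`` when the source record left it blank — missingness is a
    distinct state, never coerced to zero.
    """

    raw_name: str
    latitude: float
    longitude: float
    event_date: _dt.date
    family: str | None = None
    coordinate_uncertainty_m: float | None = None
    quality_grade: str | None = None
    original_name: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude!r} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude!r} outside [-180, 180]")
        u = self.coordinate_uncertainty_m
        if u is not None and u < 0:
            raise ValidationError(f"coordinate uncertainty {u!r} is negative")

    def with_name(self, accepted: str) -> "OccurrenceRecord":
        """Return a copy renamed to ``accepted``, keeping provenance."""
        return replace(self, raw_name=accepted, original_name=self.raw_name)


class SiteSurveyTable:
    """Per-site, per-method pooled species abundances.

    Wraps a DataFrame with columns ``site_id, method, family, species,
    count, period_label``; duplicate (site, method, taxon) rows are pooled
    additively on construction, so each combination appears at most once.
    The full set of surveyed sites per method can be wider than the sites
    with records (a surveyed site may simply have caught nothing); pass
    ``sites`` to register empty sites.
    """

    COLUMNS = ["site_id", "method", "family", "species", "count", "period_label"]

    def __init__(
        self,
        rows: pd.DataFrame,
        sites: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        df = rows.copy()
        for col in ("family", "period_label"):
            if col not in df.columns:
                df[col] = ""
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"survey table missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        df["period_label"] = df["period_label"].fillna("").astype(str)
        df["family"] = df["family"].fillna("").astype(str)
        self._validate_rows(df)
        # Pool by (site, method, taxon): counts add, period labels collapse
        # to the lexicographically first (order-independent).
        pooled = (
            df.groupby(
                ["site_id", "method", "family", "species"],
                as_index=False,
                sort=True,
            )
            .agg(count=("count", "sum"), period_label=("period_label", "min"))
        )
        self.df = pooled[self.COLUMNS].reset_index(drop=True)
        self._sites: dict[str, frozenset[str]] = {}
        for method in METHODS:
            observed = set(self.df.loc[self.df["method"] == method, "site_id"])
            registered = set(sites.get(method, ())) if sites else set()
            if observed - registered and registered:
                raise ValidationError(
                    f"rows reference {method} sites not in the registered site set"
                )
            self._sites[method] = frozenset(registered or observed)

    @staticmethod
    def _validate_rows(df: pd.DataFrame) -> None:
        bad_method = ~df["method"].isin(METHODS)
        if bad_method.any():
            row = df.index[bad_method][0]
            raise ValidationError(
                f"row {row}: unknown method {df.loc[row, 'method']!r}"
            )
        if df["species"].eq("").any() or df["species"].isna().any():
            row = df.index[df["species"].isna() | df["species"].eq("")][0]
            raise ValidationError(f"row {row}: empty species name")
        counts = pd.to_numeric(df["count"], errors="coerce")
        nonint = counts.isna() | (counts != counts.round()) | (counts < 0)
        if nonint.any():
            row = df.index[nonint][0]
            raise ValidationError(
                f"row {row}: count {df.loc[row, 'count']!r} is not a "
                "non-negative integer"
            )
        df["count"] = counts.astype(int)

    # -- site bookkeeping -------------------------------------------------

    def sites(self, method: str) -> frozenset[str]:
        self._check_method(method)
        return self._sites[method]

    def n_sites(self, method: str) -> int:
        return len(self.sites(method))

    # -- views ------------------------------------------------------------

    def method_rows(self, method: str) -> pd.DataFrame:
        self._check_method(method)
        return self.df[self.df["method"] == method]

    def site_species_sets(self, method: str) -> dict[str, frozenset[str]]:
        """Per-site sets of species with count > 0, including empty sites."""
        rows = self.method_rows(method)
        rows = rows[rows["count"] > 0]
        grouped = rows.groupby("site_id")["species"].agg(frozenset).to_dict()
        return {s: grouped.get(s, frozenset()) for s in sorted(self._sites[method])}

    def taxa(self) -> list[Taxon]:
        pairs = self.df[["family", "species"]].drop_duplicates()
        return [Taxon(f, s) for f, s in pairs.itertuples(index=False)]

    @staticmethod
    def _check_method(method: str) -> None:
        if method not in METHODS:
            raise ConfigurationError(
                f"unknown method {method!r}; expected one of {METHODS}"
            )

    # -- equality and I/O -------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteSurveyTable):
            return NotImplemented
        return self.df.equals(other.df) and self._sites == other._sites

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_survey_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sites: Mapping[str, Iterable[str]] | None = None,
) -> SiteSurveyTable:
    """Read a long-format survey CSV into a validated :class:`SiteSurveyTable`.

    ``dialect`` maps logical field names (``site_id``, ``method``,
    ``species``, ``family``, ``count``, ``date``) to the file's column
    names; unspecified fields fall back to :data:`SURVEY_DIALECT`.
    """
    dialect = {**SURVEY_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, dtype=str)
    rename = {}
    for logical in ("site_id", "method", "species", "count"):
        col = dialect[logical]
        if col not in raw.columns:
            raise ConfigurationError(
                f"{path}: required column {col!r} (for {logical!r}) not found"
            )
        rename[col] = logical
    for logical in ("family",):
        col = dialect[logical]
        if col in raw.columns:
            rename[col] = logical
    df = raw.rename(columns=rename)
    df["period_label"] = df[dialect["date"]] if dialect["date"] in raw.columns else ""
    return SiteSurveyTable(df, sites=sites)


def _parse_date(value: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value).strip()[:10])
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparseable date {value!r}") from exc


def _parse_float(value, row: int, what: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row}: unparseable {what} {value!r}") from exc


def read_occurrence_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[OccurrenceRecord]:
    """Read a Darwin Core-style occurrence CSV/TSV.

    The delimiter is sniffed, so both GBIF simple-CSV and TSV exports load.
    Missing coordinate uncertainty is preserved as missing (``None``).
    """
    dialect = {**DWC_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, dtype=str, sep=None, engine="python")
    for logical in ("raw_name", "latitude", "longitude", "event_date"):
        if dialect[logical] not in raw.columns:
            raise ConfigurationError(
                f"{path}: required column {dialect[logical]!r} "
                f"(for {logical!r}) not found"
            )

    def cell(rec, logical):
        col = dialect[logical]
        if col not in raw.columns:
            return None
        val = rec[col]
        if pd.isna(val) or str(val).strip() == "":
            return None
        return str(val).strip()

    records = []
    for i, rec in raw.iterrows():
        row = i + 2  # header is line 1
        unc = cell(rec, "coordinate_uncertainty_m")
        records.append(
            OccurrenceRecord(
                raw_name=cell(rec, "raw_name") or "",
                family=cell(rec, "family"),
                latitude=_parse_float(cell(rec, "latitude"), row, "latitude"),
                longitude=_parse_float(cell(rec, "longitude"), row, "longitude"),
                event_date=_parse_date(cell(rec, "event_date"), row),
                coordinate_uncertainty_m=(
                    None if unc is None else _parse_float(unc, row, "uncertainty")
                ),
                quality_grade=cell(rec, "quality_grade"),
            )
        )
    return records


def write_occurrence_csv(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    """Write records in the default Darwin Core dialect (lossless round-trip)."""
    rows = []
    for r in records:
        rows.append(
            {
                "scientificName": r.raw_name,
                "family": r.family if r.family is not None else "",
                "decimalLatitude": r.latitude,
                "decimalLongitude": r.longitude,
                "eventDate": r.event_date.isoformat(),
                "coordinateUncertaintyInMeters": (
                    "" if r.coordinate_uncertainty_m is None
                    else r.coordinate_uncertainty_m
                ),
                "qualityGrade": r.quality_grade if r.quality_grade is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class IncidenceSummary:
    """Species × source summary at the granularity the study publishes.

    ``table`` is indexed by (family, species) with integer columns
    ``pollard_sites``, ``malaise_sites`` (number of sites where detected,
    each ≤ ``n_sites``) and ``inat_observations`` (number of incidental
    records).  Rows that are zero everywhere are dropped on construction.
    """

    table: pd.DataFrame
    n_sites: int = 16

    def __post_init__(self) -> None:
        t = self.table
        cols = list(_SOURCE_COLUMNS.values())
        if list(t.columns) != cols:
            t = t[cols]
        t = t.astype(int)
        if (t < 0).any().any():
            raise ValidationError("incidence entries must be non-negative")
        for col in ("pollard_sites", "malaise_sites"):
            if (t[col] > self.n_sites).any():
                raise ValidationError(
                    f"{col} exceeds the number of surveyed sites ({self.n_sites})"
                )
        t = t[t.sum(axis=1) > 0].sort_index()
        self.table = t

    def column(self, source: str) -> pd.Series:
        if source not in _SOURCE_COLUMNS:
            raise ConfigurationError(
                f"unknown source {source!r}; expected one of {SOURCES}"
            )
        return self.table[_SOURCE_COLUMNS[source]]

    @property
    def taxa(self) -> list[Taxon]:
        return [Taxon(f, s) for f, s in self.table.index]

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceSummary):
            return NotImplemented
        return self.n_sites == other.n_sites and self.table.equals(other.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def summarize_incidence(
    table: SiteSurveyTable | None,
    inat: Sequence[OccurrenceRecord] = (),
    n_sites: int | None = None,
    family_lookup: Mapping[str, str] | None = None,
) -> IncidenceSummary:
    """Collapse per-site data and incidental records to an :class:`IncidenceSummary`.

    Site incidence counts distinct sites with count > 0 per method;
    incidental entries count records.  ``family_lookup`` resolves the
    family of incidental species whose records carry none (falling back
    to families seen in the survey table, then to "").
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    families: dict[str, str] = dict(family_lookup or {})

    if table is not None:
        for _, row in table.df.iterrows():
            families.setdefault(row["species"], row["family"])
        for method in METHODS:
            rows = table.method_rows(method)
            rows = rows[rows["count"] > 0]
            incid = rows.groupby(["family", "species"])["site_id"].nunique()
            for key, n in incid.items():
                counts.setdefault(key, {})[_SOURCE_COLUMNS[method]] = int(n)

    for rec in inat:
        fam = rec.family or families.get(rec.raw_name, "")
        key = (fam, rec.raw_name)
        entry = counts.setdefault(key, {})
        entry["inat_observations"] = entry.get("inat_observations", 0) + 1

    cols = list(_SOURCE_COLUMNS.values())
    if counts:
        t = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=cols)
        t = t.fillna(0).astype(int)
        t.index = pd.MultiIndex.from_tuples(t.index, names=["family", "species"])
    else:
        t = pd.DataFrame(
            columns=cols,
            index=pd.MultiIndex.from_arrays([[], []], names=["family", "species"]),
        )
    if n_sites is None:
        n_sites = (
            max((table.n_sites(m) for m in METHODS), default=0) if table else 0
        ) or 16
    return IncidenceSummary(t, n_sites=n_sites)


_FIXTURE_NAME = "la_butterflies_2015.csv"


def load_table1_fixture() -> IncidenceSummary:
    """Load the packaged Los Angeles 2015 butterfly incidence summary.

    30 species scored across three sources: site incidence for 16 Pollard
    walk routes and 16 Malaise traps, plus incidental observation counts
    for the same bounding box and season (15 Mar – 15 Jul 2015).
    """
    with resources.files("lepisurvey.data").joinpath(_FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index(["family", "species"])
    return IncidenceSummary(df, n_sites=16)
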