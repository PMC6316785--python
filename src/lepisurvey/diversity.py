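"""Richness and diversity statistics, and the paired site-level comparison.

Species richness is the number of species detected; Shannon's H
(−Σ pᵢ ln pᵢ, natural log) additionally weighs evenness of abundances.
Structured surveys with matched sites support a paired t-test on the
per-site difference between methods; incidental observation counts do
not (their column of an :class:`~lepisurvey.survey.IncidenceSummary`
counts records, not sites, so site-mean operations reject it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DegenerateInputError, ValidationError
from .survey import METHODS, IncidenceSummary, SiteSurveyTable, Taxon


@dataclass(frozen=True)
class SiteStat:
    """Richness and Shannon diversity of one site under one method.

    ``shannon_h`` is ``None`` for sites with no observed individuals
    (H is undefined on an empty sample, not zero).
    """

    site_id: str
    method: str
    richness: int
    shannon_h: float | None


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_difference: float


def shannon_h(counts: Sequence[float]) -> float:
    """Shannon's H in nats over one sample's species abundances.

    H = −Σ pᵢ ln pᵢ with pᵢ the abundance share of species i; zero-count
    species contribute nothing.  All-zero (or empty) input is an error.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size and (arr < 0).any():
        raise ValidationError("abundances must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValidationError("Shannon's H is undefined without observations")
    # scipy normalises and computes -sum(p ln p) directly
    return float(stats.entropy(arr))


def per_site_stats(table: SiteSurveyTable, method: str) -> list[SiteStat]:
    """Richness and H for every surveyed site of a method.

    Sites registered for the method but with zero observed individuals
    are reported with richness 0 and missing H.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    rows = table.method_rows(method)
    rows = rows[rows["count"] > 0]
    by_site = {
        site: grp["count"].to_numpy() for site, grp in rows.groupby("site_id")
    }
    out = []
    for site in sorted(table.sites(method)):
        counts = by_site.get(site)
        if counts is None or counts.sum() == 0:
            out.append(SiteStat(site, method, 0, None))
        else:
            out.append(SiteStat(site, method, int(len(counts)), shannon_h(counts)))
    return out


def mean_richness_from_incidence(
    summary: IncidenceSummary, source: str, n_sites: int | None = None
) -> float:
    """Mean per-site richness recovered from a site-incidence column.

    Summing a species × site 0/1 detection matrix by rows (incidence)
    or by columns (per-site richness) gives the same total, so the mean
    per-site richness equals Σ incidence / n_sites.  Only valid for
    site-based sources; observation counts have no such identity.
    """
    if source == "inat":
        raise ConfigurationError(
            "incidental observation counts are per record, not per site; "
            "a site-mean richness is undefined for them"
        )
    n = summary.n_sites if n_sites is None else n_sites
    if n < 1:
        raise ValidationError("n_sites must be >= 1")
    return float(summary.column(source).sum()) / n


def source_richness(summary: IncidenceSummary, source: str) -> int:
    """Number of species with a positive entry for the source."""
    return int((summary.column(source) > 0).sum())


def combined_richness(summary: IncidenceSummary, sources: Sequence[str]) -> int:
    """Species detected by at least one of the given sources."""
    mask = np.zeros(len(summary), dtype=bool)
    for src in sources:
        mask |= (summary.column(src) > 0).to_numpy()
    return int(mask.sum())


def singleton_count(summary: IncidenceSummary, source: str) -> int:
    """Species seen at exactly one site under a site-based source."""
    if source == "inat":
        raise ConfigurationError("singletons are defined on site incidence only")
    return int((summary.column(source) == 1).sum())


def exclusive_species(summary: IncidenceSummary, source: str) -> set[Taxon]:
    """Species recorded by ``source`` and by no other source."""
    col = summary.column(source)
    others = [c for c in ("pollard", "malaise", "inat") if c != source]
    mask = col > 0
    for other in others:
        mask &= summary.column(other) == 0
    return {Taxon(f, s) for (f, s), keep in mask.items() if keep}


def paired_t_test(
    x: Sequence[float], y: Sequence[float]
) -> TestResult:
    """Two-sided paired t-test on per-site values aligned by site.

    Equivalent to a one-sample t on the differences d = x − y:
    t = mean(d) / (sd(d)/√n), df = n − 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    if x.size < 2:
        raise ValidationError("need at least two pairs")
    d = x - y
    if np.allclose(d, d[0]):
        raise DegenerateInputError(
            "all paired differences identical; t statistic undefined"
        )
    res = stats.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=int(x.size - 1),
        p_value=float(res.pvalue),
        mean_difference=float(d.mean()),
    )


def paired_stat_test(
    stats_a: Sequence[SiteStat], stats_b: Sequence[SiteStat], field: str
) -> TestResult:
    """Paired test on a per-site statistic (``richness`` or ``shannon_h``).

    Sites are matched by ``site_id``; sites missing the statistic under
    either method are dropped from the pairing.
    """
    a = {s.site_id: getattr(s, field) for s in stats_a}
    b = {s.site_id: getattr(s, field) for s in stats_b}
    common = sorted(
        k for k in a.keys() & b.keys() if a[k] is not None and b[k] is not None
    )
    if len(common) < 2:
        raise ValidationError("fewer than two complete site pairs")
    return paired_t_test([a[k] for k in common], [b[k] for k in common])


def summary_block(summary: IncidenceSummary) -> dict:
    """The headline numbers of a three-source comparison, as one dict."""
    pollard = mean_richness_from_incidence(summary, "pollard")
    malaise = mean_richness_from_incidence(summary, "malaise")
    return {
        "n_sites": summary.n_sites,
        "total_species": len(summary),
        "pollard_richness": source_richness(summary, "pollard"),
        "malaise_richness": source_richness(summary, "malaise"),
        "inat_richness": source_richness(summary, "inat"),
        "scan_combined_richness": combined_richness(summary, ["pollard", "malaise"]),
        "inat_observation_total": int(summary.column("inat").sum()),
        "pollard_mean_site_richness": pollard,
        "malaise_mean_site_richness": malaise,
        "mean_site_richness_difference": pollard - malaise,
        "pollard_singleton_species": singleton_count(summary, "pollard"),
        "malaise_singleton_species": singleton_count(summary, "malaise"),
        "inat_exclusive_species": sorted(
            t.species for t in exclusive_species(summary, "inat")
        ),
        "pollard_exclusive_species": sorted(
            t.species for t in exclusive_species(summary, "pollard")
        ),
    }
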