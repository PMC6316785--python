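"""Bootstrap comparison of pooled species richness across survey designs.

Site-based surveys and incidental observation streams have no common
"sample" to compare means over, so richness for an area is compared by
resampling each design's own sampling units with replacement — whole
sites for structured surveys, individual observations for incidental
records — and recording the pooled richness (size of the species union)
of each pseudoreplicate.  Pseudoreplicate distributions are then
compared with a two-sample t-test.

The t-test p-values are anti-conservative: pseudoreplicates are
resamples of one dataset, not independent draws, so the test wildly
overstates certainty.  Results carry an ``anticonservative_p`` flag and
should be read as effect-size summaries of the bootstrap distributions.

All resampling uses numpy's default PCG64 generator seeded explicitly;
identical (inputs, n_boot, seed) give identical results on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError
from .diversity import TestResult


@dataclass(frozen=True)
class BootstrapResult:
    """Pseudoreplicate pooled-richness distribution for one source."""

    source: str
    n_boot: int
    unit: str  # "site" or "observation"
    richness_values: np.ndarray
    seed: int
    observed_richness: int

    def __post_init__(self) -> None:
        values = np.asarray(self.richness_values, dtype=int)
        object.__setattr__(self, "richness_values", values)
        if values.shape != (self.n_boot,):
            raise ValidationError("need exactly n_boot pseudoreplicate values")
        if (values < 0).any() or (values > self.observed_richness).any():
            raise ValidationError(
                "pseudoreplicate richness must lie in [0, observed richness]"
            )

    @property
    def mean(self) -> float:
        return float(self.richness_values.mean())

    @property
    def std(self) -> float:
        return float(self.richness_values.std(ddof=1))

    def quantiles(self, q=(0.025, 0.5, 0.975)) -> dict[float, float]:
        vals = np.quantile(self.richness_values, q)
        return dict(zip(q, map(float, vals)))


def _membership_matrix(
    species_sets: Sequence[frozenset[str] | set[str]],
) -> np.ndarray:
    species = sorted(set().union(*species_sets)) if species_sets else []
    index = {sp: j for j, sp in enumerate(species)}
    mat = np.zeros((len(species_sets), len(species)), dtype=bool)
    for i, sset in enumerate(species_sets):
        for sp in sset:
            mat[i, index[sp]] = True
    return mat


def bootstrap_site_richness(
    site_species_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    n_boot: int = 1000,
    seed: int = 0,
    source: str = "sites",
) -> BootstrapResult:
    """Bootstrap pooled richness with whole sites as the resampling unit.

    Each pseudoreplicate draws n_sites sites with replacement and scores
    the size of the union of their species sets.
    """
    if isinstance(site_species_sets, Mapping):
        sets = [frozenset(site_species_sets[k]) for k in sorted(site_species_sets)]
    else:
        sets = [frozenset(s) for s in site_species_sets]
    if not sets:
        raise ValidationError("need at least one site to resample")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    mat = _membership_matrix(sets)
    n_sites = len(sets)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_sites, size=(n_boot, n_sites))
    richness = mat[idx].any(axis=1).sum(axis=1) if mat.size else np.zeros(n_boot, int)
    return BootstrapResult(
        source=source,
        n_boot=n_boot,
        unit="site",
        richness_values=richness,
        seed=seed,
        observed_richness=int(mat.any(axis=0).sum()) if mat.size else 0,
    )


def bootstrap_observation_richness(
    records: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    source: str = "observations",
) -> BootstrapResult:
    """Bootstrap pooled richness with individual observations as the unit.

    Each pseudoreplicate draws n_records species labels with replacement
    and scores the number of distinct species drawn.
    """
    labels = list(records)
    if not labels:
        raise ValidationError("need at least one observation to resample")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    species, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    n_rec, n_sp = len(labels), len(species)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_rec, size=(n_boot, n_rec))
    drawn = codes[idx]  # (n_boot, n_rec) species codes
    onehot = np.zeros((n_boot, n_sp), dtype=bool)
    rows = np.repeat(np.arange(n_boot), n_rec)
    onehot[rows, drawn.ravel()] = True
    richness = onehot.sum(axis=1)
    return BootstrapResult(
        source=source,
        n_boot=n_boot,
        unit="observation",
        richness_values=richness,
        seed=seed,
        observed_richness=n_sp,
    )


def compare_bootstrap(
    a: BootstrapResult, b: BootstrapResult, equal_var: bool = True
) -> TestResult:
    """Two-sample t-test between two pseudoreplicate richness distributions.

    Pooled-variance by default (``equal_var=False`` for Welch).  The
    p-value inherits the anti-conservatism described in the module
    docstring.
    """
    if a.n_boot < 2 or b.n_boot < 2:
        raise ValidationError("need at least two pseudoreplicates per side")
    va, vb = a.richness_values, b.richness_values
    if va.std() == 0 and vb.std() == 0:
        raise DegenerateInputError("both bootstrap distributions are constant")
    res = stats.ttest_ind(va, vb, equal_var=equal_var)
    df = (
        a.n_boot + b.n_boot - 2
        if equal_var
        else int(np.floor(getattr(res, "df", a.n_boot + b.n_boot - 2)))
    )
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=int(df),
        p_value=float(res.pvalue),
        mean_difference=a.mean - b.mean,
    )


def compare_bootstrap_to_value(a: BootstrapResult, value: float) -> TestResult:
    """One-sample t-test of a pseudoreplicate distribution against a constant."""
    if a.n_boot < 2:
        raise ValidationError("need at least two pseudoreplicates")
    if a.richness_values.std() == 0:
        raise DegenerateInputError("bootstrap distribution is constant")
    res = stats.ttest_1samp(a.richness_values, value)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=a.n_boot - 1,
        p_value=float(res.pvalue),
        mean_difference=a.mean - value,
    )
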