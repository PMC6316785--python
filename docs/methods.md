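# Methods

## The comparison problem

Three data-gathering designs observe the same butterfly community
through different windows. Pollard walks and Malaise traps are
*site-based*: each of 16 sites yields a pooled species-abundance sample
per method over one season. Incidental records are *observation-based*:
presence-only reports with coordinates, dates and variable metadata
quality, with no notion of a survey event. The package therefore keeps
two data granularities — per-site abundance tables and a species × source
incidence summary — and chooses statistics that respect each design's
sampling unit.

## Statistics

**Richness.** Per-site richness is the number of species with count > 0;
pooled richness of a source is the size of the union of its per-site (or
per-record) species sets. Mean per-site richness can be recovered from
incidence alone: summing a species × site detection matrix by rows
(incidence) or by columns (per-site richness) gives the same total, so
mean richness = Σ incidence / n_sites. This identity is property-tested
against direct per-site computation on simulated tables.

**Shannon diversity.** H = −Σ pᵢ ln pᵢ in natural-log units, the
ecological convention. H is undefined (reported as missing, never zero)
for sites with no observations; it is computed from per-site abundances
only, since observation-based data have no abundance structure — the
per-record incidental counts deliberately refuse site-mean and diversity
operations.

**Paired comparison.** Methods sharing sites are compared with the
paired t-test: a one-sample t on per-site differences (df = n − 1,
two-sided p). A paired design conditions out site effects and has no
separate equal-variance assumption; zero-variance differences raise a
degenerate-input error rather than returning an infinite statistic.
Two-sided p-values are used throughout as the conservative default.

**Bootstrap richness comparison.** The statistic per pseudoreplicate is
*pooled* richness across resampled units — whole sites (n = 16 drawn
with replacement) for structured surveys, individual observations
(n = n_records) for incidental data — so that each pseudoreplicate
replicates the observed sampling effort in that design's own units.
Distributions (default n_boot = 1000) are compared with a
pooled-variance two-sample t-test (Welch behind a flag). These p-values
are flagged anti-conservative in every output: pseudoreplicates are
resamples of one dataset, not independent draws, so the test should be
read as an effect-size summary, not an inference. A one-sample variant
against a fixed observed value is also provided. Useful invariants hold
by construction and are tested: no pseudoreplicate contains a species
absent from the data, and the bootstrap mean never exceeds observed
pooled richness (unions over subsamples cannot grow).

## Occurrence cleaning

Stage order is fixed — quality flag, family, date window, bounding box,
coordinate uncertainty — but all stages are record-wise predicates, so
the surviving set is order-invariant and the pipeline idempotent; only
the audit trail depends on the order. Conventions, chosen once and
documented here:

* date window inclusive at both ends; bounding box closed (boundary
  points kept) — "between" conventions resolved to least surprise;
* records with *missing* coordinate uncertainty are kept, with a logged
  warning (configurable); the default cap is 2,500,000 m, the scale at
  which a record stops being usable for a city-scale comparison;
* default allowed families are the six butterfly families
  (Hesperiidae, Papilionidae, Pieridae, Nymphalidae, Lycaenidae,
  Riodinidae);
* taxonomy reconciliation is a one-step synonym map (cycles rejected),
  preserving the original name as provenance. The packaged defaults fix
  the two known platform-name mismatches in the shipped dataset
  (*Paratrytone melane* → *Poanes melane*; *Zerynthia rumina*
  misapplied to *Papilio rumiko*).

## The synthetic world

Raw per-site abundances behind published survey comparisons are usually
unpublished, so testing the full pipeline requires a generative
stand-in with known truth:

* **Occupancy.** Species i occupies each site independently with
  probability ψᵢ. Default ψ is anchored to the packaged dataset's site
  incidence (detection-corrected, floored at 1/32 for species the
  structured surveys missed), so the default community's mix of
  widespread and scarce species matches the surveyed area.
* **Abundance.** Occupied sites hold a zero-truncated Poisson(λᵢ) number
  of individuals (occupancy means at least one individual); λ is
  lognormal(μ = 1.0, σ = 0.7) across species, drawn once per model seed.
  Zero truncation makes "occupied" and "present" coincide, which the
  perfect-detection limit requires.
* **Detection.** Each of k survey events (default 8 per site per season,
  matching roughly fortnightly sampling over four months) detects a
  present species with per-method probability p: default 0.30 for walks,
  0.04 for traps, chosen so that expected pooled richness under the
  default community reproduces the field-typical pattern (walks detect
  most of the fauna; traps miss a third or more; incidental data fall in
  between). A detecting event records 1 + Binomial(N − 1, p)
  individuals; counts pool over events.
* **Incidental records.** n (default 104) multinomial draws with species
  probability ∝ wᵢ × total true abundance; w is a per-species reporting
  weight (default 1) that makes "photogenic-species" reporting bias a
  tunable parameter. Each record gets a uniform point in the bounding
  box, a uniform date in the season window, a lognormal coordinate
  uncertainty (median ≈ 30 m) with an optional extreme-outlier arm, and
  — at a configurable rate — a synonymous name requiring reconciliation.
* **Randomness.** One seed feeds named substreams (occupancy, abundance,
  detection, incidental, corruption) via `numpy` `SeedSequence` spawning
  over the PCG64 generator; identical seeds give byte-identical
  serialized worlds. Detection events are drawn by thresholding
  per-survey uniforms and all site-level randomness uses per-site
  substreams, so on matched seeds observed richness is *exactly*
  non-decreasing in detection probability, number of surveys and number
  of sites — the monotonicity tests check this deterministically rather
  than statistically.

`make_paperlike_fixture` is a separate deterministic construction, not a
draw from the model: it assigns each species to exactly its published
number of sites, emits exactly one incidental record per published
observation, adds one extreme-uncertainty record (105 → 104 under
cleaning) and applies the two known synonym corruptions. It exists so
integration tests can verify that the full clean → reconcile → summarize
path reproduces the packaged incidence table exactly.

What the simulator does **not** emulate: spatial autocorrelation between
sites, within-season phenology (dates do not affect detectability),
observer heterogeneity, and misidentification beyond synonym swaps.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness of the survey designs
to those real-world complications.

## Problem sizes in the test suite

Monte-Carlo checks run on deliberately small communities so the suite
stays fast: parameter-recovery uses 220–250 worlds of 5–6 species × 10–12
sites (binomial 4σ envelopes), the bootstrap power check 200 replicate
worlds of 8 + 8 sites, and the ordering-recovery check 60 full-size
worlds at n_boot = 1000. Exact-enumeration oracles (two-unit bootstraps,
small composition scans for the Shannon maximum) are preferred over
sampling wherever the state space is enumerable.

## Known limitations

* The bootstrap t-test mirrors a procedure in common field use; its
  p-values are anti-conservative and flagged as such, and the package
  intentionally offers no confidence-interval machinery beyond quantiles
  of the stored pseudoreplicate distribution.
* Incidence summaries cap site-based entries at n_sites but cannot
  validate that observation counts refer to the same spatial frame; that
  is the cleaning pipeline's job.
* The data model is species-level only; records identifiable only to
  genus or family must be resolved or dropped before loading.
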