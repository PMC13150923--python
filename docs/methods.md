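# Methods

This note documents the models, parameters and numerical choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the design was genuinely open.

## Text extraction

All patterns operate on the raw, unsegmented Chinese character stream; word
segmentation is a pluggable no-op because every matched construct is an exact
character sequence. This deliberately trades the recall of a full NLP stack
for auditability: a match can always be pointed at in the source text.

**Article-19 screening** is pure substring search for the three citation
variants (ASCII digits, Chinese numerals, full-width digits). Substring
semantics give the digit boundary for free: 刑法第190條 cannot match because
the matched strings end in 條.

**Appeal chains.** A judgment citing a prior decision does so in a
不服 {JID} …。 clause. Every token inside such a clause matching the JID
grammar `CODE,YY,TYPE,NO,DATE,SEQ` (configurable regex; real platform
identifiers vary) becomes a parent link. Cases are the connected components
of the citation graph (own union-find; tests cross-check against networkx).
Which member represents the case is not dictated by the data, so the package
retains the **latest judgment by date** (ties: larger docket number, then
lexically larger JID) and keys the case by its earliest member. Citations of
judgments absent from the corpus are recorded as dangling links and the
component is built from the available members.

**FACT sections** are the span between the first 事實 header and the first
subsequent 。理由 sequence (the sentence end immediately preceding the REASON
header). Internal sentence breaks inside the span are preserved; a missing
header on either side yields "absent", never a partial span.

**Police offices.** The mention starts after the earlier of the 訴由 / 案經
markers and is trimmed within that sentence at an office suffix. The suffix
vocabulary (分局, 派出所, 警察局) is closed and configurable, with branch
suffixes taking precedence over the bare headquarters suffix — a full name
such as 臺北市政府警察局大安分局 contains 警察局 before 分局, and precedence
(rather than first-position) trimming is what captures the full name intact.
Resolution against the gazetteer: exact full-name match, else unique
short-name match, else — for colliding short names — the unique candidate
whose county string occurs in the judgment text. Collisions without a county
cue are surfaced as `ambiguous` rather than guessed, and ambiguous cases are
excluded from all spatial analyses. This county-cue rule is the package's
codification of a manual disambiguation step; residual ambiguity is a status,
not an error.

The pipeline runs in two modes: restricted to Article-19 judgments (the
mental-illness case database; the extraction report's stage counts are then
monotone non-increasing) or over all judgments with Article-19 as a per-case
flag (the corpus used to build spatial panels, where all-crime denominators
are needed).

## Trend statistics

Yearly Article-19 proportions use all-judgment yearly totals as denominators;
years with zero totals are excluded and flagged. The Cochran–Armitage
statistic uses equally spaced year scores 0, 1, 2, … by default
(configurable); Z is invariant to positive affine rescaling of the scores, a
property asserted numerically in the tests. Reported percentages and fold
changes round half-up (2 decimals and 1 decimal respectively) to match how
such numbers are conventionally printed; the underlying values are never
rounded. Two-sided p-values are reported, with direction taken from sign(Z).
Degenerate inputs (pooled proportion 0 or 1, zero score variance) are flagged
with Z undefined rather than silently zeroed.

## Emerging hot spots

The space-time cube is a complete district × year array of case counts
(zero-filled; records outside the frame are routed to a reject table). The
default study frame is 365 districts × 10 annual steps = 3650 bins.

*Spatial weights* are binary queen contiguity — polygons sharing at least one
boundary point are neighbors — with the focal district included in its own
neighborhood, as Gi* requires. Islands keep a self-only neighborhood with a
warning. *Temporal pooling* is backward-looking with window k = 1 (the bin's
step and the one before), the referenced tooling's default; the window is a
parameter.

Gi* for bin b uses the global mean X̄ and global scale S = √(Σx²/n − X̄²)
over **all bins of the cube** (one reference distribution, not per time
slice — whether the original tooling normalizes per slice is not recoverable,
so the whole-cube dialect is used and exposed here as the single
implementation). A bin whose neighborhood happens to span the entire cube has
identically zero deviation and its z is defined as 0; a constant cube is
flagged degenerate with all z = 0. p-values are two-sided normal;
Benjamini–Hochberg FDR is applied **jointly across all bins** (one family),
matching a single corrected significance criterion at α = 0.05.

Per location, the Mann-Kendall test (tie-corrected variance, ±1 continuity
correction, normal approximation) runs on the sequence of Gi* z-scores, and
the hot/cold significance history plus the trend feed a fixed first-match
rule table: new, consecutive, intensifying (≥90% of steps hot, final hot,
significant upward trend), persistent (≥90% hot, no significant trend),
diminishing, sporadic, oscillating, historical — hot side first, then the
cold side with the trend direction mirrored, else "no pattern". Two
consequences of first-match ordering worth knowing: a suffix run with an
earlier opposite-side flag classifies as *consecutive* (the run rule
precedes the oscillating rule), and *historical* is reachable only when the
trend is significant (otherwise *persistent* fires first). The 90% threshold
and the taxonomy follow the referenced tooling's documented semantics; maps
typically display only a reduction of it.

No permutation inference is offered; both Gi* and Mann-Kendall use normal
approximations.

## GTWR

Local weighted least squares at every observation point (district centroid,
year); no out-of-sample prediction grid. The space-time metric
d = √(Δx² + Δy² + τ²Δt²) requires a **projected CRS in meters** — geographic
coordinates are rejected at I/O, geodesic distances are not implemented. A
single τ (meters per year) folds temporal separation into the spatial metric
and is selected on a small grid jointly with the bandwidth rather than as
separate space/time scale parameters.

Kernels: gaussian `exp(−(d/h)²)` (default, fixed bandwidth) and bisquare
`(1−(d/h)²)²·1{d<h}` for sensitivity runs. The bandwidth is chosen by
leave-one-out cross-validation (self-weight forced to zero; coordinate
duplicates are *not* excluded, so twin observations keep CV scores finite by
design) over a grid, ties to the smaller bandwidth; if every candidate yields
a non-finite score the error advises raising the bandwidth floor.

Implementation: with M the row-wise outer products of the design, all
XᵀWᵢX and XᵀWᵢy are obtained as two dense matrix products, so a 3650-point
fit is a batched solve of 3650 small systems (seconds on one CPU). A singular
local system falls back to ridge jitter λ = 1e-8·tr(XᵀWᵢX)/p, logged.
Diagnostics: ENP = Σᵢ hᵢᵢ with hᵢᵢ = xᵢᵀ(XᵀWᵢX)⁻¹xᵢ·wᵢᵢ; adjusted R² uses
n − ENP − 1 degrees of freedom and is flagged undefined when that is ≤ 0.
ENP decreases monotonically toward p as the bandwidth grows and every local
coefficient converges to global OLS (asserted to 1e-6 in tests). Note that
other GTWR implementations may use a different ENP convention, so adjusted
R² values are not comparable across packages.

Per-predictor summaries report the mean local coefficient with a 95% CI; how
such CIs should be built from local estimates is genuinely open, so two
constructions are implemented — normal approximation on the mean
(mean ± 1.96·sd/√n, the default) and the 2.5/97.5 percentiles of the local
distribution — plus the quartiles (Q25/median/Q75) of the local surface.
Significance stars derive from the CI-vs-zero test (so one star coincides
exactly with the 95% CI excluding zero).

Model matrices: the *full* set uses the 12 per-resource densities (3 bed
types, 6 staff categories, 2 department types, psychiatry doctors), the
*summary* set the 4 aggregate densities; both add the low-income household
count, the college-degree share, a year term centered at 2012, and an
intercept. Densities are per 10,000 persons — the same scale as the crime
rate — because the source materials speak of "population density of
resources" without fixing a scale. The case-proportion denominator is the
category's own case count in that district-year. "Number of beds" in the
summary resource index is the sum of acute, chronic and intensive beds; the
index weights (1, 2, 3, 4) are configurable.

The SLX robustness model augments the design with row-standardized
queen-lagged predictors (WX) and fits global OLS; lags of constant columns
are dropped (collinear with the intercept, warned), and rank deficiency is an
error naming the collinear columns.

District-level correlation maps use Pearson r between the summary resource
index and the category's mental-illness crime count (counts by default —
configurable to rates; which the source maps used is not stated) over the
district's years; districts where either series has zero variance are NA.

## Synthetic data

`gen_corpus` assembles schematic Chinese-pattern documents — not fluent legal
prose — that realize exactly the constructs the extractor matches, plus
distractors that must not match (刑法第190條; 事實 mentioned after 理由 with
no later REASON header). Default conditions: 1,000 judgments over 2012–2021,
Article-19 probability 0.3 per case (high enough to give the trend and
extraction checks power at n = 1000; the real-world proportion is two orders
of magnitude smaller and is *not* asserted), appeal probability 0.3 with
chains capped at 3 (children filed at the Supreme Court code so chains
survive the court filter), a 20% high-court share among roots for the filter
check, FACT present in 99% of documents, office sentences in 80%
(訴由 30% / 案經 50%), short-name mentions half the time, 20% of offices
planted as short-name collisions, and county cues present in half the
colliding short-name mentions — those without a cue are *expected* to come
out ambiguous, mirroring a geocoding yield below 100%. The truth sidecar
records, per judgment: the planted Article-19 flag, parent JID, FACT span,
office full name and district, and the expected resolution status.

`gen_panel` lays districts on a square metric grid (1 km cells, EPSG:3826
declared) — 365 districts × 2012–2021 by default. Populations are lognormal
(median 30,000, σ = 0.4, 1%/year growth); resource counts are Poisson around
smooth per-capita intensity fields (planes with per-seed random gradients);
category case totals are generated as non-mh cases plus mh cases so planted
mh intensities are never truncated and mh ≤ total holds exactly. Three
planted truths drive the validation suites:

* a **growing cluster**: a 3×3 block whose violent-category intensity is
  multiplied by 1.6 for each year from the fifth step on (base 1.5 expected
  cases per bin) — the emerging-hot-spot power target;
* a **regression law** for GTWR recovery:
  y = β₀(u,v) + β₁(u,v,t)·x₁ + ε, ε ~ N(0, 0.5), with x₁ the realized
  psychiatry-doctor density, β₀ = 1 + 0.5u and
  β₁ = 1 + u + v − 0.3t̃ + 1.5·exp(−((u−0.3)² + (v−0.7)²)/(2·0.2²))
  (u, v, t̃ normalized to [0,1]); the sidecar stores the exact design, y and
  coefficient surfaces;
* a **planted effect** of +0.3 psychiatry-doctor density on the larceny
  mental-illness rate, for sign-recovery checks through the full
  panel-derivation + GTWR path.

Generators are deterministic given their spec seed (distinct fixed substream
tags keep corpus and panel independent under a shared seed). What the
synthetic data does **not** emulate: real legal prose and its formatting
variance, OCR noise, true Taiwanese geography and administrative boundaries,
empirically calibrated resource levels, or spatial autocorrelation in the
covariate noise. Passing tests therefore demonstrate that the *methods* are
implemented correctly and recover known signals under controlled conditions —
not that real-world extraction would reach the same yields.

## Problem sizes

The formal validation scales are: extraction on 1,000-document corpora; GTWR
surface recovery at the full 365 × 10 frame over 20 seeds; planted-cluster
detection over 200 seeds on a 100-district × 10-year frame; SLX recovery over
100 seeds on an 8×8 lattice; Cochran–Armitage null calibration over 10,000
replicates. Unit tests exercise the same code paths on smaller instances of
the same generators. Cluster "detection" means at least half the planted
block's districts end in a hot category while districts outside the block's
contiguity ring stay below a 20% hot fraction (the ring itself legitimately
pools the planted counts and is excluded from the far field). SLX recovery is
judged per coefficient (own and spillover each within 2 SE of truth): the
joint two-coefficient event has expected rate ≈ 0.95² ≈ 0.91 even for a
correct estimator, so the marginal rates are the meaningful correctness
check; both are reported.

## Known limitations

* Pattern extraction is exact-match; paraphrased citations, OCR errors or
  unusual formatting are out of scope by design.
* Normal approximations throughout (Gi*, Mann-Kendall, Cochran–Armitage);
  no permutation or exact options.
* The Gi* reference distribution is whole-cube; per-slice normalization is a
  known dialect of other tooling and would shift z-scores.
* Fixed (non-adaptive) kernel bandwidth; no multiscale or mixed GWR, no
  spatial-error models.
* GeoJSON only, with a `crs_epsg` extension property; no shapefile support,
  no reprojection — inputs must already be in a metric projection.
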