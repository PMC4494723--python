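# Methods

## The triangulation model

The package infers whether a platform user belongs to a target region from
three independent, rule-based evidence channels evaluated over an
observation span (default: the 11-day and 96-hour spans around the
February 10, 2013 Hattiesburg EF-4 tornado, first touchdown 17:00 CST =
23:00 UTC):

- **tweet channel** — the user mentioned (or retweeted) the handle of a
  regional news outlet. Plain-text occurrences of an outlet's name do not
  count; the evidence is the structured mention, which is a deliberate act
  of addressing the outlet. Mentions accumulate over the whole span.
- **biography channel** — a regional term appears in the profile biography
  (state and principal city names; regional universities; the local
  "SMTTT" chant).
- **location channel** — a regional term, state code, or in-region 5-digit
  ZIP appears in the free-text location field.

A user is *regional* iff at least one criterion row fires. Each matched row
is labelled **exclusive** (the only row that fired for that user) or
**inclusive** (at least one other row fired), and per-row tallies plus
per-category exclusive shares quantify how much each filter uniquely
contributes. Rows overlap by design (a "Hattiesburg, MS" location fires
both the city-name row and the state-code row); counts are per row, not
deduplicated across rows, and the per-category exclusive share needs no
deduplication because exclusive users are disjoint across rows by
definition.

Profile fields can change mid-span; the package reads biography, location
and time zone from the user's most recent record in the span. Time zones
are tabulated descriptively only — their spread over dozens of zones is
precisely why they are not usable as a regional criterion.

### Term matching

All matching is case-insensitive and **token-based**: text is split into
maximal alphanumeric runs and a term matches as a contiguous token
subsequence. This is what makes short state codes safe ("Starkville, MS"
matches `ms`, "MSU" does not) and prevents homonym capture ("petal" does
not match "Petaling Jaya"). A substring-compatibility switch reproduces the
looser behaviour of naive substring filters, which is retained because the
post-hoc homonym purge it necessitates is part of the modelled workflow:
the purge drops records whose location contains an excluded place name as
a token, or whose geotag falls outside the region envelope while every
term that matched them is a strict prefix of an excluded name.

### Extraction rules

The first-pass filter mirrors commercial firehose rule matching over five
categories: disaster keywords in text, disaster hashtags, regional terms
in biography/location, regional news-outlet mentions, and geotags inside
the statewide region. The shipped term lists are editable placeholders for
the categories the original workflow used; the exact commercial rule
grammar (negations, proximity operators) is out of scope.

## GPS validation

Geotag confirmation is fully offline: point-in-polygon containment against
GeoJSON region boundaries (shapely-backed even-odd containment, boundary
points counting as inside, holes honoured). The shipped polygons are
deliberately coarse synthetic rectangles for the two target states —
containment logic, not cartography, is what the fixtures exercise; real
boundaries load from any user GeoJSON. A regional user with at least one
geotag is *GPS-confirmed* if any geotag lands inside the region;
unconfirmed users whose stated location still matches a location criterion
row are *location-consistent* (travellers), and

    likely regional accuracy = (confirmed + consistent) / GPS-active users.

## Sampling for quality assessment

Manual-review sample sizes use the normal-approximation formula for a
proportion, `n0 = z^2 p(1-p) / e^2`, at the workflow's stated standard of
99 % confidence and 3.0 % margin of error, with worst-case `p = 0.5` and
finite-population correction `n = n0 / (1 + (n0 - 1)/N)`, ceiling-rounded
and capped at `N` (at the standard settings: 1,844 for an effectively
infinite population). The original workflow reviewed 900 users per stratum,
which does not follow from these standards for any plausible population
size; the pipeline therefore exposes both the formula and an explicit
override (`qa_sample_override`) rather than reverse-engineering the
discrepancy. QA error rates carry Wilson score intervals — a deliberate
choice where no method was specified, preferred over Wald for its behaviour
at zero observed errors.

## Event-window analytics

The analysis span is anchored on the event instant. The default geometry is
a 96-hour span from −50 h to +46 h split at impact: two 48-hour windows
shifted two hours leftward so the pre window captures the run-up to impact.
Windows are half-open on the right (a record exactly at the split lands in
the post window). Summaries count tweets, retweets, hashtag and geotagged
tweets, distinct users, client applications and languages per window, and
average account age, followers, friends and influence score over each
distinct user's latest in-window record, with account age measured back
from the window's reference time (the event by default). Hourly series bin
records by `floor((t - event)/1h)` and, over the default geometry, sum
exactly to the window totals. Combined 96-hour totals are field-wise sums;
the summed user figure is a *window-user* tally that double-counts users
active in both windows, and is documented as such. Fold changes are plain
post/pre ratios computed from the package's own summaries.

## Synthetic corpus generator

The generator emulates the features the analysis relies on, with defaults
calibrated to the modelled 2013 corpus regime:

| parameter | default | calibration |
|---|---|---|
| `regional_fraction` | 0.31 | 8,423 regional of 26,938 active users |
| `base_rate` | 2.4 tweets/user/day | 81,441 regional tweets / 8,423 users / 4 days |
| `retweet_fraction` | 0.335 | 27,309 / 81,441 |
| `hashtag_fraction` | 0.238 | 19,361 / 81,441 |
| `gps_enabled_fraction` | 0.061 | 515 / 8,423 users |
| `gps_noise_outside_fraction` | 0.027 | 63 of 2,353 geotags out-of-region |
| `missing_bio_fraction` | 0.143 | 1,201 / 8,423 blank biographies |
| `missing_location_fraction` | 0.038 | 316 / 8,423 blank locations |
| `event_spike_multiplier` | 5.0 | order of the observed impact-hour surge |
| `spike_halflife_h` | 12 h | chosen: surge decays within the post window |
| `diurnal_amplitude` | 0.6 | chosen: marked day/night cycle, no dead hours |

Tweet times are an inhomogeneous Poisson process — sinusoidal diurnal
intensity (peak 15:00 local) times a multiplicative post-event spike
decaying with the configured half-life, applied to regional users —
sampled exactly by thinning against the maximum intensity. Per-user
generators are namespaced from the master seed, so corpora are
reproducible byte-for-byte and editing one parameter does not reshuffle
unrelated users. Every simulated account emits at least one record (an
empty account is invisible to profile-based classification, and the
generator models the *active-user* corpus the pipeline actually sees).
Regional profiles draw biography/location strings verbatim from the filter
term pools subject to the missingness fractions; a regional user missing
both fields is guaranteed a news mention so every planted regional user is
recoverable in principle. A configurable fraction of non-regional users
receives a homonym confounder location ("Petaling Jaya") and, when
geotagged, coordinates at that locale. Planted per-window tallies are
recounted from the emitted corpus at generation time and asserted equal.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linguistically realistic text (term noise,
misspellings, sarcasm), follower-graph structure and retweet cascades,
user-level heterogeneity in tweet rates beyond the planted mixture,
pseudo-retweet contamination (supported in ingest via the opt-in
`RT @user` heuristic but not planted by default), non-English content, and
profile fields that *almost* match terms in ways token matching cannot
separate. Perfect precision/recall on noise-free synthetic corpora is a
correctness check of the filtration logic, not an accuracy claim about
real streams.

## Numerical and design notes

- Timestamps are stored UTC; local event times are converted with a
  configured UTC offset. Naive input timestamps are taken as UTC.
- The flat-table interchange format escapes embedded tabs/newlines/
  backslashes with backslash escapes and encodes absent optionals as `\N`;
  the write→read round trip is the identity on every field (property
  tested). The escaping scheme is an artifact convention.
- The native retweet flag is authoritative; the `RT @user` prefix
  heuristic is opt-in and off by default, since pseudo-retweets are a
  known contaminant.
- Region probing order is sorted by region id, so points on a shared
  boundary resolve deterministically.
- QA sampling uses numpy's Generator with the run seed; identical seeds
  reproduce identical samples.
- Degenerate inputs: empty windows yield zero counts with `None` means;
  zero GPS-active users yields an undefined (flagged) accuracy; fold
  change with a zero pre value raises rather than returning infinity.
- Pipeline intermediates are persisted as flat tables/CSV/JSON per stage,
  and the manifest keeps two funnels (tweet counts and user counts), each
  monotonically non-increasing through filtration.

## Problem sizes

The shipped test and acceptance runs use synthetic corpora of 40–2,000
users (up to ~10⁴ tweets), which is ample for the identities, oracle
equivalences and ground-truth-recovery properties being checked; the
`--profile study` preset of the `synth` command generates the ~10⁴-user,
~10⁵-tweet regime of the modelled corpus for heavier experiments.

## Known limitations

Rule-based triangulation cannot see users who share no profile signal and
mention no outlet — anonymity bounds recall on real data. Term lists are
English-only and region-specific; porting the method means rewriting the
criteria config, not the code. The shipped polygons are coarse stand-ins;
accuracy figures against them say nothing about boundary-adjacent users.
The reported-value fixtures encode published window columns and validation
tallies for arithmetic-identity checks only — the underlying corpus is
proprietary and its per-row counts are not recomputable.
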