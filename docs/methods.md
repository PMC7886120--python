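# Methods

## Cohort model

The unit of analysis is an *index-diagnosis cohort*: every patient whose
claims contain at least one code whose 3-character ICD-10 category
equals the index category (default `F32`).  The index date is the
earliest such claim.  Two code sets are derived per patient from
truncated categories:

* **medical histories** — categories claimed in `[index − 730 d, index)`;
* **complications** — categories claimed in `(index, index + 730 d]`.

Both windows are half-open at the index date: a claim on the index day
that is not the index code belongs to neither set.  This is a
convention, chosen to avoid ambiguity about same-day comorbid coding;
the boundary claims (exactly 730 days before, exactly 730 days after)
are *inside* their windows.  Multiplicity and within-window timing are
discarded — a history is a per-patient yes/no variable — so duplicate
claims collapse silently and row order never matters.  The index
category itself is excluded from both sets (only the index category, not
neighbouring mood-disorder categories; excluding a broader code set is a
study-design decision left to the user via the input data).  "New"
patient means first index claim within the observed data; no washout
period beyond the data start is imposed.  Truncation to 3 characters is
the default granularity because claims analyses conventionally report
category-level disease labels; codes shorter than 3 characters pass
through unchanged with a one-time warning.

`require_full_windows` (default off) drops patients whose observed claim
span does not cover both full windows.  It is off by default because it
changes the cohort size t, and hence every support value, in a way that
depends on enrollment artefacts rather than on the association
structure.

## Rule indices and mining

For ordered pair (X, Y): a = both, b = X only, c = Y only, d = neither,
t = a+b+c+d.  support = a/t, confidence = a/(a+b),
lift = {a/(a+b)}/{(a+c)/t}.  Zero denominators raise a typed error
(`UndefinedIndexError`); undefined rules are never emitted.

Frequent unordered pairs are found with the Apriori pruning step: a pair
is counted only if both singleton counts reach the threshold (sound
because a joint count never exceeds a marginal; verified against
exhaustive enumeration in the tests).  Both directed rules of every
frequent pair are evaluated, since confidence and lift are asymmetric
and both orientations of a pair can be of interest.  Default filters:

| parameter        | default | meaning |
|------------------|---------|---------|
| `min_pair_count` | 51      | discard pairs observed in ≤ 50 patients (infrequency cut) |
| `min_confidence` | 0.5     | report only rules right at least half the time |
| `top_k`          | none    | optional truncation of the sorted table |

The infrequency cut is interpreted as a threshold on the *joint* count
a.  Sorting is support descending, then confidence descending, then
lexicographic codes — a deterministic total order.  Only single
antecedent → single consequent rules are mined; higher-order itemsets
are out of scope.

**Stratified second stage.**  The stratum of an antecedent pair (X, Y)
is the subset of patients with both codes in their pre-onset set; its
size equals the contingency a of the pair on the pre matrix and becomes
the t of the stratified analysis, which mines the subset's post-onset
matrix with the same machinery.  Stratum selection policies: `top_n`
(first n distinct unordered pairs of the sorted pre-onset table, both
orientations counting once), `top_n_excluding` (same, skipping rules
that touch an excluded code set — useful when one ubiquitous category
dominates the top of the table), and `explicit`.

## Mapper

Each rule is a point in (support, confidence, lift) space.  Because the
first two are fractions and lift is a ratio around 1, columns are
z-scored (sample SD) before distances by default; raw mode is available.
A constant column standardises to zeros with a warning rather than NaN.

* **Distance**: Euclidean (the only metric in v1).
* **Lens (filter)**: default eccentricity — the mean of a point's
  distance-matrix row, self-distance included.  Alternatives:
  `coordinate` (one column of the standardized matrix) and
  `max_variance_projection` (projection on the first principal
  direction, sign fixed so the largest-magnitude loading is positive).
  Eccentricity is a reasonable default for unlabelled rule clouds;
  the projection lens is the right choice when the cloud is expected to
  split along its dominant axis, as in the two-blob reference fixture.
* **Cover**: with range R = max − min of the lens values, interval
  length L = R / (n − (n−1)·ω) for n intervals at overlap fraction ω,
  interval i starting at min + i·L·(1−ω).  Consecutive intervals then
  overlap by exactly ω·L.  Membership is half-open [lo, hi) with the
  last interval closed, so ω = 0 gives an exact partition (and a nerve
  with no edges when each preimage is one cluster).  Constant lens
  values yield a single unit-width interval.  Note ω ≤ 0.5 bounds the
  coverage multiplicity of interior points at 2; larger overlaps are
  allowed and cover points up to ⌈1/(1−ω)⌉ deep.
* **Clustering**: single linkage on each interval's preimage.  The cut
  threshold is chosen from a `num_bins`-bin (default 10) histogram of
  the dendrogram merge heights over [0, max height]: the first empty bin
  above the first occupied one marks a gap in the merge-height
  distribution, and the cut is placed at its left edge.  No gap (e.g.
  all merges at numerically one height) means one cluster; a singleton
  preimage is one cluster.  Histogramming from 0 rather than from the
  smallest merge keeps the heuristic from amplifying noise-level height
  variation into spurious gaps, which matters for dense, evenly spread
  preimages.
* **Nerve**: one node per cluster with size and per-index means (of the
  raw, unstandardized values) attached; an edge joins clusters from
  different intervals with intersecting members, weighted by the
  intersection size.  No self or same-interval edges.  Connected
  components are reported in a deterministic order (member count
  descending, then smallest member rule id) as a stand-in for
  presentation-style group labels.

The chain contains no randomness, so a rerun with the same inputs and
configuration reproduces the graph exactly.

## Synthetic claims generator

The generator emulates the structure of an index-diagnosis cohort drawn
from an employment-based claims database: every patient receives one
index claim at a date uniform over a multi-year enrollment span chosen
so both 730-day windows fit inside the observation period; background
categories are independent per patient and window; planted pairs are
drawn as X ~ Bern(p_x), Y|X ~ Bern(conf), Y|¬X ~ Bern(p_y_base), giving
closed-form indices support = p_x·conf, confidence = conf,
lift = conf / (p_x·conf + (1−p_x)·p_y_base).  A stratified planted rule
applies this dependence only inside the stratum of a pre-onset pair and
leaves X, Y independent elsewhere, so the pair's cohort-wide confidence
is a dilution of its in-stratum value — the signature the stratified
mining stage is designed to detect.  Event dates are uniform strictly
inside their window; since the analysis discards within-window timing,
the date distribution exists only to exercise the windowing code.  Each
present code is emitted as one claim (configurable duplicates for
testing duplicate collapse).  All draws come from one seeded generator
in a fixed order, so output is byte-reproducible.

The default study cohort (`default_study_config`) uses 5,000 patients,
50 background categories with geometrically decaying prevalence (0.30
down to ~0.01), 12 planted pre-onset pairs spanning support 2–10 %,
confidence 0.50–0.72 and lift 1.1–6 (magnitudes typical of published
claims-cohort rule tables), and one stratified post-onset pair at
confidence 0.593 inside the anxiety + sleep-disorder stratum.  Cohort
size 5,000 keeps a full two-stage run around a second while leaving
binomial noise on a confidence estimate near ±0.01–0.04.

**What the generator does not emulate**: realistic ICD-10 frequency
profiles, coding practice variation, seasonality, enrollment churn,
temporal ordering effects, rule-out (suspected) diagnoses, and
higher-than-pairwise dependence.  Passing tests therefore demonstrate
correctness of the *machinery* (counting, filtering, stratification,
graph construction) and estimator consistency under the planted model —
not clinical validity of any mined rule on real data.

## Numerical and degenerate-input choices

* All counting is exact integer arithmetic; indices are computed as
  float ratios only at the end.
* Rule tables print one-decimal percent display columns alongside
  full-precision columns (shortest-repr floats), so reading a table back
  reproduces the mined values bit-for-bit.
* Empty cohort → empty journey list (logged), but a pipeline run aborts
  with a manifest recording the failed stage, since nothing downstream
  is meaningful.
* A stratum absent from the data yields `(0, [])`, not an error.
* Mapper needs ≥ 2 rules; the pipeline skips graph construction (with a
  log line and a manifest flag) below `min_rules_for_mapper`
  (default 10) — small rule tables are more legible as tables.
* The last cover interval's upper edge is clamped up to the observed
  maximum to guard against float round-off excluding the extreme point.

## Known limitations

* Pairwise rules only; no sequence/temporal rules, no significance
  testing of rules (support/confidence/lift only, by design).
* One index code per run; no multi-disease batch mode.
* Euclidean Mapper with a scalar lens; no 2-D lens combinations, no
  persistent homology.
* The histogram-gap clusterer is a heuristic: its cluster count is
  sensitive to `num_bins` for preimages whose merge-height distribution
  is close to uniform.
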