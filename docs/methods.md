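# Methods

This note records the scientific and numerical choices behind
`falltiers`: the tiered detection model, the conventions that were
genuinely open, the synthetic-data design, and what the tests do and do
not establish.

## Signal model and framing

Streams are tri-axial accelerations in m/s² (the raw Android convention;
a resting device reads a vector of magnitude ≈ 9.80665 m/s² = 1 g),
sampled nominally at 20 Hz and blocked into consecutive,
**non-overlapping** 3 s frames of N = 60 samples. Non-overlap matches the
arithmetic of roughly 28,800 analyzed windows per 24 h day; a trailing
partial frame is dropped rather than padded, because a partial window has
no defined feature semantics. Timestamps are accepted when successive
gaps stay within ±50% of the nominal interval; larger irregularities are
logged and framing proceeds by sample count, since fixed-rate hardware
sampling is assumed throughout. The internal canonical unit is m/s²; the
DT thresholds are expressed in g and converted at comparison time.

## Tier conventions

**Pre-elimination.** The motionless test is per successive sample pair
(L1 difference of the three axes strictly below `th_pe`); a frame is
eliminated only when *all* of its pairs pass, so a single spike always
escapes to the downstream tiers — eliminating any frame containing
activity would risk missing a fall, which is the one error this tier must
never make. `th_pe = 7` is applied in m/s²: 7 m/s² of summed axis change
is a plausible motion gate, whereas 7 g would eliminate nearly
everything. The unit is configurable (`pre_elimination.th_pe`).

**Double thresholding.** The per-frame statistic is the *maximum*
per-sample SV within the frame, for both the event frame (the impact peak
determines severity) and the post frame (the maximum is the strictest
possible inactivity test: a still person's SV stays near 1 g). Boundary
ties are fixed so the four regions partition the quarter-plane exactly:
`SV_t = th_low` is still a low event; `SV_t = th_high` with an inactive
post frame is still ambiguous (not yet harsh); `SV_{t+1} = th_inactivity`
counts as continued activity. The decision for frame *t* is emitted only
once frame *t+1* is complete (≈ 3 s latency). The final frame of a finite
stream has no successor: it is resolved by PE if motionless and otherwise
reported with the `AMBIGUOUS_END` sentinel — a continuously monitoring
device never reaches this case.

**Features.** The 43-name schema and its order are frozen
(`FEATURE_NAMES`) so models and tables can never mis-align. Standard
deviation is the population form (divide by N), the natural convention
for a fixed-length window statistic. "Average consecutive differences"
uses *absolute* differences: signed differences telescope to
≈ (last−first)/N and carry almost no information, while the feature group
is meant to capture suddenness of trajectory changes. Binned
distributions use 10 equal-width bins over the frame's own [min, max]
(last bin right-closed, degenerate range → all mass in bin 0). Features
stay in raw m/s²; the tree is scale-equivariant per feature, so
normalization would change nothing.

**Feature selection.** OneR scores each feature by the training accuracy
of its best one-level rule, using the classical supervised discretization
with a minimum of 6 majority-class instances per interval (the
traditional default; the bucketing parameter is exposed). Score ties are
broken by frozen schema order for reproducibility. The final
configuration keeps the top 5 features. Classical Relief (k = 1 neighbor,
all-instance sampling, min-max-normalized Manhattan distances) is
provided as a secondary ranker; an SVM-weight ranker is deliberately out
of scope.

**Tree.** Binary numeric splits only; candidate thresholds are midpoints
between consecutive distinct sorted values; among candidates with
strictly positive information gain the split maximizing gain ratio
(gain / split information, bits) is chosen, ties resolved by lowest
schema index then lowest threshold. Recursion stops at purity, below
`2·min_leaf` instances (default `min_leaf = 2`), or when no candidate
gains; leaves predict the majority class. No pruning is applied — the
bare induction rule is kept reproducible, and the synthetic classes are
clean enough that pruning would be inert. Models serialize to a versioned
human-readable JSON document.

**Engine.** Per-tier call counters (`CallCounters`) expose the
computational content of the energy argument: eliminated frames incur
zero SV/feature/tree work, and feature extraction and prediction run
exactly once per ML-decided frame. The double-buffer feed reproduces the
acquisition/detection split of a deployed system in simulated time:
ingestion never blocks on decisions, whole frames are handed over, and a
lagging consumer queues frames rather than dropping them. The alert
state machine uses a 20 s cancellation window; notification delivery is a
pluggable sink (no SMS/geo-location).

## Synthetic data

The generator emulates the *phenomenology the tiers threshold on*, not
biomechanics. Each event is an SV profile m(t) in g applied along a
random gravity direction (uniform on the sphere, fixed within an event),
plus a small perpendicular wobble and additive Gaussian sensor noise
(default σ = 0.1 m/s² per axis). Orientation randomization prevents
per-axis features from being trivially informative while leaving the
SV-based tiers orientation-invariant by construction.

Profiles: stillness is gravity + noise. Gait is a sinusoidal SV
oscillation (walk ≈ 2 Hz / 0.25 g amplitude, run ≈ 3 Hz / 0.55 g, stairs
between), with running tapering to 0.4 g amplitude in its final frame so
a gait bout ends below `th_low` while keeping its predecessor's post
frame above `th_inactivity`. Falls are a free-fall dip (to 0.2–0.42 g for
0.25–0.45 s), a one-sample impact spike, a fast ringdown, then at least
one frame of lying still; harsh variants peak near 3 g (always caught by
DT), slow-pace and on-knees variants peak in the ambiguous 1.5–2.4 g band
(always reaching the ML tier); falls out of walking/running prepend the
gait profile. Postural transitions (sit down, stand up) briefly unweight
the body to ≈ 0.8 g and end in a sharp contact jolt to ≈ 1.8–1.9 g — the
jolt is what lets them escape pre-elimination and, when followed by
stillness (a per-event coin flip by default), populate region II with
non-falls. Impact peaks carry ±10% per-event jitter and the dip/onset
timings vary, so classes overlap in individual features.

What this establishes — and does not: falls differ from sit-downs chiefly
through the deeper and longer free-fall dip (visible in the average
resultant acceleration and the binned distributions). That separation is
a *modeling choice*, motivated by physics but not fitted to recorded
falls; passing the held-out benchmark shows the pipeline's machinery is
correct and well-calibrated for these conditions, not that real-world
sensitivity would match. Real recorded falls include orientation changes
after impact, soft or staged impacts, and sensor saturation (±2 g ranges
clip harsh impacts), none of which are modeled.

Benchmark composition spreads events near-uniformly over the six fall
and six ADL kinds; events are shuffled and separated by one motionless
padding frame. The daily-life preset interleaves ADL bouts (walk-heavy
mix) into stillness at a target activity fraction; at 10% activity the PE
tier resolves the large majority of frames — gentle gait frequently stays
under the 7 m/s² gate, which is precisely the tier's function.

All randomness flows from one seed: the pipeline seed fans out to named
sub-seeds (generate / selection / training / …) via a CRC-keyed seed
sequence, and each event draws its own spawned generator, so any stage
can be re-run independently and traces are bit-reproducible.

## Evaluation

Scoring is event-level — a fall event counts as detected when at least
one of its frames is decided FALL — because detectors are judged on
events, not windows; a frame-level false-positive view exists for
long-duration analyses. Sensitivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP); reported percentages round half-up to one
decimal while machine output keeps full precision. Accuracy is the
balanced form (sensitivity + specificity)/2, chosen to neutralize the
heavy non-fall majority. F-measure is 2TP/(2TP+FP+FN).

McNemar's comparison of two detectors uses the asymptotic statistic
(b−c)²/(b+c) on the discordant counts against chi-square with 1 df,
two-sided by default (a one-sided option exists for directional
hypotheses). The continuity-corrected variant (|b−c|−1)²/(b+c) is the
form that tracks the exact binomial sign test (within ~0.01 in p for
b+c ≥ 25); the plain form overshoots the tail slightly at small counts.

Threshold calibration sweeps a grid of (th_low, th_high, th_inactivity)
triples over a labeled trace, scoring each point event-wise with either a
pass-through oracle for region II (an upper bound assuming a perfect ML
tier) or region-II-dependent events excluded. The chosen point maximizes
TPR among those attaining the minimal FPR (lexicographic, favoring few
false alarms first — the deployment priority).

## Problem sizes and defaults

The study sizes used by `scripts/acceptance.py` are a 200-event training
set (80 falls / 120 ADLs), a disjoint 1,050-event benchmark (150 falls /
900 ADLs, mirroring the detector-evaluation design the thresholds were
built for), and a one-hour daily-life trace at 10% activity for routing
and false-alarm measurement. Pipeline defaults: Th_PE 7 m/s², Th_low
1.5 g, Th_high 2.4 g, Th_inactivity 1.3 g, 20 Hz × 3 s framing, top-5
features, `min_leaf` 2, `min_bucket` 6, 20 s cancel window. All are
overridable via the YAML config; unknown keys are rejected.

## Known limitations

- The generator's waveforms are stylized; quantitative results on it do
  not transfer to recorded human falls (see above).
- Sub-regions I vs VI and IV vs V of the DT plane are merged: their
  outcomes are identical and their geometric boundary adds nothing to
  the decision.
- No adaptive or per-user thresholds; no pruning in the tree; no
  missing-value handling (the extractor cannot produce missing values).
- The alert mechanism is simulated (no audio, SMS or geo-location), and
  live sensor acquisition is out of scope.
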