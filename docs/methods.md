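# Methods

This note documents the models and procedures implemented in `mcmine`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions that make the pipeline
deterministic.

## Low-level recognizers

### Inertial activity

Streams are 3-axis accelerometer + 3-axis gyroscope at 50 Hz from a
smartphone and a smartwatch, segmented into non-overlapping 3-s windows
(150 samples). The smartphone's placement is unconstrained, so its two
triads are collapsed to acceleration- and turn-rate-magnitude channels
before feature extraction — any global rotation of the phone is then
invisible to the classifier (asserted by test). The watch is
wrist-fixed, so its six raw axes are kept and its two magnitudes added,
giving 10 effective channels.

Per channel: mean, zero-crossing rate (sign changes of the mean-removed
signal over n−1), max, min, population σ, quartiles Q1/Q2/Q3 (linear
interpolation between order statistics), range, and the first m = 5 real
cepstrum coefficients (inverse FFT of the log magnitude spectrum, log
floored at 1e−12 so constant channels stay finite). 10 × 14 = 140
features, z-scored with training statistics.

Classification is k-nearest-neighbour with k = 3 under Euclidean
distance. The neighbour search is an explicit scan with a stable sort,
so equal distances resolve by training-row order; a vote tie goes to the
tied label with the nearest single neighbour. These conventions are part
of the contract (the test suite checks equivalence with a brute-force
oracle, ties included), which is why the search is not delegated to a
library with unspecified tie behaviour. A window missing one device is
imputed with training-mean features for the absent device.

### Skeleton (video) activity

20-joint 3-D skeletons at 30 fps, 3-s windows with 50 % overlap.
Only the six indoor activities are legal; training data containing
Walking or Running is rejected. Per configured joint pair, each frame
yields the Euclidean inter-joint distance and the elevation angle of the
joint-joint vector above the camera's horizontal (x, z) plane
(`atan2(Δy, hypot(Δx, Δz))` ∈ [−π/2, π/2]; coincident joints give
(0, 0)); the window feature is the per-pair mean and population σ of
both. Features depend only on coordinate differences, hence are
invariant to global translation. The default pair list is the 19 bone
edges plus 6 cross-limb pairs (hand–hand, hand–head ×2, foot–foot,
hand–hip ×2) — all 190 pairs of a 20-joint skeleton would be quadratic
with little added signal; the list is configurable. The classifier is a
CART decision tree (Gini, min leaf 2, fixed seed for tie-breaks).

### Audio emotion

Mono speech at 44.1 kHz, framed at 25 ms / 10 ms hop throughout. Voice
activity detection thresholds frame energy at
`min(1.5 × median, 0.5 × max)`: the median term adapts to the noise
floor, while the max term prevents a uniformly loud signal from
suppressing itself (an all-silent signal yields an all-false mask). The
voiced stream is cut into non-overlapping 3-s segments whose order is
shuffled with a seeded RNG — segment order cannot be used to
reconstruct the conversation, a privacy measure that costs nothing
because features are per-segment. At prediction time live windows are
silence-trimmed the same way, so they match the training distribution;
windows with under 0.5 s of voiced material are skipped.

Features (34 per segment): mean/σ of log frame energy; mean/σ/range of
the per-voiced-frame pitch; min/max/skewness of frame energies; mean/σ
of the first 13 MFCCs. Pitch is the autocorrelation peak (via the power
spectrum) in the 60–400 Hz band with parabolic lag refinement — ≤ 5 Hz
error on pure tones across 80–350 Hz (swept in tests). MFCCs use a
Hamming window, 2048-point FFT, 26 triangular mel filters to the Nyquist
frequency and an orthonormal DCT-II; a pure gain change moves only
coefficient 0. The classifier is an RBF-kernel SVM with γ = 0.01 and
C = 1 (one-vs-one) on z-scored features; an optional grid search over
(γ, C) is available but the fixed values are the default.

### Location

Per-second GPS fixes resolve against a per-user personal map of the five
places, each a (lat, lon, radius) disc with a 50 m default radius. A fix
maps to the nearest place whose haversine distance (mean Earth radius
6371.0088 km) is within its radius, ties broken lexicographically;
otherwise `Unknown`, which produces no decision. A gap of more than 5 s
without an in-radius fix finalizes the open location context.

## Fusion, notification, high-level inference

Decisions are fused every 3 s in slots aligned to the session origin.
Vertical fusion is simple majority within one recognizer's slot
decisions; a tie goes to the label with the most recent decision
(recency as freshness). Horizontal fusion sums, per label, the weights
of the recognizers voting for it; weights are renormalized over the
recognizers actually present, making the outcome invariant to uniform
scaling and reducing to plain majority under equal weights. Weights
derive from recognizer performance, w_i = a_i / Σ a_j; the shipped
activity weights (0.5076 inertial, 0.4924 video) strictly favour the
inertial recognizer in any two-way disagreement. Emotion and location
have single recognizers, so their horizontal step is the identity (kept
in the code path for uniformity).

The notifier emits an event only when the fused label differs from the
last notified one; event counts therefore equal label-run boundaries
exactly (tested against a run-length oracle). Streams that go quiet
(> 5 s without a decision, for emotion and location) emit a finalization
that closes the open context; the next label always notifies.

Each change event closes the store's open context for its (user,
category) at the event time and opens a new one; records are half-open
intervals [t_start, t_end) and an instant t is inside iff
t_start ≤ t < t_end (open end: t ≥ t_start). The store enforces at most
one open low-level context per (user, category) and one open high-level
context per user. On every new LLC, the engine queries the user's
concurrent contexts at the new start time, composes them (at most one
per category — a duplicate signals corruption), verifies the
composition (legal labels, single user, all intervals containing the
start), and classifies it by scanning definitions in priority order,
returning the first match or `Unclassified`. A finalization triggers
re-inference with the reduced composition, so the high-level state can
degrade gracefully when a stream disappears.

The definitional model replaces a full ontology reasoner: each rule is
(required activities, allowed locations, allowed emotions, priority),
`ANY` matches anything including an absent category, an explicit set
never matches an absent one, and priorities are unique with more
specific rules ranked first. The defaults are

| priority | class | activities | locations |
|---|---|---|---|
| 1 | OfficeWork | Sitting | Office |
| 2 | HavingMeal | Eating | Home, Restaurant |
| 3 | Housework | Sweeping | Home |
| 4 | Exercising | Running, Stretching, Walking | Gym |
| 5 | Exercising | Running | ANY |
| 6 | Inactivity | Sitting, Standing, LyingDown | ANY |

with every rule accepting any emotion — the package's own instantiation
of the principle that what a person does and where outranks how they
sound. Definitions load from YAML/JSON and can be swapped at runtime;
instances optionally export as RDF/Turtle.

## Synthetic data

The generator produces the *study conditions*: 10 training subjects and
5 further scenario subjects, each with seeded offsets on every signature
parameter (amplitudes ±10 %, frequencies ±5 %, gravity directions
jittered, voice register ±7 %, loudness ±15 %), so leave-one-subject-out
folds genuinely differ between train and test.

Activity signatures are sinusoidal accelerations of class-specific
amplitude and frequency on top of a gravity orientation — e.g. Sitting
(0.1 m/s², static), Walking (2 m/s² @ 2 Hz), Running (6 m/s² @ 3 Hz),
Eating (wrist bursts at 0.3 duty) — static classes get smoothed
aperiodic sway instead of a tone. Skeleton streams pose a 20-joint stick
figure per class and oscillate the relevant limbs. Emotion audio is a
five-harmonic voice source with per-burst pitch and loudness drawn from
class distributions that overlap in pairs (Anger/Happiness loud-high,
Neutral/Sadness soft-low), separated by silences. GPS fixes are Gaussian
(σ = 5 m) around place centres a few hundred metres apart.

Scenario scripts are eight one-minute steps covering all five high-level
classes; skeleton packets exist only during indoor activities and audio
only during steps with a scripted emotion. Ground truth is exact by
construction.

**What passing these tests shows — and does not.** The benchmark bars
(macro-F ≥ 0.90 inertial/skeleton, ≥ 0.75 emotion, ≥ 0.99 place
resolution, ≥ 95 % high-level slot accuracy) demonstrate that the
*pipeline machinery* — windowing, features, classifiers, fusion,
notification, inference — is correct and end-to-end trainable. They say
nothing about accuracy on real recordings: the signatures are
caricatures without transitions, co-articulated activities, sensor
artifacts, real prosody or GPS multipath. The emotion signatures overlap
by design so that the live emotion track shows genuine misrecognitions
(≈ 0.84 slot accuracy in replays) while the high-level timeline stays
perfect — reproducing the robustness *structure*, not any numeric
result, of real deployments.

## Numerical and design conventions

- Window sample counts are `round(window_s × rate)`; consecutive window
  starts differ by exactly the hop. Out-of-order packets are rejected;
  a gap in a stream resets its buffer (the stale partial window is
  dropped) rather than bridging the gap with misdated samples.
- Fusion slots are `[3k, 3k+3)` from the session origin; decision
  timestamps are window starts, so replay introduces no artificial
  latency.
- Scoring excludes *transition slots*: with 3-s windows at up to 50 %
  overlap, any slot intersecting (boundary − 3 s, boundary + 3 s) can
  contain straddling windows and is left out, mirroring the absence of
  a null-class/transition model in the recognizers.
- Problem sizes used by the acceptance script: 10 subjects × 8
  activities × 10 windows (inertial), × 6 classes × 19 windows
  (skeleton), × 4 emotions × 8 segments (audio), 2000 Monte-Carlo fixes,
  and 5 scenario replays of 8 minutes — sizes chosen so the full
  from-scratch run completes in minutes while every class keeps enough
  support per fold.
- All randomness flows from explicit seeds through
  `numpy.random.SeedSequence`; two runs of simulate → train → replay
  with the same seed produce byte-identical metrics JSON (tested).

## Known limitations

- The definitional matcher reproduces observable classification
  behaviour only; there is no description-logic reasoning, property
  chains or cardinality axioms beyond "one constituent per category".
- Single-process, in-order streaming; no transport, back-pressure or
  clock skew handling. Multi-user state is keyed but scenarios are
  single-user.
- The audio recognizer assumes the training and live VAD see similar
  speech styles; heavily whispered or clipped speech would shift the
  energy functionals.
- Physiological/video emotion recognition and audio-based activity
  recognition are out of scope, as is skeleton estimation from raw
  depth video — the skeleton recognizer starts from joint coordinates.
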