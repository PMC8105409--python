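# Methods

This note documents the models and procedures implemented in
`songstates`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real recordings.

## Acoustic features

Songs are analyzed in 10 ms Hann-tapered FFT windows stepped every
1 ms (`FeatureConfig.window_ms`, `step_ms`). Spectra are restricted to
the zebra finch song band, 300–8600 Hz, before any feature is
computed, so low-frequency room noise cannot dominate the Wiener
entropy. A window is *voiced* when its amplitude exceeds
`threshold_db` (default 50 dB) against an uncalibrated `baseline_db`
(default 70 dB = full-scale RMS); both are configuration, not
constants, because absolute levels depend on the recording chain.

Per-feature notes:

- **Wiener entropy** `log(geometric mean / arithmetic mean)` of the
  power spectrum is computed from the *native-resolution* (unpadded)
  spectrum, lightly smoothed across frequency
  (`spectral_smooth_bins = 7`) so that the chi-squared fluctuations of
  a single periodogram do not bias broadband sounds away from zero,
  and with spectral bins floored at `wiener_floor = 1e-3` of the
  arithmetic mean. Without the floor, the entropy of tonal sounds is
  hypersensitive to the noise floor: near-empty bins contribute
  unbounded log terms. The floor bounds the statistic below at about
  −6.9; white noise sits near 0 and pure tones well below −3.
- **Pitch** uses a weighted harmonic-sum estimator: candidate
  fundamentals are scored by `Σ_k S(k f0)/k` (the 1/k weights break
  octave ties toward the true fundamental), refined by parabolic
  interpolation. Windows whose harmonic-sum peak explains less than
  `harmonicity_min = 0.08` of band power fall back to the spectral
  centroid of the pitch band — noisy sounds get a stable, if nominal,
  pitch. Pitch is then smoothed over `pitch_smooth_ms = 11` within
  each voiced run: pitch moves on syllable timescales, so the
  smoothing suppresses per-window estimator noise without distorting
  frequency sweeps.
- **Frequency modulation** is the ratio of time- to
  frequency-direction derivatives of the amplitude-normalized
  spectrum; for an ideal moving ridge this equals the ridge slope in
  Hz/ms. Derivative energies are averaged over `fm_avg_ms = 15` before
  the ratio (stability against broadband noise), and the slope maps to
  degrees via `atan(slope / fm_scale_hz_per_ms)` with a 5 Hz/ms scale,
  so typical song sweeps span roughly 10–70°. The modulation
  *direction* is the sign of the time–frequency derivative
  correlation, reported only when |correlation| exceeds 0.2;
  unmodulated sounds get sign 0 instead of a noise-driven coin flip.
- **Spectral continuity** is the cosine similarity of smoothed spectra
  3 ms apart, in [0, 1].

These contracts are behavioral: the reference tools in this field do
not publish bit-exact algorithms for pitch or continuity, so the
extractor is designed to satisfy the documented invariants (amplitude
scaling shifts only amplitude; tones yield their frequency to within
2%; chirps yield higher FM than tones; white noise yields near-zero
entropy) rather than to replicate any specific implementation.

## Vocal states and song diversity

The 10-state partition is population-level: voiced windows from all
birds are pooled, the pitch density (histogram smoothed with a
Silverman-style bandwidth) is cut at the three deepest minima between
its four most prominent modes, and within each pitch region cluster
centers are found as density peaks in the (signed FM, Wiener entropy)
plane. Default states per region are 2/3/3/2 from very-low to high
pitch — down/up modulated states at the pitch extremes, and
down/unmodulated/up triplets in the two central regions.

Numerical choices: peak selection treats two maxima as one cluster
unless they differ along FM by ≥ 0.8 population standard deviations
(or, failing that, by ≥ 2 standard deviations of entropy) — within-
cluster entropy fluctuations are comparable to between-cluster entropy
differences, so entropy alone rarely separates states, while the
up/flat/down modulation classes always do. When fewer separated
maxima exist than required states, remaining centers are placed on the
populated density bin farthest from every chosen center, so sparse but
real clusters are not absorbed by dominant ones. Assignment is nearest
center (features scaled by their population standard deviations)
within the window's pitch region; windows outside the fitted pitch
range clip to the nearest region; ties go to the lower state label.
Every voiced window therefore receives exactly one label — no
residuals. The partition serializes to versioned JSON and can also be
hand-specified, e.g. to encode boundaries read off a published figure.

Song diversity is the Shannon entropy (base 2) of the bird's
state-abundance vector, in [0, 3.32] bits; pooled diversity applies
the same entropy to the count-weighted mean abundance vector, and by
concavity is never below the weighted mean of member diversities.

## Similarity and influence

Two songs are compared through 70 ms windows of the per-millisecond
feature sequence (log pitch, signed FM, Wiener entropy, continuity),
hopped every 3 ms and confined to voiced segments, so windows never
straddle silent gaps. The distance between two windows is the trimmed
mean (worst 35% of frames dropped) of frame-wise Euclidean distances
after scaling each feature by its *measurement resolution* — 4%
relative pitch, 8° FM, 1.2 entropy units, 0.1 continuity — not by its
population spread. Three deliberate choices live here:

- *Log pitch*: similarity of pitch is relative; a 3% shift means the
  same thing at 500 Hz and at 2500 Hz.
- *Resolution scaling*: population-spread scaling makes the legitimate
  variation between two birds' renditions of the same species-typical
  sound smaller than measurement noise, which would make true copies
  indistinguishable from merely same-category sounds. Scaling by the
  extractor's resolution keeps genuine copies (which differ only by
  measurement noise plus a few percent of copy jitter) far closer than
  different birds' instances.
- *Trimming*: syllable junctions and transients contaminate a minority
  of frames in a window; a 35% trim makes the distance robust to them.
  The null model computes the identical statistic, so p-values remain
  calibrated.

Distances convert to p-values by left-tail rank against an empirical
null of window distances between unrelated birds' songs (default
50,000 sampled cross-bird pairs; at least 20 birds). A window pair is
significant when its p-value is below `alpha / 8`: false matches are
driven by coincidentally close sound pairs rather than by the raw
count of heavily overlapping window comparisons, and the fixed
divisor of 8 holds the false-coverage rate of unrelated songs near
`alpha` across the song lengths this pipeline sees (calibrated on
synthetic corpora; it is a configuration-level constant, not fitted
per song). Significant pairs are grouped into diagonally contiguous
*sections* (runs break across >30 ms time jumps), each section's
p-value is a Fisher combination of its de-overlapped window p-values,
and the score is the percentage of the reference song's voiced
duration covered by retained sections. The computation is repeated
five times with the reference motif boundaries jittered by ±10 ms
(seeded) and the median is reported, emulating the variability of
manually outlined motifs. Influence is the identical computation with
the pupil's song as the covered reference.

One consequence worth knowing: unrelated birds drawing syllables from
a shared species-typical repertoire occasionally produce
near-identical renditions. Such pairs legitimately score one
syllable's worth of similarity (~10–20% for desk-scale songs); the
scorer is calibrated so this stays the exception, not the rule.

## Syllables and recombination

Syllables are voiced segments (gaps under 5 ms merged, segments under
15 ms dropped). Types are assigned within each bird by single-linkage
agglomerative clustering over z-scored (duration, mean pitch, mean
signed FM, mean entropy, mean continuity), cut at 1.5 z-units; each
feature's z-scale is floored at the extractor's resolution so a
near-constant feature cannot amplify pure noise into spurious types.
Labels are canonicalized by first temporal occurrence, making the
clustering invariant to row order. Type diversity and syntax (bigram)
entropy use the same Shannon measure; bigrams never cross bout
boundaries, and the bigram entropy is of the joint bigram
distribution, not a conditional entropy.

Recombination compares syllable boundaries inside similarity sections
(tutor as reference): a pupil syllable linked to two or more
*consecutive* tutor syllables is a merge, a tutor syllable linked to
two or more consecutive pupil syllables a split. Only tutor syllables
covered ≥ 80% by sections count — an operationalization of restricting
the analysis to clearly and fully imitated syllables. The
consecutiveness requirement excludes spurious events from matches
across motif repeats, and events duplicated by motif repetition are
collapsed by their interval-duration signature (20 ms tolerance).
Counts are a lower bound; no correction is applied for the detection
asymmetry between merging and splitting.

## Balanced-imitation statistics

The pair table carries per-pair similarity, influence, diversities,
and the two abundance vectors. Key conventions:

- *Detrending* subtracts each state's mean abundance separately within
  tutors and within pupils, making every state equally abundant on
  average in each role; this guarantees zero expected correlation
  under shuffled pairings (verified by a seeded 1000-shuffle test).
- *Regression* stacks ten detrended points per pair; the slope and
  residual R² come from ordinary least squares (statsmodels), with an
  optional tutor-clustered robust covariance for the repeated-tutor
  dependency. A full mixed-effects replication is deliberately out of
  scope: the detrended regression plus cluster-robust errors keeps the
  statistical contract testable without tying results to a specific
  mixed-model fitter.
- *Diagonal bias* at threshold 0.2: among points with tutor abundance
  above 20%, the fraction the pupil produces at lower abundance, minus
  the same fraction with roles reversed; counts are computed per pair
  and pooled. The *direction-shuffle* null swaps tutor/pupil roles
  within each pair with probability 1/2 (pairs are never broken); the
  direct p-value uses the +1 correction and is never exactly zero.
- *Gain curves* bin tutor abundances into half-open 0.1-wide bins
  centered at multiples of 0.1; the gain is the median pupil abundance
  in a bin over the bin center. The zero-centered bin is omitted (its
  gain is undefined), as are unpopulated bins.
- Quartile partitions sort by the ranking column with stable ties;
  Q1 is always the top quartile. A Bonferroni utility (threshold 0.01)
  is provided for report-level multiple-testing control and is never
  applied inside estimators.

## The synthetic colony

The generator emulates the statistical structure of a breeding-colony
song corpus, not zebra finch timbre. Notes are harmonic stacks (1/k
amplitude harmonics over a linearly swept fundamental) mixed with
band-limited noise; ten archetypes place notes in the ten vocal
states: fundamentals near 480 / 850 / 1500 / 2600 Hz, with
down/up sweeps at the pitch extremes, down/flat/up triplets in the
central regions (the modulated medium-pitch states noisier, the flat
states nearly pure harmonic stacks). Between-bird renditions of an
archetype jitter the fundamental by ±12% and the sweep by ±24%;
tutor-to-pupil copies jitter an existing instance by at most ±1.5%
(within the ≤5% contract), which is what lets the similarity scorer
tell copies from coincidences. Notes within a syllable are joined by a
10 ms crossfade (no junction clicks); the ground-truth abundance
accounting assigns half the crossfade to each neighbor.

Tutor songs realize a target abundance vector (an exponentially tilted
random direction whose tilt is bisected to hit a target entropy) as
45–90 ms notes grouped into 1–3-note syllables, with a motif voiced
budget of 1.3 s repeated twice. Tutor diversities are sampled as
`log2(10) − X`, `X ~ Gamma(2, 0.12)` clipped to [0, 1.05]: median near
3.1 bits with a left tail toward ~2.3 bits, the shape reported for
real colonies. Pupils copy a fidelity-fraction of tutor syllables and
improvise archetype notes so that their total abundances approach
`normalize(tutor_p^beta)`; the improvisation budget grows as
`1 + 0.5 (1 − fidelity)` times the tutor's duration — pupils that copy
less improvise more — which makes influence genuinely drop below
similarity at partial fidelity. Per-pair fidelities get a family-level
Gaussian effect (σ = 0.12) so imitation quality runs in families.
Colonies are organized as founder families with two first-generation
clutches and one chain pair per extra generation; abundance vectors in
the pair table are multinomial samples (n = 3000 windows) of the
realized vectors, emulating estimation from a finite recording.

The balancing transform is a one-parameter stand-in whose `beta = 1`
limit is faithful abundance copying and whose small-`beta` limit
flattens toward uniform — the qualitative shape of the observed gain
curves — enabling parameter-recovery tests without claiming the
biological mechanism.

## What the tests show, and what they do not

All tests run on synthetic corpora at desk scale (tens of birds,
songs of a few seconds, 100-pair colonies), sized so the full suite
and the acceptance script run in minutes on one CPU. They establish
that each operation satisfies its contract under known ground truth:
closed-form entropies; ≥95% state-assignment recovery; 100%/50%
similarity/influence on the copy-plus-improvisation construction;
exact recovery of merge/split constructions; calibrated nulls; correct
ordering of balancing exponents from gain curves. They do not
establish performance on real recordings, where cage noise, calls,
amplitude-dependent segmentation errors, and non-stationary recording
chains add failure modes the generator does not emulate; the partition
module in particular assumes curated song bouts as input.

Known limitations: the similarity score is not bit-compatible with any
existing reference software; there is no time-warping alignment, so
strongly tempo-shifted copies score low; noisy (high-entropy) sounds
have intrinsically less reliable pitch, making their copies harder to
detect than tonal ones; and recombination counts inherit the
merge/split detection asymmetry discussed above.
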