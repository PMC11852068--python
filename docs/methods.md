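# Methods

This note documents the models, estimators and design choices behind the
pipeline, the assumptions they rest on, and what the synthetic validation
does and does not establish about real recordings.

## Synthetic cohort model

Each subject's recording is a channels × samples matrix

x_c(t) = Σ_b s_c,b · g_b(t) · z_b(t) + σ √(fs/1000) · ε_c(t) + A · sin(2π·50·t)

where z_b is a unit-variance band-limited latent oscillator per band
(white noise band-passed with a 4th-order zero-phase Butterworth),
s_c,b ∈ {−1, +1} is a per-channel random mixing sign, ε_c is private white
noise, and A is the mains amplitude. The gain g_b(t) equals `gain_pre`
everywhere except the one-second interval after each event, where it equals
`gain_post` — an instantaneous coupling switch matching the binary pre/post
contrast the analysis makes. Events are spaced 2.5 s apart so epochs never
overlap.

Defaults emulate the target study design: 4 subjects × 60 trials,
16 channels, 30 kHz acquisition, 1 s + 1 s epochs, beta coupling
(0.3, 0.8) and constant (0.2, 0.2) coupling in the other four bands,
`noise_sd = 1`, `line_amp = 1`, mirroring a beta-specific connectivity
increase after target detection.

**Noise convention.** `noise_sd` is the private-noise SD referred to a
1 kHz bandwidth; generation at fs scales the white noise by √(fs/1000) so
its spectral density — and therefore the in-band SNR and the coherence
level — is independent of the generation rate. The 1 kHz "fast" mode
(`config.fast()`) is consequently statistically equivalent to the 30 kHz
default after downsampling (verified: pre/post beta coherence 0.615/0.900
at 1 kHz vs 0.613/0.896 at 30 kHz on matched seeds).

**What the generator does not model:** 1/f background, spikes, transients,
artifacts, non-stationary baselines, behavioural variability, or any
spatial electrode geometry. Passing tests therefore demonstrate that the
pipeline recovers a planted linear-mixing coupling change under Gaussian
noise — not that it would detect effects in real tissue, where effect
sizes, noise spectra and artifact structure differ.

## Preprocessing

All filters are applied forward-backward (zero phase), so band-limited
features do not shift in time; this matters because windows are assigned to
conditions by position relative to the event. Choices where the chain
design was open:

- broadband: 4th-order Butterworth band-pass 1–250 Hz (standard LFP
  practice; stable at these corners);
- notch: 2nd-order IIR at 50 Hz, quality factor 30 (≈1.7 Hz width);
- downsampling: 8th-order Butterworth anti-alias low-pass at 0.4 × fs_out,
  then keep every fs_in/fs_out-th sample (floor length convention);
- epochs: half-open sample range [event − pre·fs, event + post·fs), giving
  exactly 2000 samples at 1 kHz; trials too close to the recording edge
  are excluded with a warning.

A second broadband pass is near-idempotent only for signals whose energy
lies inside the passband; broadband white noise keeps losing
transition-band power on every pass, which is why the idempotence check in
the tests uses in-band noise.

## Coherence networks

Multitaper magnitude-squared coherence with nw = 3 and k = 5 Slepian
tapers per 256-sample window (a standard variance/resolution compromise for
short windows; both exposed in config). The per-pair, per-window network
weight is the arithmetic mean of coherence over the frequency bins inside
the band (bin spacing fs/256 ≈ 3.9 Hz; delta contains a single bin — a
band with no bin raises an error). Estimator facts the tests pin down:
identical signals give coherence 1; independent signals sit at a bias
floor that decreases with taper count (≈1/k); coherence is invariant to
positive channel rescaling.

Windows: n = floor((epoch − win)/step) + 1 = 14 for a 2 s epoch; a window
is "pre" iff its midpoint is strictly before the event sample, which
yields the 7 + 7 condition split (the straddling 8th window counts as
post). Windows overlap 50 %, so consecutive per-window values are serially
dependent — see Statistics.

## Threshold selection

The grid is the 100 interior points i/101, avoiding the degenerate 0 and 1
endpoints. Binarization keeps edges with weight strictly above the
threshold. Each binarized matrix is scored by the Surprise of its detected
community structure: the −log10 cumulative hypergeometric probability of
at least the realized number of intra-community edges when m edges fall
uniformly on M node pairs. The detector is a greedy agglomerative search
that applies, from singletons, the single merge or single-node relabel
that most increases S until no move improves it; candidate order (hence
tie-breaking) is fixed by a seed. The optimal threshold is the argmax of
mean S over every trial-window matrix of every subject, ties broken toward
the smallest threshold (retaining more edges). Scoring is per window with
grand averaging; the largest-connected-component fraction per threshold is
reported as a percolation diagnostic but does not enter the selection
rule.

Numerics: the hypergeometric tail is evaluated in log space from a
log-factorial table, summing whichever of the upper tail or complementary
lower sum is shorter; values are memoized per graph. S of a trivial
partition (all-in-one or all singletons) and of an empty graph is 0 by
construction/convention. Brute-force oracles (exact rational tail sums,
exhaustive partition enumeration) verify both the S values and the greedy
detector on all partitions of graphs with n ≤ 8.

## Graph features

Average node degree k̄ = 2m/N with N fixed at the channel count (isolated
nodes stay in the graph), and Newman modularity Q evaluated on the
partition found by an analogous greedy modularity maximizer (merges plus
single-node refinement, seeded tie-breaks). Features are computed on the
binarized graphs at the band's optimal threshold. Q is computed by the
community-sum identity Σ_c [e_c/m − (d_c/2m)²], which the tests verify
against the literal pairwise double sum and against networkx.

## Statistics

With exactly two conditions, the "ANOVA" is a two-group one-way
fixed-effects ANOVA — identically the square of the pooled-variance t test
(verified numerically). Marks: `**` p < 0.01, `*` p < 0.05, `n.s.`
otherwise; summaries use the n−1 standard deviation, formatted to two
decimals. No multiple-comparison correction is applied.

Two observation granularities are supported. The default treats every
trial × window value as an observation (matching the 7-values-per-condition
decoding granularity). Because 50 %-overlapping windows are serially
dependent within a trial, per-window ANOVAs are mildly anti-conservative;
calibration checks (type-I error, p-value uniformity) therefore use the
trial-mean granularity, whose observations are independent across trials.
Null calibration of the test itself is checked on i.i.d. synthetic feature
tables.

## Decoding

Per subject and feature, rows are (trial, condition) pairs and columns the
7 per-window values in temporal order (14 for the degree‖modularity
concatenation); subjects stack to 480 × 7 or 480 × 14. Folds are
stratified by condition (pooled across subjects; the class balance makes
every fold 50/50). Per-column standardization is fit on training folds
only. Decoder defaults, chosen for small-sample reproducibility rather
than tuned performance:

- margin: linear-kernel SVC, C = 1;
- tree: depth ≤ 5, minimum leaf 5, seeded;
- recurrent: single Elman layer, 16 tanh units, logistic read-out of the
  final state, Adam (lr 1e-2), 50 epochs, batch 16, seeded
  initialization; the combined set is presented as a 7-step sequence of
  (degree, modularity) 2-vectors.

ROC curves pool held-out scores (decision function for the margin decoder,
positive-class probability otherwise) across folds; ties move diagonally,
so the trapezoidal AUC equals P(random positive outscores random negative)
plus half the tie probability.

On null (no-effect) data, cross-validated accuracy sits slightly *below*
0.5 — the standard CV anti-learning artifact: held-out class means are
anti-correlated with training-fold class means. The chance-level tests
bound accuracy from above rather than testing a two-sided 0.5.

## Problem sizes used in validation

The acceptance script runs the full default cohort (4 × 60 trials at
30 kHz; ≈2 min on one CPU). The test suite validates the same 4 × 60
cohort in the statistically equivalent 1 kHz fast mode, recovery of the
planted effect over 20 replicate cohorts of 1 subject × 20 trials (full
Surprise sweep each), and null calibration over 40 constant-coupling
cohorts of 12 trials. Oracle suites use graphs with n ≤ 8 (exhaustive
partition enumeration is exponential in n).

## Known limitations

- Undirected, band-averaged, zero-lag coherence only; no directed or
  frequency-resolved connectivity.
- The Surprise and modularity maximizers are greedy; on small graphs they
  match the exhaustive optimum in ≥ 80 % of random instances (and never
  exceed it), but global optimality is not guaranteed.
- The middle sliding window straddles the event and is assigned by its
  midpoint; a small amount of cross-condition contamination in that window
  is inherent to the windowing.
- Decoding pools subjects without subject-grouped folds by default, so
  reported accuracies include within-subject information; a grouped-fold
  variant can be built by filtering the feature table per subject.
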