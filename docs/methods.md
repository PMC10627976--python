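# Methods

This note records the models, conventions and numerical choices behind
`ppafuse`, in the order data flows through the package.

## Signals and preprocessing

A `Recording` is one subject's channels × samples matrix at a fixed
sampling rate with a TD/ASD label.  The reference geometry is a
151-channel whole-head child MEG system recording 180 s at 1000 Hz; the
bundled default montage reproduces its documented 70 left / 11 midline /
70 right partition, but the true sensor coordinates are not public, so
the assignment is synthetic and only the partition is meaningful.
Hemispheric analyses drop the 11 midline channels and keep one 70-channel
block, preserving order.

Filtering (1–100 Hz band-pass, 50 Hz notch) is always zero-phase
(forward–backward IIR).  This is a deliberate contract rather than a
convenience: the phase feature below is computed from raw DFT phases, and
a causal filter's group delay would rotate every phase by a
frequency-dependent amount.  Upstream artifact handling (ICA, bad-sensor
interpolation) is out of scope; the package assumes cleaned input.

## Spectral features

Both feature families live on the integer 1–100 Hz grid with six
canonical bands — delta (1–4), theta (4–8), alpha (8–13), beta (13–30),
low gamma (30–50), high gamma (50–100 Hz) — with **inclusive** integer
edges, so alpha has N_fb = 6 bins and boundary bins (4, 8, 13, 30, 50 Hz)
belong to both neighbouring bands.  Inclusive edges are the convention
the rest of the arithmetic (band bin counts, feature dimensions) is built
on.

**Band power.**  Welch's method: the record is cut into 8 equal segments
with 50% overlap (180 s → 40 s segments), each Hamming-windowed, and the
squared-magnitude spectra are averaged with one-sided density
normalisation.  Power at integer f is read from the nearest DFT bin —
exact whenever the segment length is an integer number of seconds.  The
band feature is `10·log10` of the arithmetic mean of S_xx over the band's
bins.  The absolute spectral scale is irrelevant by construction: any
fixed positive rescaling shifts every dB value by a constant that the
per-feature z-scoring removes, so only relative band structure reaches
the classifier.  The 50 Hz bin (depressed by the notch in real data) is
retained in both gamma bands.

**Preferred phase angle.**  Phases come from a *single full-length DFT*
of the whole recording — not from Welch segments — evaluated at bin f·T,
which is exact because recordings with a non-integer number of seconds
are rejected rather than interpolated.  For a band, the unit phasors
e^{iθ(f)} of its bins are averaged; the argument of that mean vector is
the PPA, its modulus the phase consistency (1 = all bins in phase, 0 =
uniformly dispersed).  Magnitudes are deliberately ignored: low-power
bins count exactly as much as high-power ones, which is what makes the
feature amplitude-invariant (and means it degrades gracefully, not
silently, as SNR falls).  A degenerate resultant (consistency < 1e−12,
e.g. perfectly uniform phases) yields PPA = 0 rather than an exception;
downstream z-scoring tolerates the arbitrary value.

Feature matrices are channel-major, band-minor: 151 channels × 6 bands =
906 features per subject whole-head, 70 × 6 = 420 per hemisphere.

## Selection and normalisation

Features are z-scored per column using mean and sample standard
deviation (ddof = 1) fitted on *training subjects only* and applied to
validation and test rows; zero-variance columns map to exactly zero and
are flagged.  Ranking uses the classical pooled-variance two-sample
t-test (Welch's variant is switchable), computed on training rows only;
a feature is selected when p < threshold, ranked by ascending p with ties
broken by column index for determinism.  Phase angles are treated as
plain reals in (−π, π] here, which can in principle miss wrap-around
class differences; circular alternatives are out of scope.  The
threshold is not an inference level but a tuning knob, swept over
0.005–0.05 in steps of 0.005 and chosen by mean validation accuracy
(ties toward the smaller threshold).  No multiple-testing correction is
applied, for the same reason.

## Classifier

A fixed two-layer network: 10 tanh hidden units, two softmax outputs read
as posterior probabilities (TD = 0, ASD = 1; decision rule ASD iff
P(ASD) ≥ 0.5, the tie assigned to ASD so the two half-open rules compose
into one).  Training minimises the mean squared error between softmax
outputs and one-hot targets with full-batch Adam steps (learning rate
0.02); full-batch gradient optimisation on this loss is the contract, and
Adam was chosen as a robust, dependency-free realisation of it.  Training
stops at 10 000 epochs, when training MSE reaches 1e−5, or after 6
consecutive epochs of increasing validation MSE — and the returned
weights are always those of the minimal-validation-error epoch, never the
last one.  Weight initialisation is a seeded 1/√fan-in Gaussian; with the
same seed, data and config, training is bit-reproducible.  On small
cohorts the network fits its training set essentially perfectly; early
stopping on the explicit validation split is the only capacity control,
which is why the validation set exists as a first-class citizen in the
fold plan.

## Cross-validation protocol

Stratified fivefold nested CV on subjects: each class is shuffled
(seeded) and dealt round-robin into five mutually exclusive test folds;
within each fold the remaining subjects split 3:1 per class into training
and validation.  For a balanced 60-subject cohort: 18+18 train, 6+6
validation, 6+6 test.  Everything fitted — z-score parameters, t-tests,
network weights — sees training rows only; the p-threshold and the
fusion weight are chosen on validation accuracy only; test subjects are
scored exactly once.  One threshold is chosen per feature kind across
folds (by mean validation accuracy), matching the single-threshold
reporting convention of the protocol.  Per-fold test metrics (accuracy,
sensitivity = ASD recall, specificity = TD recall, in %) are averaged
with SEM = sd/√k.  A reproducibility digest (SHA-256 over selected
feature indices and trained weights) makes leakage testable: corrupting
test rows must leave the digest unchanged.

## Fusion

Feature-level fusion concatenates the normalised PSD and PPA columns
(PSD first) and re-runs selection on the fused matrix, which also curbs
the doubled dimensionality.  Score-level fusion forms
`w·P_psd + (1−w)·P_ppa` per subject and class; rows stay normalised by
convexity.  The weight is swept over {0.1, …, 0.9} on validation scores
pooled across folds and the first maximiser wins, mirroring the
single-threshold convention.  The complementarity diagnostic is one
Pearson coefficient per reseeded CV repetition between the two models'
pooled training P(ASD) scores.  A caveat discovered and documented here:
when both models fit their training subjects near-perfectly — which the
synthetic presets below induce — both score vectors track the labels and
the coefficient approaches 1 regardless of error independence; the
statistic is informative only while training scores vary, as they do on
noisy real-world features.  The per-subject misclassification overlap
(which subjects *both* models get wrong) is the sharper diagnostic in the
saturated regime.

## Empirical chance level

The smallest accuracy k/n whose one-sided tail probability under
Binomial(n, ½) is ≤ α, by exact tail summation (no normal
approximation).  For n = 60, α = 0.05 this is 37/60 ≈ 61.67%.

## Synthetic cohorts

Each affected channel of a class-c subject is
`x(t) = Σ_b Σ_{f∈b} a_{c,b}·cos(2πft + φ_f) + ε(t)` with
φ_f ~ von Mises(μ_{c,b}, κ_{c,b}) drawn independently per subject,
channel and bin, and ε white Gaussian noise (σ = 1 by default);
unaffected channels are pure noise.  The von Mises family was chosen
because its concentration κ maps directly onto phase consistency,
giving closed-form expectations for recovery tests (circular mean → μ,
spread monotone in κ).  Class-dependent amplitudes create pure power
effects; class-dependent mean directions create pure phase effects.
Per-subject phase draws are the sole source of class overlap besides
noise — real recordings additionally vary in amplitude, background 1/f
spectrum, artifacts and channel covariance, none of which are modelled,
so passing tests demonstrate correctness of the pipeline's recovery and
ranking behaviour, not clinical effect sizes.

Default geometry is desk-scale — 20 channels (9/2/9), 30 s at 250 Hz,
30 subjects per class — chosen as the package's standard simulation size
so that a full nested-CV run completes in seconds; the full 151-channel
study geometry can be requested explicitly.  Four presets define the
study conditions: `null` (identical specs, including a genuine theta
signal with random per-subject phase, so calibration is tested on
correlated features rather than white noise); `phase-only` (equal
amplitudes, theta preferred angle differing by π/2 at κ = 5 on five
channels); `power-only` (uniform phases, alpha amplitude 0.5 vs 0.8,
≈ 4 dB, on five other channels); `both` (the two effects injected
independently on disjoint channels).  These effect sizes are strong by
design — each single-kind model should clearly beat chance so that the
ordering properties (phase effect favours PPA, power effect favours PSD,
fusion not worse than the best single kind, null at chance) are sharply
testable; the examples additionally construct fainter cohorts where the
models err and fusion's subject-rescue behaviour is visible.

## Numerical conventions and edge cases

Phases are mapped to (−π, π] (the −π branch folded to +π).  Empty
feature selections are refused by the trainer with a diagnostic and score
zero validation accuracy during the threshold sweep rather than
aborting the sweep.  Degenerate t-tests on identical class samples give
t = 0, p = 1.  Constant score vectors make a complementarity coefficient
undefined; it is recorded as NaN and excluded from the mean.  All
randomness — cohort generation, fold assignment, weight initialisation —
derives from explicit integer seeds through independent SeedSequence
streams, and a repeated run with the same seed reproduces every report
byte-for-byte.

## Known limitations

Sensor space only; no source model, no cross-channel coupling features.
The linear treatment of circular PPA values in z-scoring and t-tests can
miss wrap-around effects.  The 151-channel montage is positional only
(no geometry).  The synthetic generator omits 1/f background, amplitude
variability and artifacts, so absolute accuracies on it say nothing
about clinical data; only the relative orderings and calibration
behaviour transfer.
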