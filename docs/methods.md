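# Methods

This note documents the models, conventions and numerical choices behind
`emgchart`, in the order the pipeline runs them.

## Synthetic EMG model

Surface EMG during an isometric contraction is, to a first approximation,
band-limited coloured noise whose amplitude scales with muscle activation
and whose marginal amplitude density is closer to Laplacian than Gaussian.
The simulator generates each channel-record as:

1. white Gaussian noise, filtered by a 4th-order Butterworth band-pass at
   the protocol band (clipped below the Nyquist frequency; a pad of up to
   one second of samples is generated and discarded to remove the filter
   start-up transient);
2. a Gaussian spectral bump (centre and width from the motion profile,
   plus a 0.15 floor so the band is never fully suppressed) applied
   multiplicatively in the frequency domain — this is what gives motions
   distinguishable spectral shapes;
3. optionally a monotone marginal map from the Gaussian to a Laplacian
   amplitude density (rank-preserving, so spectral structure survives;
   the default profiles use it);
4. exact RMS normalization followed by multiplication with the channel
   gain, so an RMS doubling is *exactly* a gain doubling, and mean
   removal (DC is outside every protocol band anyway).

Class structure is planted through per-motion profiles: channel gains
spread geometrically across motions (default loudest/quietest ratio 4,
with a mild rotated cross-channel pattern so no channel dominates), and
spectral centres spread over the lower half of the pass-band. Two
variability terms make the data non-trivial: a log-normal per-(subject,
motion, channel) gain perturbation (sd 0.1 by default — between-subject
variability) and a log-normal per-record jitter (sd 0.08 — trial-to-trial
variability). These defaults were chosen once as plausible for forearm
recordings: they keep a single amplitude feature below 10% error when
class gains differ by a factor of two or more, and leave chance-level
error when profiles are identical.

Not modelled (deliberately): rest periods, notch filters, resampling from
hardware rates, electrode shift, force-level variation, and physiological
motor-unit dynamics. Records are born at the protocol's final sampling
rate. Consequently, passing tests show that the *pipeline machinery*
behaves correctly under the statistical structure the features are
designed to detect; they say nothing about error rates on real recordings,
which have richer temporal structure and artefacts.

Three protocol presets mirror the study conditions the package targets
(dataset 1: 20 subjects × 4 channels × 8 motions × 60 trials × 2 s at
1024 Hz, band 20–500 Hz; dataset 2: 30 × 7 × 6 × 24 trials × 4 repetitions
× 3 s at 1000 Hz, band 10–400 Hz; dataset 3: 8 × 2 × 10 × 6 × 5 s at
1000 Hz, band 20–450 Hz).

## Feature battery

58 extraction methods yield 81 named scalars per window. The canonical
EMG-literature definitions are used throughout; because several features
are under-documented in the literature, the exact conventions adopted here
are listed:

- **Amplitude family.** IEMG = Σ|x|; MAV = mean|x|; MAV1/MAV2 =
  centre-weighted MAV (0.5 outside the middle half; linear ramps for
  MAV2); MAVS (2 segments) = MAV of the second half − MAV of the first;
  RMS; VAR = Σx²/(N−1) (zero-mean convention); SSI = Σx²; WL = Σ|Δx|;
  DAMV = Σ|Δx|/(N−1); DASDV = √(ΣΔx²/(N−1)); LD = exp(mean log|x|) with
  zero samples excluded and an all-zero window mapping to 0; TM = |mean
  x³| and V = |mean x³|^(1/3) (order 3; absolute value before the root
  keeps the result real); M2 = Σ(Δx)²; MAX = peak of the rectified signal
  after a 6th-order zero-phase Butterworth low-pass at 5 Hz; AFB = value
  of the 32 ms moving-RMS envelope at its first local maximum (falling
  back to the global maximum when none exists); KURT (Pearson, 3 for a
  Gaussian), SKEW; HIST = counts in 3 equal-width bins spanning
  [min, max].
- **Threshold counts.** ZC counts sign changes whose jump exceeds the
  threshold; SSC counts samples with (x_i−x_{i−1})(x_i−x_{i+1}) ≥
  threshold; WAMP counts |Δx| ≥ threshold; MYOP is the fraction of
  |x| ≥ threshold. Thresholds are in raw signal units and ship as
  per-protocol presets — ZC 10 / 0.01 / 10⁻⁵, SSC 16 / 10⁻⁴ / 10⁻¹⁰,
  WAMP and MYOP 20 / 0.02 / 5×10⁻⁵ for protocols 1/2/3 — plus a "unit"
  profile suited to unit-RMS synthetic data.
- **Spectral family.** One shared convention: the unwindowed one-sided DFT
  periodogram of the window, bin width fs/N, normalized so ΣP =
  mean(x²) (Parseval constant 1/N). MNF, MDF (first bin where cumulative
  power reaches half of TTP), PKF, MNP, TTP, SM (order-2 moment Σ P f²),
  VCF = SM2/SM0 − (SM1/SM0)², OHM = √(SM2/SM0)/(SM1/SM0). The five
  features whose published band conventions vary are isolated in their own
  functions so a different convention is a one-line change: FR = power in
  [20, 45] Hz over power in [95, min(500, Nyquist)] Hz; PSR = power within
  ±20 Hz of the peak over total; DPR = max/min of the 9-bin
  moving-average-smoothed PSD within 20 Hz–0.9 Nyquist; SMR = power above
  20 Hz over power below 20 Hz (motion-artefact band); SNR = signal band
  over power above 500 Hz, or above 0.9 Nyquist when the rate leaves no
  room; PSDFD = Katz fractal dimension of the max-normalized PSD.
- **AR / cepstral.** Order-4 Yule–Walker fit via the biased
  autocorrelation and a Toeplitz solve, coefficients a_k in the
  convention x[n] = Σ a_k x[n−k] + e[n]; cepstral coefficients by the
  recursion c₁ = −a₁, c_p = −a_p − Σ_{l<p} (1 − l/p) a_l c_{p−l}.
- **Complexity.** ApEn and SampEn with m = 2, r = 0.2 × window sd,
  Chebyshev distance; ApEn counts self-matches, SampEn does not and
  restricts templates to the common index range. Both run on pairwise
  distance matrices built incrementally (running max over shifted
  diagonals), which makes them O(N²) memory but fast in practice. DFA
  over dyadic box sizes {4, 8, 16, 32, 64} with quadratic detrending and
  a log2–log2 least-squares slope; Higuchi with kmax = 8 (the common
  default; the choice is config-free but documented); Katz in the
  amplitude-only variant (L = Σ|Δy|, d = max|y_i − y₀|), which makes a
  monotone ramp exactly dimension 1; box counting on the unit-square
  normalized waveform over dyadic grids 2¹..2⁶; VFD via
  variance-of-increments scaling over dyadic lags (D = 2 − slope/2);
  MFL = log₁₀ √(ΣΔx²); CEA as the coarse-grained variance scaling
  exponent of block means — the cited construction is not printed in the
  sources available, so this estimate is isolated in its own function.
- **Spectral-moment descriptors (TDPSD).** m₀ = √Σx², m₂ = √ΣΔx²,
  m₄ = √ΣΔ²x², each power-transformed m ← m^0.1/0.1; descriptors
  f₁ = log m₀, f₂ = log(m₀−m₂), f₃ = log(m₀−m₄), f₄ = log of the
  sparseness ratio m₀/√((m₀−m₂)(m₀−m₄)), f₅ = log of the irregularity
  factor m₂/√(m₀m₄), f₆ = log(Σ|Δx|/Σ|Δ²x|). Logs are taken of absolute
  values clipped at 10⁻³⁰⁰ so the descriptors are total functions of
  non-zero windows; the cosine-similarity fusion step some
  implementations add across a log-scaled signal copy is not applied —
  the six descriptors are emitted directly.
- **Multi-window energies.** The window is split into 3 equal consecutive
  sub-segments (remainder samples dropped); each is tapered by a Hamming
  window or a symmetric trapezoid with 25% ramps and its energy Σ(w·x)²
  reported.
- **Differenced variants.** DAR, DCC, DAMV, DASDV, DLD, DTM, DVARV and DV
  apply the base extractor to the first difference of the window; WL and
  M2 are difference-based by definition.

The battery is a pure function of (window, sampling rate, parameter
profile); repeated calls are bitwise identical, and direct-sum oracle
implementations in the test suite agree with the optimized paths to 1e-9.

## Windowing, standardization, point cloud, PCA

Windows are 0-based and half-open; length and stride are round(ms·fs/1000)
samples (250 ms at 1024 Hz is exactly 256), windows never span records,
and the last window ends within one stride of the record end. Features are
standardized to zero mean and unit sample variance within each (subject,
channel) group; zero-variance groups map to zeros with a warning, and the
operation is idempotent. The point cloud transposes the standardized
whole-record table: rows are features, columns are observations sorted by
(subject, channel, trial, motion, repetition) so runs are reproducible.
PCA treats features as the observations: a full SVD of the column-centred
matrix, retaining the smallest number of components whose cumulative
explained variance reaches the target (default 0.95), never more than the
matrix rank.

Windowed feature tables used for classification are standardized with the
same per-(subject, channel) transform fitted on themselves; for the
held-out comparisons this means scaling statistics see the test windows.
This mirrors the per-subject standardization practice of the field and is
uniform across all compared feature sets, so it does not bias the
comparisons among them.

## Mapper

Filter: Euclidean distance to the k-th nearest neighbour with k = 2, i.e.
the distance to the nearest *other* point (k = 1 is the point itself).
Cover: MI uniform intervals over [min, max] of the filter, length
L = R/(1 + (MI−1)(1 − MO/100)), stride L(1 − MO/100), closed endpoints
(a boundary point belongs to both intervals); the last interval's upper
edge is clamped to the exact maximum because the floating-point sum can
undershoot it by one ulp and silently drop the extremal point. Local
clustering: Ward agglomeration of each preimage. Edges connect nodes in
adjacent intervals sharing members, weighted by the shared count; no
intra-interval edges; identical-member nodes in adjacent intervals are
both kept; nearest-neighbour and clustering ties resolve by point index.

**Dendrogram cut rule.** The number of clusters per preimage is decided by
a gap rule on the Ward merge heights: a merge qualifies as a gap when it
exceeds mean + 2·sd of all previous merge heights *and* exceeds 3.0× the
largest previous height; the cut is at the largest qualifying relative
jump, and a preimage with no qualifying gap stays one cluster. The naive
"first statistical outlier" rule was tried first and systematically
shatters elongated preimages: on an evenly spaced chain, Ward heights grow
geometrically on their own (merging two equal segments scales the height
by ~√2, and four collinear equally spaced points produce a 2√2 ≈ 2.83
jump), so early near-equal heights (sd ≈ 0) plus the intrinsic growth
trigger spurious cuts that disconnect the chart. The 3.0 ratio sits just
above the 2√2 chain bound while genuine cluster separations in practice
exceed it severalfold. Both knobs (`gap_sd`, `gap_ratio`) and the
treatment of singleton clusters are exposed as estimator parameters.

**Decomposition.** Connected components are listed largest first. Within a
component the core is the set of nodes of degree ≥ 3; removing it leaves
chains, each an arm (a core-less component that is itself a path of ≥ 2
nodes counts as one arm; an isolated node has none). Auto-annotation
labels each arm, core and leftover node per component; explicit label maps
are also accepted.

A planted Y-shaped validation cloud (`planted_three_arm_cloud`) encodes
the intended geometry — one dense chain running into a junction from which
two progressively sparser chains radiate at 120° — and charts as exactly
one core plus three arms at MI = 3, with arm membership preserved when the
cover refines to MI = 8.

## Evaluation

Per feature (or feature set) and subject, the window-level matrix has one
column per channel and one row per analysis segment. Davies–Bouldin uses
the mean Euclidean distance to the class centroid as scatter and averages
each class's worst (S_c + S_d)/‖μ_c − μ_d‖ ratio; coincident centroids
give +inf with a warning. The Fisher index scalarizes the scatter-matrix
"ratio" as trace(S_w)/trace(S_b) (the determinant ratio is a noted
alternative, not implemented). Classification error is the percentage of
incorrect predictions pooled over stratified 10-fold cross-validation
(shuffled with a fixed, configurable seed); LDA and a linear SVC (C = 1,
one-vs-one by construction) are the classifiers. A "by-trial" fold mode
assigns whole trials to folds to avoid temporal leakage between
overlapping windows; the default "by-window" mode matches common practice.
Cohen's d uses the pooled standard deviation, with bands 0.2/0.5/0.8 for
small/medium/large.

## Selection and comparison

Chart-guided selection needs an annotated chart and a per-feature report.
Node groups whose mean filter value is at or below the configured quantile
(default median) of node filter values are "tight" and contribute one
unit; looser groups contribute `quota_high` units (default 2). A unit is a
single feature or a whole multi-component family (AR, DAR, CC, DCC, HIST,
MHW, MTW, TDPSD), ranked by its best member under the chosen criterion
(default SVM error, lower is better) and expanded atomically. SFS is the
classical greedy wrapper on mean within-subject 10-fold CV error and is
constrained to the chart-guided set's size by default. The comparison
protocol holds out 30% of each subject's windows (stratified by motion)
for testing, evaluates transfer as the mean within-subject CV error on the
*other* dataset(s), and reports Cohen's d against the all-features
baseline (where "all features" means all columns of the given table).

## Pipeline and problem sizes

The CLI chains simulate → extract → chart → evaluate → select → compare
from one JSON/YAML config; every artifact records a hash of the config
(minus the output directory), later stages refuse mismatched hand-offs
unless forced, and all randomness flows from the config seed, so repeated
runs are byte-identical. The bundled test and acceptance configurations
run scaled-down protocols (2–3 subjects, 2–4 trials, 3–5 motions, 0.5–1 s
records) — sizes chosen so the entire pipeline, including the O(N²)
entropies and the SFS wrapper, completes in minutes on one CPU while
every structural property (record counts, window arithmetic, chart
topology, selection behaviour) is still exercised at full fidelity. On
such miniature clouds the Mapper chart of the 81 features is more
fragmented than on full-size runs, because few observations leave most
feature-points mutually distant; the planted-cloud checks cover the
connected-topology regime explicitly.

## Known limitations

- The synthetic generator encodes class information only through
  stationary amplitude and spectral-shape differences; features sensitive
  to non-stationarity or higher-order temporal structure (DFA, CEA,
  entropies) carry less class signal here than on real EMG.
- CEA, DPR, SMR, SNR, FR and the Higuchi kmax follow documented but
  non-authoritative conventions (each isolated behind its own function).
- EDF input/output is not provided; recordings move as long-format
  delimited text.
- Error rates on the bundled synthetic conditions are near zero for most
  multi-channel feature sets; the comparison machinery is therefore
  validated structurally (effect sizes, transfer gaps, determinism)
  rather than against empirical error levels of real recordings.
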