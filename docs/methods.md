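# Methods

This note documents the models, conventions and numerical choices behind
`ladcycle`, and what its synthetic benchmarks do and do not demonstrate.

## Interval model

Coordinates are 0-based half-open (BED convention). Normalization sorts by
(chromosome, start) and merges overlapping **and book-ended** intervals:
domain callers emit contiguous domains, and two abutting intervals are
indistinguishable in coverage terms. All set operations (intersection,
subtraction, union, Jaccard) are exact in base pairs and are verified in
the test suite against a brute-force per-bp membership oracle. The Jaccard
index of two empty sets is reported as missing (NaN), not 0, to avoid a
spurious "no overlap" signal.

## cov_max and border standardization

For each LAD, the maximal footprint (cov_max) is the merged union of its
coverage over all CTs and replicates; merged regions receive stable
identifiers in (chromosome, start) order. For a cov_max region [S, E) of
length L and a sample whose fragments inside it span [a, b):

    rel5 = 1 − (a − S)/L        rel3 = 1 − (E − b)/L

so 1 means the border reaches the cov_max limit and 0 means the LAD is
absent from that sample. Internal configuration between a and b (splits,
fusions) is deliberately ignored; only the outermost extremities count.
Both border values are normalized by the full length L — linear in bp and
consistent with both endpoints of the 0–1 scale. 5′ is the lower genomic
coordinate (LADs are unstranded; reference-strand convention).

Gain/loss decomposition between two samples classifies each differential
region by its containing LAD: a gained region whose containing LAD has no
overlap with the reference is a stand-alone gain, otherwise an extension
(book-ended regions count as extensions); mirrored for losses. The bp
identity coverage(comparison) − coverage(reference) = gained − lost is a
tested invariant.

Descriptive statistics and gene-distance calculations use replicate
*intersects* per CT; rhythm fitting always consumes per-replicate series.
Borders with zero variance across all samples are excluded from rhythm
fitting (`min_border_sd`, default 0: drop exactly-constant borders only).
The variability criterion is exposed as a parameter because the selection
rule for "variable" borders is a free choice of the analyst.

## Rhythm engine

The engine assumes an even grid (default CT0…CT30, Δ = 6 h, so n = 6
points) and combines two detectors per replicate series.

**JTK_CYCLE.** For each candidate period T (default 2Δ…nΔ = {12, 18, 24,
30, 36} h; a 6 h candidate would equal the Nyquist limit and is excluded)
and each lag φ ∈ {0, Δ, …}, the reference cos(2π(t−φ)/T) is reduced to its
tie-group pattern and Kendall's S between data and reference is computed.
With distinct data values the null of S is exact: the Jonckheere–Terpstra
statistic's distribution is built by convolving Mann–Whitney count
distributions (Gaussian-binomial coefficients, integer arithmetic), which
for n = 6 agrees with full 720-permutation enumeration to machine
precision. Tied data fall back to the normal approximation with the
tie-corrected Kendall variance and a continuity correction. The reported p
is the **minimum two-sided p over all (T, φ) patterns, uncorrected** — the
published JTK_CYCLE convention. This convention is intrinsically
anticonservative: at n = 6 the marginal null rate P(p_JTK < 0.05) is ≈ 0.20
(measured over 2,000 simulations), because ~20 discrete patterns each
attain minimum p-values of 1/90–1/30. A within-scan Bonferroni correction
would restore validity but drives the power on 6-point series to ~0, so the
min-p convention is kept and the stringent 0.005 threshold downstream must
be read against it.

**Lomb–Scargle.** The classical periodogram (via `scipy.signal.lombscargle`
on mean-subtracted data) is normalized by the sample variance (ddof 1) and
scanned over periods 12–48 h on a frequency grid oversampled 10× relative
to 1/span. The peak z has ceiling (n−1)/2. Significance uses the
finite-sample single-frequency tail p₁ = (1 − 2z/(n−1))^((n−3)/2) — exact
for Gaussian noise under this normalization — rather than the large-n limit
e^(−z), which at n = 6 assigns p₁ ≈ 0.08 even to a noiseless cosine and
would make clean signals undetectable. The Horne–Baliunas-style correction
p = 1 − (1 − p₁)^M uses M = number of scanned frequencies by default. This
deliberately over-counts (the band holds only ~2 independent Fourier
frequencies) and yields a conservative LS: measured null P(p_LS < 0.05) =
0.013. The alternative `n_effective="independent"` (M = span·(f_max −
f_min) + 1) is provided but not default: near the power ceiling the beta
tail is so steep that the smaller M becomes strongly anticonservative
(measured combined null rate 0.44 at the 0.05 level).

**Combination.** Fisher's method, X = −2 Σ ln p ~ χ²(2k). Default strategy
(`"replicates"`): per replicate Fisher({p_JTK, p_LS}) with df 4, then
Fisher across the k replicate meta p-values with df 2k — k therefore equals
the replicate count (2 for LAD data, 3 for expression data). The `"flat"`
strategy (all 2k p-values in one test, df 4k) is implemented and behaves
near-identically in calibration and power. Zero p-values are clamped to the
smallest positive value with a warning. JTK and LS are computed on the same
data, so the independence assumption of Fisher's method is violated;
combined-null calibration measured on pure-noise 2-replicate series:
P(p_combined < 0.05) ≈ 0.096, P(p_combined < 0.005) ≈ 0.008. The stringent
0.005 threshold for "periodic" calls keeps the realized false-positive rate
below 1%; the relaxed 0.05 tier is a candidate screen, not a calibrated
test.

**Periods, phase, groups.** The reported period is the mean of the JTK and
LS periods (each first averaged across replicates). Amplitude, baseline and
phase come from a post-hoc least-squares cosine fit at the mean period on
the replicate-averaged series; the phase is the time of the first maximum
in [0, period). Periods are snapped to groups 12/18/24/30 h when within
± 3 h (half the sampling resolution); a value inside two windows goes to
the nearer center, exact midpoints to the lower one; outside all windows
the group is "none". Phases snap to the nearest quadrant {0, π/2, π,
−π/2}; for the 12 h group only {0, π} are reported because a 12 h cosine in
quadrature sampled every 6 h is exactly constant (the engine returns p = 1
for it, a tested property). Expression series are z-scored per gene and
replicate (sample sd; constant series map to zeros) before fitting.

## Randomization validation

Three distinct non-identity permutations of the CT order are drawn once per
run (seeded) and applied globally to every border series; replicate pairing
within a CT is kept fixed, since only the time order is under test. Each
permuted series is re-fitted; its period group is recorded only when
significant at the verdict threshold, else "none". A border passes when its
experimental group differs from the shuffled group in ≥ 2 of 3 rounds
("different" = different period group, including significant→none; an
exact-hour comparison would be noise-dominated). A series with no
significant experimental rhythm cannot pass — there is nothing to validate.
The verdict threshold defaults to the relaxed 0.05 tier: at n = 6 the JTK
null is so coarse that even clean 24 h borders land near p ≈ 0.01, and a
0.005 verdict threshold would make the test vacuous for most true rhythms.

## Gene–LAD geometry

A gene belongs to a LAD iff its single-bp TSS (start for +, end−1 for −
genes) lies inside the LAD. Distances run from the gene's 5′ and 3′ ends to
the nearest 3′ and 5′ LAD borders respectively, strand-respecting; a gene
entirely inside a LAD is measured to its first neighbors (the containing
LAD is excluded); a LAD overlapping but not containing the gene gives
distance 0 on that side; a side with no LAD on the chromosome is missing
(NaN), never 0. The headline "nearest" distance is min(d5, d3) over present
sides — the only reduction consistent with "nearest". Distance variation
between three CTs spaced 12 h apart is reported as signed deltas (negative
= the gene moved closer) with descriptive quadrant labels; genes missing a
distance at any of the three CTs are excluded with a logged reason. Gene
capture near LADs uses body overlap with the region widened by 2.5 Mb on
each side; genes overlapping the region itself are reported separately.

## Synthetic data

The generator emulates the measured quantities, not the assay: LAD borders
move as rel(t) = clamp(baseline + A·cos(2π(t−φ)/T) + ε, 0, 1) with
independent Gaussian replicate noise per side and sample; whole-LAD
appearance/disappearance is a cosine gate; borders are converted to
integer bp by rounding half-up (platform-stable), so recovered border
values match injected ones to within 1 bp/L (a tested inverse-consistency
property, measured max error 0.4 bp). Expression is FPKM(t) = max(0, base +
A·cos + ε) with truncations counted. Clamping events are counted and
reported in the stage manifest. Default study-like conditions: 40 LADs
(half with one cosine border, A = 0.4 of cov_max, baseline 0.6, noise sd
0.05, periods cycling 12/18/24/30 h; a quarter noise-only; a tenth gated;
the rest constant), 2 LAD replicates; 120 genes (40% periodic with
amplitude:noise 4:1, 30% noisy aperiodic, 30% constant), 3 expression
replicates. An NS (non-synchronized) sample outside the grid is emitted for
gain/loss analysis as a noise-only realization.

What passing synthetic benchmarks shows: the pipeline inverts its own
generative model and controls its stated error rates under cosine dynamics
with Gaussian replicate noise. What it does not show: robustness to
domain-caller artifacts (fragmented calls, coverage-dependent border
uncertainty), non-sinusoidal waveforms, autocorrelated noise between
neighboring time points, or replicate-correlated noise — real data have all
of these.

## Problem sizes and determinism

The test suite and the reproduction script use 200 borders for recovery
and noise calibration, 100 LADs for inverse consistency, 100 simulations
for the randomization pass rate, 40 genes for expression classification,
and 1,000 random instances for the interval-algebra oracle; these sizes
give binomial-99% resolution on every asserted rate while keeping the whole
suite in the low minutes on one CPU. Every stochastic routine takes an
explicit seed; identical config and seeds produce byte-identical outputs
(a tested end-to-end property), pipeline stages never mutate their inputs,
and each stage directory carries a manifest with the config hash and seed.

## Known limitations

- n = 6 time points is at the edge of what rhythm detection supports: JTK's
  exact null is coarse (smallest attainable two-sided p per pattern
  1/90–1/30), LS power peaks at z = (n−1)/2, and 30 h signals are sometimes
  captured by the 36 h JTK pattern, pushing the mean period outside the
  30 ± 3 h group (~5% of clean 30 h borders at default conditions).
- The relaxed 0.05 tier is anticonservative (~10% realized on noise); use
  the stringent tier for calls and the relaxed tier only as a screen.
- Period estimates are bounded by the candidate grid (JTK) and the scan
  range (LS); rhythms outside 12–48 h are not detectable by design.
- The randomization check with 3 shuffles is a qualitative guard, not a
  permutation p-value.
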