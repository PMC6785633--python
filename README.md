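# ladcycle

Periodicity analysis of lamina-associated domain (LAD) dynamics across the
circadian cycle.

## The problem

Lamina-associated domains are broad, heterochromatic genomic regions that
contact the nuclear lamina; they are called from lamin B1 ChIP-seq as BED
intervals, one set per circadian time point (CT) and biological replicate.
Two questions drive this package:

1. **Do LAD borders oscillate with circadian time?** Each LAD's maximal
   footprint over the whole time course (*cov_max*) is given the reference
   value 1, and for every sample the 5′ and 3′ extremities are standardized
   to a relative length in [0, 1] (1 = border reaches the cov_max limit,
   0 = the LAD is absent). The resulting border time series are fitted with
   a two-method rhythm engine and validated by randomizing the CT order.
2. **Is periodic gene expression coupled to LAD dynamics?** Genes are
   classified as periodic / non-periodic from FPKM time courses with the
   same engine, assigned to LADs by transcription-start-site overlap, and
   related to LAD geometry through strand-aware gene-to-nearest-LAD
   distances per CT.

A first-class synthetic-data generator emulates all inputs (LAD BEDs per
CT × replicate, gene BED6, FPKM TSV) with injected ground-truth rhythms, so
every stage is testable without external data.

## The statistics

For a series *y(t)* sampled at CT0, CT6, …, CT30 (Δ = 6 h):

- **JTK_CYCLE rank test.** For each candidate period *T* ∈ {12, 18, 24, 30,
  36} h and lag φ ∈ {0, Δ, …, T−Δ}, Kendall's S is computed between *y* and
  the reference cos(2π(t−φ)/T). The null distribution of S given the
  reference's tie groups is **exact** (Harding convolution of Mann–Whitney
  count distributions; for n = 6 it reproduces full 720-permutation
  enumeration to machine precision). The minimum two-sided p over all
  (T, φ) is reported, the JTK_CYCLE convention.
- **Lomb–Scargle periodogram** over periods 12–48 h, normalized by the
  sample variance; peak significance uses the finite-sample single-frequency
  tail p₁ = (1 − 2z/(n−1))^((n−3)/2) with a Horne–Baliunas-style correction
  p = 1 − (1 − p₁)^M over the scanned frequencies.
- **Fisher combination.** X = −2 Σ ln pᵢ ~ χ²(2k). Per replicate the
  {p_JTK, p_LS} pair is combined (df 4), then the replicate meta p-values
  are combined across k replicates (df 2k). Periods are the mean of the JTK
  and LS estimates; amplitude and phase come from a least-squares cosine fit
  at that mean period. Periods snap to groups 12/18/24/30 h (± 3 h, half the
  sampling resolution) and phases to quadrants Φ ∈ {0, ±π/2, π} — for the
  12 h group only {0, π}, since quadrature phases are invisible at 6 h
  sampling.
- **CT-order randomization.** Border series are re-fitted under 3 global
  random permutations of the CT order; a detected periodicity is accepted
  only if it differs from the shuffled result in at least two of the three
  rounds.

Significance thresholds follow the two-tier convention: stringent
p < 0.005 for "periodic" calls, relaxed p < 0.05 for the wider candidate
set. See `docs/methods.md` for assumptions, calibration measurements and
known limitations (notably: the min-p JTK convention is anticonservative at
n = 6, which the thresholds must be read against).

## Worked example

`examples/02_border_rhythm.py` injects a 24 h cosine into one LAD's 5′
border (relative length 0.6 ± 0.4, replicate noise sd 0.03, first maximum
at CT6), writes BED-level interval sets, recomputes cov_max and the border
series from the intervals, and fits the rhythm engine:

```
recovered 5' border series (rows = replicates, cols = CT0..CT30):
[[0.6   0.992 0.586 0.202 0.585 1.   ]
 [0.609 0.973 0.57  0.24  0.581 1.   ]]

p_jtk      = 0.0087
p_ls       = 0.2158
p_combined = 0.0151   (Fisher chi-square, 2k df)
period     = 24.2 h -> period group 24
phase      = 5.9 h -> phase group pi/2
```

The injected rhythm is recovered: period group 24, first maximum near CT6
(phase quadrant π/2), combined p below the relaxed threshold. The other
scripts in `examples/` cover interval algebra and gain/loss decomposition,
the randomization verdict, gene-to-LAD distances, and the full pipeline
(`ladcycle all --outdir ladcycle_out` from a shell does the same as
`examples/05_full_pipeline.py`), whose summary on the default synthetic
study (seed 0) prints:

```json
{
  "border_period_recovery_rate": 0.95,
  "gene_period_recovery_rate_relaxed": 1.0,
  "gene_period_recovery_rate_strong": 0.4791666666666667,
  "n_borders_fitted": 68,
  "n_borders_periodic_relaxed": 25,
  "n_borders_periodic_strong": 13,
  "n_genes_classified": 120,
  "n_genes_nonperiodic_reference": 0,
  "n_genes_periodic_strong": 23,
  "n_lads_periodic_relaxed": 24,
  "n_lads_periodic_strong": 13,
  "n_verdict_passes": 24
}
```

Here 95% of the variable borders with injected cosines recover their true
period group at p < 0.05, and 13 borders pass the stringent p < 0.005 call.

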