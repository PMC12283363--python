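# Methods

This note documents the models, algorithms and numerical choices behind
`xomap`, in the order data flows through the package.

## Simulator

### Crossover placement

Bivalent CO positions on a chromosome are drawn from a stationary
gamma-renewal process on the genetic map: a Poisson(ν·λ) number of points
uniform on `[0, G]` (G = genetic length in cM) is sorted and every ν-th
point is kept, starting from a uniformly random phase offset in
`{0, …, ν−1}`. Inter-event distances are then gamma-distributed with
integer shape ν, the expected event count is λ, and ν = 1 reduces exactly
to a homogeneous Poisson process (no interference). Larger ν yields
sub-Poisson count dispersion and repelled events — the phenomenology of CO
interference. Non-integer shapes are deliberately out of scope; the integer
construction is simple, exact and stationary (no edge bias from the
renewal start).

`obligate_co` implements CO assurance by rejection: chromosomes drawing
zero events are redrawn until at least one occurs. This conditions the
count on being positive and therefore inflates the realized mean above λ;
it is off by default and intended for wild-type-like simulations only.

### Transmission and genotypes

Each bivalent CO is transmitted to the sampled chromatid independently with
probability 1/2 (no chromatid interference). This halves the mean count
(meiocyte:gamete ratio 2:1) and preserves the sign of count dispersion, so
interference remains detectable in gametes. The gamete's starting parent is
uniform per chromosome; haplotype blocks alternate at each breakpoint. At a
BC1 marker the recurrent Col parent always contributes a Col allele, so the
offspring is HET exactly where the gamete segment is Ler and HOM_COL
elsewhere — the expected per-marker Ler allele frequency is 0.25, which is
why the QC minor-allele-frequency window (0.2, 0.3) retains well-behaved
markers.

### Physical–genetic map

Maps are piecewise linear between user anchors, strictly increasing in both
coordinates, anchored at (1 bp, 0 cM) and (chromosome length, G). The
default five-chromosome panel uses TAIR10 assembly lengths and centromere
midpoints, a uniform 4 cM/Mb arm rate and a ten-fold suppressed rate within
centromere ± 2 Mb — a deliberately stylized U-shaped landscape. Conversion
rounds to integer bp; round trips are exact to ±1 bp.

### Observation model

Read depth per call is Poisson(`depth_mean`, default 1.2). A call is
MISSING when its depth is zero (P ≈ 0.30 at 1.2×) or, independently, with
probability `p_missing`. Genotyping errors are independent substitutions:
HET→HOM_COL (`e_het_to_hom`), HOM_COL→HET (`e_hom_to_het`), and any call →
HOM_LER (`e_hom_ler`), the artifact class that a Col backcross cannot
produce. With `read_based_het_calls` the HET genotype is instead derived
from simulated reads (Binomial(depth, ½) Ler reads; all-Col → HOM_COL,
all-Ler → HOM_LER), so a HET covered by a single read is miscalled
HOM_COL or HOM_LER with equal probability — the allele-dropout mechanism
that makes the HOM_LER class common in real shallow data. The flag is off
by default because the explicit error rates are easier to reason about in
tests; the `simulate` defaults (`e_het_to_hom = e_hom_to_het = 0.01`,
`e_hom_ler = 0.02`) are artifact choices stated in the config echo, not
estimates from any dataset.

What the simulator does *not* emulate: gene conversion, aneuploidy,
viability selection on gametes, segmental duplications or mapping bias
producing locally clustered genotyping errors, and non-uniform marker
ascertainment. Passing recovery tests therefore demonstrate correctness of
the pipeline's logic under the stated noise model, not robustness to every
real-data pathology.

## QC filter chain

Order: per-genotype depth mask → site mean depth → site MAF → high-missing
samples → impossible homozygotes → SNV-count percentile. Interpretation
choices where the conventional wording is ambiguous:

* Depth bounds [4, 100] apply per genotype call (call set MISSING), the
  common VCF filtering semantics; a per-site total-depth variant is
  available via `dp_scope="site"`. Note that per-genotype `min_dp=4`
  combined with ~1.2× data masks ~94% of calls; when simulating
  shallow-depth scenarios the bound is set to 0 and missingness arises from
  zero-depth calls instead.
* Mean depth bounds [1, 1.5] apply to the per-site mean of raw depths
  across all samples.
* MAF is the minor-allele frequency from calls that are non-missing after
  depth masking, counting Ler alleles as 2·#HOM_LER + #HET over 2·#calls.
* "More than 75% missing" and the 5%/95% percentile rule use strict
  inequalities; quantiles interpolate linearly between order statistics, so
  samples exactly at a quantile are kept and the filter can never empty the
  population.

The percentile step is not idempotent: re-running it recomputes quantiles
on the already-trimmed distribution and trims again (counts 1..100 lose the
5+5 tails, then 5+5 more). The depth, mean-depth, missing-sample and
HOM_LER stages are idempotent, and the MAF step is stable except where
HOM_LER removal changes allele counts; the QC report records every step so
reruns are auditable.

## Crossover calling

Within each sample–chromosome, missing calls are removed and the remaining
sequence smoothed by sliding windows of w = 20 consecutive SNVs (step 1):
each window takes its modal genotype; ties (possible for even w) inherit
the previous window's value, a leading tie takes the first untied window's
value, and an all-tied sequence collapses to its first observed genotype.
Each marker then takes the value of the window in which it is the
⌈w/2⌉-th element, clipped at chromosome ends; sequences shorter than w use
a single window.

The centred window→marker assignment is the one genuinely open design
choice here. A "window starting at the marker" assignment looks natural but
systematically shifts every inferred transition about w/2 markers toward
the chromosome start, because the first window whose majority flips begins
half a window before the true breakpoint; centring the assignment aligns
the smoothed transition with the haplotype switch, so the reported
breakpoint interval (last marker of the left run, first marker of the
right run) brackets the true CO. The midpoint estimator is the floor of
the interval midpoint; the interval itself is always reported so users can
substitute other estimators.

Accuracy: with error-free genotypes, every called event's interval contains
the true CO whenever true COs are separated by more than w markers and sit
clear of the terminal half-window (verified exhaustively in tests). At a 1%
per-call error rate, a miscall adjacent to a breakpoint can shift the modal
boundary by one marker: measured on the default recovery scenario, ~80% of
intervals contain the true CO strictly and ~99% do within one non-missing
flanking marker. Double COs closer than ~w markers are merged by
construction; `min_run_markers` (default 1 — the modal window is the
denoiser) can additionally absorb short runs into the larger flanking run.
Events are binned into non-overlapping 1-Mb windows (bin b covers
(b−1)·10⁶ < mid ≤ b·10⁶; the final partial bin is kept and flagged).

## Interference statistics

Only chromosomes with exactly two called COs contribute inter-CO distances.
The permutation null redraws, for each qualifying instance, two positions
with replacement from the empirical pool of all CO midpoints on that
chromosome in the same dataset — preserving the chromosome's CO landscape
while destroying within-gamete pairing. The compared statistic is the mean
distance; the test is one-sided in the "interference increases distances"
direction with p = (1 + #{null mean ≥ observed}) / (n_perm + 1), n_perm =
500 by default. An alternative scheme (`shuffle`) permutes the observed
midpoints themselves across instances. Simulation shows the test is
calibrated at ν = 1 (type-I ≈ 0.05) with power ≥ 90% at ν = 5 and 200
gametes.

CoC uses the indicator convention (a window is "hit" by ≥1 CO midpoint)
and the pooled-ratio estimator Σf_ij / Σf_i f_j over all window pairs at
each distance d ∈ 1..15 Mb, per chromosome and pooled; pairs with
f_i·f_j = 0 contribute to neither sum, and a zero denominator omits the
point. Pooling is robust to empty bins, unlike a mean of per-pair ratios.
The LOESS summary is a classic tricube-weighted local polynomial
(span 0.75, degree 2 — the conventional defaults), fitted by weighted
least squares at each grid point on the ⌈span·n⌉ nearest observations;
duplicate-x degeneracies fall back to the weighted mean.

## Group comparisons

The nested ANOVA fits y ~ sex + sex:genotype with sequential (type I) sums
of squares and F-tests against the residual mean square. The follow-up is
Tukey–Kramer over sex×genotype cell means: q = |m_i − m_j| /
√(MSE/2·(1/n_i + 1/n_j)) referred to the Studentized range with k = number
of cells — the Kramer form because realistic group sizes are unbalanced.
Landscape comparisons test each 1-Mb window on the 2×2 table (COs in
window vs elsewhere) × (group A vs B) with Pearson χ², df = 1, no
continuity correction; windows with an empty in-window margin are skipped,
and Benjamini–Hochberg adjusted p-values are reported alongside raw ones
because no single multiplicity convention dominates for landscape scans.

The focus/CO ratio 100·foci·t/co uses t = ½ for the gamete-transmission
argument (a gamete carries on average half the meiocyte's COs under no
chromatid interference); t is an explicit parameter. Minimum chiasma
scores count rod bivalents as one and ring bivalents as two.

## Focus colocalization

Spot detection is out of scope; the module starts from channel-labelled
point sets (µm) in a bounded field. A point "overlaps" when any point of
the other channel lies within 0.33 µm (Euclidean), matching the percentage
definitions (overlapping × 100 / channel total); one-to-one pairs are
additionally reported via greedy nearest-first matching. The randomness
control rotates the green set 90° about the field centre in bounds-
normalized coordinates, so non-square fields remap within bounds and four
rotations restore the input exactly. Empty channels yield undefined (None)
percentages rather than zero.

## Problem sizes and seeds

Validation scenarios use: 200 offspring × ~11,000 markers (≈10,300 after
QC) for parameter recovery; 2,000 gametes per population for CoC bands;
200 replicates × 500 permutations for type-I calibration and 20 replicates
for power. These sizes give Monte-Carlo error comfortably inside the
asserted bands while keeping the full suite fast. All randomness flows
from a single top-level seed through `numpy.random.default_rng`; derived
substream seeds are drawn below 2³¹.

## Known limitations

* Breakpoint resolution is one inter-marker interval at best and degrades
  by ±1 marker per adjacent miscall; no HMM segmentation is attempted (the
  modal-window procedure is the method being modelled, and an HMM would be
  a different estimator).
* CoC is computed on physical distance only (Mb), not genetic distance.
* The permutation and CoC machinery assumes called events; systematic
  caller biases (merged close double COs) propagate into interference
  estimates, visible as CoC ≈ 0 at d ≤ 1 Mb even for ν = 1 called data.
* No gamma-shape maximum-likelihood estimation of interference strength is
  provided; ν is a simulation input, not a fitted parameter.
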