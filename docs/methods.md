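# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `meioscope`. Empirical figures quoted here are the ones
the test suite and `scripts/acceptance.py` themselves compute.

## The meiosis simulator

The simulator generates F2 populations with the statistical structure that
the downstream analyses assume, so every stage can be checked against known
truth without any external data.

**Crossover placement.** Crossovers are placed per bivalent in physical
coordinates (bp). Interfering class I events follow a *stationary gamma
renewal process*: inter-event distances are gamma with shape ν and scale
chosen so the expected count over `[0, L]` equals `class1_mean`. The first
event is drawn from the equilibrium delay distribution (the interval
covering the origin is length-biased, gamma with shape ν + 1, and the
origin sits uniformly inside it); without this, the process start would
fake extra interference near position 0. At ν = 1 the process reduces
exactly to homogeneous Poisson (tested by count dispersion and position
uniformity). Non-interfering class II events are Poisson with uniform
positions, optionally confined to the two chromosome ends
(`terminal_fraction`) to emulate mutants whose crossovers concentrate
sub-telomerically. The gamma renewal model is a generative stand-in: it is
the standard phenomenological model for interference strength ν, not a
mechanistic claim (e.g. about coarsening dynamics, which are out of scope).

**Transmission.** Each crossover joins one chromatid of each homolog,
chosen uniformly and independently (no chromatid interference — the
standard assumption). A gamete transmits one of the four chromatids; an F2
individual is the union of two gametes from independent meioses, and its
genotype at a marker is the allele sum (P1/H/P2). The obligate crossover is
deliberately *not* enforced: a zero-crossover bivalent missegregates with
probability `obligate_escape_p`, and the individual then carries 1 or 3
copies with equal odds. Trisomic chromosomes carry both parental homologs
(nondisjunction sends both to one pole), so their genotype reads
heterozygous throughout; monosomics read as the single parental haplotype.

**Defaults as study conditions.** The wild-type-like defaults are
`class1_mean = 1.8`, `class2_mean = 0.2` (class II ≈ 10% of events, the
interference-insensitive minority pathway), ν = 5 (within the range
reported for *Arabidopsis* class I interference), 2% genotype error, and a
50 kb mean marker spacing. This yields ≈ 9.5 detected crossovers per F2
individual over the five chromosomes, in the range seen in real Col × L*er*
F2 sequencing. Marker positions are jittered-regular
(`pos_i = (i + U) · spacing`): dense parental SNP lists cover the genome
fairly evenly, so a map whose gaps have exponential tails (hundreds of kb
of marker desert) would misrepresent the data; the jittered grid keeps the
requested mean density with a maximum gap below twice the spacing.

**What the simulator does not model.** Read-level artifacts, structural
variants (notably large inversions), recombination hotspots/landscapes
beyond terminal confinement, correlated genotype-error tracts, GC or
mappability bias in coverage, and mosaicism. Tests passing on simulated
data therefore validate the *estimators and pipeline logic*, not robustness
to these real-data complications.

## Crossover calling

A deterministic three-step segmentation replaces HMM-based callers:

1. **Vote.** A centered window of 15 informative (non-missing) markers
   votes on each marker's state; the provisional state is the majority.
   Markers whose majority fraction is below the 0.8 purity threshold take
   the state of the nearest confident marker (ties toward the left) — a
   symmetric fill, so transition boundaries are not biased in either
   direction.
2. **Raw-run rescue.** A run of at least `min_segment_markers` (default 5)
   *identical raw* calls overrides the smoothed states. The vote window
   cannot represent genuine segments shorter than about half its width, yet
   five consecutive identical mis-calls at a few percent error rate have
   probability ~10⁻¹⁰ per site, so such runs are effectively certain to be
   real. This makes `min_segment_markers` the caller's true resolution
   limit (≈ 5 × marker spacing).
3. **Absorption.** Runs shorter than `min_segment_markers` are absorbed
   into the flanking state with more supporting markers (ties left),
   shortest run first, until the segmentation is stable and alternating.

One crossover event is emitted per adjacent segment pair, positioned at the
midpoint between the last marker of the left segment and the first marker
of the right segment. Direct P1↔P2 transitions — two crossovers inside one
marker gap — are flagged (`double-in-gap`) rather than resolved; they are
excluded from cis-DCO analyses, and in truth-evaluation a flagged event may
account for two true crossovers.

Measured fidelity under the default conditions (1000 individuals, ν = 5,
2% error, 50 kb markers): ≈ 95.5% of true crossovers recovered within
100 kb, ≈ 0.013 false events per individual-chromosome, median midpoint
error ≈ 16 kb. The residual misses are physically invisible events: pairs
of crossovers closer than the 5-marker resolution and events within
~250 kb of a chromosome end (no room for a flanking segment). Without
interference (ν = 1) recovery drops to ≈ 94% because close pairs are more
common.

## Ploidy calling

Windowed depth (100 kb) is summarized per chromosome and divided by a
sample-level disomic baseline: the length-weighted mean depth over all
chromosomes, re-estimated up to 5 times while excluding chromosomes whose
provisional ratio falls outside [0.8, 1.2]. The iteration prevents a
trisomic chromosome from inflating its own reference (with 5 chromosomes, a
whole-chromosome trisomy shifts a naive baseline by several percent). If
every chromosome is excluded, the plain mean is used with a warning.
Classification is by fixed strict thresholds — ratio > 1.2 trisomy,
< 0.8 monosomy — applied identically to whole chromosomes and to arms
(windows assigned to arms by midpoint relative to the centromere midpoint);
"partial trisomy" means exactly one trisomic arm. All ratios are invariant
to rescaling depth by a constant. At 10% depth noise and ≥ 100 windows per
chromosome the per-chromosome mean has a standard error below 1%, so
classification is essentially exact (measured ≥ 99% over 1000 calls).

## Interference statistics

**Observed distances.** A cis-DCO is a maximal P–H–P triple of consecutive
segments with *matching* parental flanks within one individual-chromosome;
its length is the distance between the two transition midpoints. P1–H–P2
triples are excluded: matching flanks are what guarantees the two
transitions are consecutive breakpoints on a single transmitted chromatid.

**Expected null.** Per chromosome, two sets of 400 crossover midpoints are
drawn with replacement from all identified crossovers of the genotype; each
first-set midpoint is paired with a uniformly drawn second-set midpoint and
the absolute distance recorded (self-pairs retained). Sampling is with
replacement because per-chromosome crossover counts can be below 400.
Distances are pooled across chromosomes for fitting and binning (a
per-chromosome mode exists).

**Gamma fits and bootstrap.** Both distance sets get two-parameter gamma
maximum-likelihood fits (no location shift). The shape MLE solves
`log(a) − ψ(a) = log(mean) − mean(log)` by Newton iteration from the
standard closed-form start; this is vectorized, which makes the
1000-iteration bootstrap (refit on resamples, record the shape) cheap. The
implementation is cross-checked against `scipy.stats.gamma.fit(floc=0)` in
the tests. Zero distances are replaced by half the smallest positive
distance (logged); a constant sample drives the shape to the 10⁶ cap with a
warning. Observed-vs-expected shape is compared with a Mann–Whitney U test
on the two bootstrap distributions; distance sets themselves are compared
with an unpaired rank test by default (the paired signed-rank variant is
available for equal-length binned frequencies, since a pairing unit for raw
unequal-size distance sets is undefined).

**CoC.** Observed and expected distances are binned at 3.5 Mb from zero;
expected counts are rescaled so the totals match; CoC per bin is
observed/expected (undefined bins reported as NaN). CoC < 1 at short
distances indicates positive interference; CoC > 1 indicates clustering.

### Calibration of the F2 cis-DCO estimator — an important property

For F2 (two-gamete) data this estimator is **not** calibrated to CoC = 1
under independent crossover placement, and users should not expect a flat
unit profile from a no-interference control. The reason is visibility
masking: a cis-DCO spanning distance *d* is only observed if the *other*
gamete contributes no breakpoint inside the span (probability ≈ e^(−d/L) at
the typical one breakpoint per chromatid) and matches the flanking parental
allele. Long observed distances are therefore depleted relative to the
midpoint-pair null, which has no such constraint. Measured at ν = 1 with
1000 individuals (both at truth level and through the caller): first-bin
CoC ≈ 1.3–1.45, falling to ≈ 0.5 by 15–20 Mb, mean ≈ 0.78 over
well-populated bins, with the observed median ≈ 30% below the expected
median. The same masking inflates the observed gamma shape slightly
(≈ 1.41 vs ≈ 1.32), so the bootstrap shape comparison — which detects any
systematic shift — declares "observed > expected" in well over half of
no-interference runs. Consequences:

* Genotype-to-genotype and short-vs-long *contrasts* remain meaningful
  (masking affects all genotypes with similar crossover density alike),
  and strong interference (ν = 5) is recovered essentially always
  (observed shape ≈ 3.5–4.7 vs expected ≈ 1.3, declared in 50/50 seeded
  runs).
* The absolute CoC level and the ν = 1 type-I behaviour of the shape test
  are biased by construction; a calibrated alternative would apply the
  same visibility process to the null, which this package intentionally
  does not do because it implements the field's published procedure as
  defined.

**Negative interference.** With class-II-only crossovers confined to the
terminal 20% of each chromosome (10% per end, density 5 per bivalent), the
first distance bin is overrepresented: observed/expected ≈ 1.46–1.49
through the caller at 20 kb marker spacing, 1.58 at truth level. The gap
between the two is caller resolution — pairs closer than 5 markers and
terminal flanks shorter than 5 markers are unobservable — so detection of
clustering (CoC > 1) is robust, while its measured magnitude depends on
marker density.

## Landscapes

Crossover midpoints are binned into fixed-origin 300 kb windows (last
window truncated; edge handling is a convention, stated here once).
Frequencies are events per F2 individual, so window sums conserve event
counts exactly. Scaled arm profiles map each window midpoint to [0, 1] from
telomere to centromere per arm and average across all arms. Cross-genotype
comparisons use Spearman rank correlation on identical windows (constant
profiles give NaN). Regional summaries group windows by midpoint into
pericentromere (a required, user-supplied annotation — operationally
methylation-defined, which the package does not compute) versus arm, report
per-window mutant/wild-type ratios, group medians, and a one-sided rank
test for stronger pericentromeric reduction; a rank test replaces
ANOVA/Tukey deliberately, as no distributional assumptions are warranted
for ratio data with zeros removed.

## Seed-based recombination frequency

For a double-reporter interval, RF (cM) = 100 × (1 − √(1 − 2(N_G +
N_R)/N_T)). The closed form inverts the expected single-fluorescent seed
fraction under independent assortment of the two cassettes; it is exact on
hand-computable inputs (e.g. N_G = N_R = 30, N_T = 400 → 16.334 cM) and
unbiased in simulation round trips (|bias| < 0.05 cM at N_T = 4000,
RF = 21.8). Its domain ends where the single-fluorescent fraction reaches
1/2; beyond that the square root is undefined and the package raises rather
than clamps. Confidence intervals come from multinomial resampling of the
three seed classes (percentile method; resamples crossing the domain
boundary clamp to 100 cM, which only occurs near the boundary itself).
Coverage measured at RF = 20, N_T = 1000: ≈ 95 ± 2%.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed or `numpy` Generator, and
identical seeds give bit-identical outputs (tested at pipeline level via
output-file hashes). The test suite's simulation sizes — 10 000 draws for
placement statistics, 200–1000 individuals for pipeline properties, 50
seeds per arm for the interference power/type-I study — were chosen so that
Monte-Carlo error is small relative to each asserted margin.
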