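# Methods

This note documents the models implemented in `cellcheck`, the
parameters that matter, the synthetic-data generator used for testing
and benchmarking, and the numerical and design choices made where the
problem left room.

## Signals

A genotyping array reports two per-marker quantities.  The B-allele
frequency (BAF) is the fraction of fluorescent signal attributable to
the alternate (B) allele; in a diploid cell population it clusters at
0, 0.5 and 1 for the RR, RA and AA genotypes.  The Log R Ratio (LRR)
is the log-scaled ratio of observed to expected total intensity,
centred at 0 for two copies.  Copy-number changes move both: a
single-copy gain carried by a fraction *f* of cells moves heterozygous
BAF from 0.5 to 1/(2+*f*) and (1+*f*)/(2+*f*) and raises LRR; a loss
removes the heterozygous band and lowers LRR.  BAF is highly
reproducible across array runs; LRR is dominated by systematic noise
on real data.  This asymmetry shapes several defaults below.

## Whole-chromosome screen (polysomy)

The per-chromosome BAF histogram (100 bins over [0, 1], moving-average
smoothed over 5 bins) is reduced to its central region — between the
first local minimum right of the RR peak and the last local minimum
left of the AA peak — and rescaled so that region's maximum is 1.  The
homozygous peaks dwarf the heterozygous ones, so fitting the scaled
central region keeps the fit sensitive to the signal that actually
discriminates states; the AA peak can optionally be included.  The bin
width and smoothing window are chosen so a peak of sd 0.03 (the
cleanest arrays) still spans at least six bins.

Three constrained Gaussian-sum models are fitted to the scaled region
with `scipy.optimize.least_squares` (Trust Region Reflective, a damped
least-squares method supporting the bound constraints; multi-start
over initial separations δ₀ ∈ {0.05, 0.1, 0.17, 0.25}, best solution
by lowest mean absolute deviation then smallest δ):

* **CN2** — one peak fixed at 0.5 (free height and width);
* **CN3** — two peaks at 0.5 ± δ with equal heights;
* **CN4/contamination** — a central peak at 0.5 and side peaks at
  0.5 ± δ with independent heights, plus two contaminant-heterozygote
  peaks at δ and 1 − δ.  All five centers follow from one parameter:
  a two-genome mixture at fraction *f* = 2δ places host-RA genotypes
  at (1 ∓ *f*)/2 and contaminant-RA-over-host-homozygote genotypes at
  *f*/2 and 1 − *f*/2.  Without the outer pair the fit mis-anchors
  once *f* ≳ 0.3 brings those peaks into the modelled region.

Peaks share one width (bounded to [0.01, 0.15]) unless `free_widths`
is set.  Model selection uses the mean absolute deviation over the
fitted bins.  Because each richer model nests the previous one, three
guards are applied: an aberrant model must beat 30% of the CN2
deviation (`fit_gate`); its implied cell fraction must reach
`min_fraction` (default 0.20 — the split is not trustworthy closer to
0.5); and its defining peaks must have fitted magnitude of at least
`peak_size` = 0.1 in scaled units (a three-peak fit whose central peak
has vanished is a two-peak fit wearing extra parameters).  The
contamination model additionally must beat 70% of the CN3 deviation
(`cn4_gate`).  When the CN2 fit itself fails to converge or its
deviation exceeds an absolute cap of 0.3, the chromosome is reported
as FAIL rather than forced into a state.

Fractions: trisomy *f* = 4δ/(1 − 2δ) (inverse of the peak-position
formula above); contamination *f* = 2δ, reported for the minority
genome as 2·min(δ, 0.5 − δ) since a mixture at *f* is the exact BAF
mirror image of one at 1 − *f*.

Sample-level verdict: a genuine trisomy affects one or a few
chromosomes; contamination reproduces the same peak split everywhere.
When more than half the screened chromosomes are aberrant and their
canonical δ values agree within 0.05, the sample is flagged
contaminated, per-chromosome CN3 labels are converted to the
contamination interpretation and the fraction is the median 2δ.

## Sub-chromosomal CNV caller (HMM)

Four states: CN0 (complete loss), CN1, CN2, CN3.  An explicit CN4
state is deliberately absent: for integrity screening it is enough to
flag a gain, and a stable CN3/CN4 separation is not achievable from
these signals.

**BAF emissions.**  Peaks are truncated Gaussians
G(β, β₀) = c·exp(−(β − β₀)²/d²) normalized to unit area on [0, 1]
(the erf-based normalizer makes a boundary peak twice the height of an
interior one).  Per state, with Hardy–Weinberg genotype priors
(f_RR, f_RA, f_AA) computed from the marker's population alternate
allele frequency:

* CN1: G(β, 0)(f_RR + f_RA/2) + G(β, 1)(f_AA + f_RA/2)
* CN2: G(β, 0)f_RR + G(β, 1)f_AA + G(β, 0.5)f_RA
* CN3: G(β, 0)f_RR + G(β, 1)f_AA + [G(β, β₀) + G(β, 1 − β₀)]·f_RA/2
* CN0: an observed BAF has probability 0.

d defaults to 0.04, the typical heterozygous-cluster spread of a clean
array.  β₀ defaults to 1/3 (every cell aberrant).

**LRR emissions** are exp(−(λ − μ_s)²/Λ²) with μ = (−0.45, 0, 0.3)
for CN1/CN2/CN3 and Λ = 0.2, normalized to a maximum of 1 (the
proportionality constant is free; a max-1 convention keeps the factor
in [0, 1] and does not change state ranking).

**Blending.**  The site emission is
`P_err + (1 − b(1 − P(β|s)))·(1 − l(1 − P(λ|s)))` with P_err = 1e-4.
The BAF density is rescaled by its interior-peak mode (d·√π) so both
factors are O(1); near boundary peaks the scaled value can slightly
exceed 1, which is harmless since only ratios between states matter.
The weights b (default 1) and l (default 0.2) moderate each channel.
The low default LRR weight exists for real arrays, where LRR is barely
reproducible between runs; it is a robustness concession, not an
information-theoretic optimum.  On data whose LRR noise really is
Gaussian — including the simulation benchmark below — the appropriate
weight is l = 1, and with l = 0.2 the caller is structurally unable
to detect small deletions: a deletion's positive per-site evidence is
bounded by −ln(1 − l) ≈ 0.22 from LRR plus a weak homozygosity term
from BAF, against a ≈ 26-unit double transition penalty, i.e. ~100
markers minimum.  With l = 1 the minimum falls to four markers.

**Missing data.**  Markers with no genotype call are dropped in
single-sample mode.  In paired mode they are kept with the
missing-call BAF probabilities P(N/A|CN0) = 0.5 and 0.5/3 for the
other states — a run of no-calls in one sample is itself evidence for
a homozygous deletion — and the LRR term is disabled at such sites.
A marker with a called genotype but missing BAF is treated as fully
missing (the signal, not the call, carries the information).

**Transitions.**  Symmetric, off-diagonal p = 1e-9 per basepair.  The
step matrix between consecutive markers is T^g for gap g in bp; powers
up to 10,000 are pre-computed and cached, larger gaps use
exponentiation-by-squaring, and gaps beyond 10 Mb use the 10 Mb power
(the chain is effectively mixed by then).  Initial distribution:
P(CN2) = 0.5, 0.5/3 for the rest.

**Decoding.**  Viterbi in log space gives the segmentation (ties are
broken toward CN2, then the lower state, for deterministic output);
scaled forward–backward gives per-site posteriors, a segment's quality
being the mean posterior of its assigned state (also exposed as a
Phred value capped at 99).

**β₀ re-estimation.**  When only a fraction of cells carries a gain
the CN3 heterozygous peaks shift toward 0.5 and the default β₀ = 1/3
can miss them.  The update
β₀′ = Σ(0.5 − |0.5 − βᵢ|)Pᵢ(CN3) / ΣPᵢ(CN3) over heterozygous sites is
iterated (tolerance 1e-4, max 20 iterations) with two stopping rules:
the total CN3 posterior mass must amount to at least ~2 effective
sites (otherwise there is no gain signal and the estimate would chase
noise outliers), and the separation 0.5 − β₀′ must keep 95% of
normally distributed BAF values below 0.5, using the CN3-weighted
spread actually measured in the data (floored at the model scale
d/√2) so the rule adapts to the noise level.

**Paired mode.**  The product chain over 16 state pairs.  Emissions
multiply.  Transitions couple the samples with the shared-state prior
σ ∈ [0, 1]:

    (1 − σ)·T[i,j]·T[x,y] + σ·T[i,j]   destination and source concordant
    T[i,j]·T[x,y]                      destination concordant only
    (1 − σ)·T[i,j]·T[x,y]              destination discordant

rows then normalized.  At σ = 0 this is exactly the Kronecker product
of independent chains (paired posteriors factorize into the two
single-sample posteriors); at σ = 1 discordant destinations are
impossible.  The initial distribution is coupled the same way, so
σ = 1 also forbids a discordant first marker.  The intersection of
marker positions is decoded; difference segments are maximal runs
where the two decoded states disagree — inherited variation shared by
both samples appears as a concordant non-CN2 pair and is not a
difference.  β₀ re-estimation, when requested, applies to the query
sample.

## Synthetic data

The generator reproduces the conditions of an array-based validation
study at desk scale.  Each experiment is one 40 Mb chromosome:

* marker gaps exponential with median 2 kb (the marker spacing of a
  0.5M genome-wide array);
* per-marker alternate allele frequencies from a symmetric Beta(a, a)
  with a solved so expected Hardy–Weinberg heterozygosity is 15%
  (a ≈ 0.214, the U-shape typical of array SNP panels), genotypes
  drawn per marker from the Hardy–Weinberg proportions;
* per-experiment noise: BAF sd uniform in [0.03, 0.08], LRR sd in
  [0.13, 0.26] — the ranges observed across real arrays;
* one to three non-overlapping aberrations per chromosome
  (Poisson(2.57) conditioned to {1, 2, 3}, mean 2.30, ≥ 50 kb apart),
  loss or gain with equal probability;
* aberration lengths from a two-piece log-normal: log-scale median
  1.7 Mb with the lower and upper standard deviations anchored so the
  1st and 99th percentiles land on 18 kb and 4 Mb.  The strongly
  asymmetric percentile profile cannot be matched by any single
  log-normal; the split form hits all three quantiles by construction
  (verified by a generator self-test).
* inside a loss, heterozygous markers move to (1−f)/(2−f) or its
  mirror (0/1 at f = 1) and LRR to −0.45; inside a gain, to 1/(2+f)
  and (1+f)/(2+f) with LRR +0.3; noise is added afterwards and BAF is
  clipped to [0, 1].  Recorded genotypes are the underlying diploid
  genotypes (the emission model never reads them; β₀ estimation reads
  heterozygosity, which is the pre-aberration state).

Whole-chromosome generators produce trisomies (clonally duplicated
allele per site) and contaminations (independent second genotype at
the same allele frequency, dose-weighted BAF; LRR left at the
attenuated intensity shift for trisomy, 0 for contamination, though
the screen reads only BAF).

What the generator does **not** emulate: GC waves and other systematic
LRR biases, batch effects, probe-specific cluster distortions,
genotyping-error structure, and real linkage-disequilibrium-driven
allele-frequency geography.  Benchmarks on this generator therefore
measure the statistical behaviour of the models under their own noise
assumptions — real-array error rates are higher, and the low default
LRR weight exists precisely because real LRR violates the Gaussian
assumption.

## Benchmark settings

The benchmark calls every simulated chromosome in single-sample mode
with d = 0.04, Λ = 0.2, μ = (−0.45, 0, 0.3), b = 1, p = 1e-9,
P_err = 1e-4, and two deliberate pipeline choices:

* **l = 1**: simulated LRR is honestly Gaussian, so it is fully
  weighted (see the blending discussion above; with the real-data
  default l = 0.2 small deletions are undetectable in principle).
* **LRR cleaned by a centered 9-marker moving average** before
  calling — the standard low-pass step for array intensities (the
  field's reference screening tool smooths over 10 markers by
  default; a centered window needs an odd width).  Smoothing
  suppresses the single-marker LRR excursions that would otherwise
  produce spurious loss calls.

Scoring follows the overlap rule: a truth region is detected by any
overlapping call of matching direction (loss truth vs CN0/CN1 call,
gain truth vs CN3 call), a non-diploid call overlapping no
direction-matched truth is a false positive, and the false discovery
rate is call-level (spurious calls / all non-CN2 calls).  A call
overlapping two truth regions detects both; the missed/added length
of detected regions quantifies boundary accuracy.

At this design's conditions the benchmark lands at a ~2% miss rate
and ~0.1–0.2% FDR over 2,000 experiments, with detection above 99.5%
for deletions spanning ten markers and duplications spanning four
heterozygous markers, false negatives split roughly evenly between
small duplications and small deletions, and false positives being
duplication-type calls driven by BAF noise.  The minimum-footprint
probe (clean deletions of k = 1..12 markers at BAF sd 0.04, LRR sd
0.2, no smoothing) first calls deletions at four markers and never
below.

## Known limitations

* Contamination fractions are identifiable only up to the minority
  genome (f vs 1 − f are BAF mirror images).
* Contamination below ~20% of cells sits at the reporting gate; the
  screen is advertised for fractions of roughly 20% upward.
* The CNV caller's absolute error rates on real arrays are dominated
  by systematic LRR noise the simulation does not model; the paired
  mode with σ ≈ 0.5 is the practical mitigation.
* Sex chromosomes are not special-cased; users should restrict to
  autosomes or interpret X/Y calls with the expected ploidy in mind.
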