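# Methods

## HRC prediction from sequence

The hydroxyl-radical cleavage (HRC) intensity of duplex DNA correlates with
minor-groove width and local backbone accessibility and can be estimated from
sequence with a tetramer lookup: each base is covered by four tetramers
(starting 3, 2, 1 and 0 bases upstream), and the profile value at base *i* is
the weighted average of their contributions with weights 1/6, 1/3, 1/3, 1/6.
Two table dialects are supported:

* **single** — one intensity per tetramer (256 values);
* **per_offset** — four intensities per tetramer, one for each position the
  tetramer covers (the original sliding-tetramer method produces four
  estimates per position, one from each covering tetramer).

The weights sum to 1, so adding a constant to every table entry shifts the
profile by exactly that constant, and a constant table yields a constant
profile — both are tested invariants.

**A structural null worth knowing.** For a *single*-dialect table the profile
is a convolution of the per-start tetramer-value series with the kernel
(1/6, 1/3, 1/3, 1/6). That kernel's frequency response at period 3 is exactly
zero: the weights reaching each residue class mod 3 sum to 1/3. Any strictly
3-periodic signal expressible as one value per tetramer start is therefore
annihilated by the weighting, and single-dialect tables cannot transmit
codon-driven 3-bp periodicity into the profile (finite-window leakage aside).
The per_offset dialect has no such cancellation, because the four covering
tetramers contribute four *different* values. The synthetic structured table
is consequently per_offset; real cleavage tables derived from the
four-estimates-per-position scheme are of this kind as well.

Edge policies: `trim` (default; profile only where all four tetramers exist,
length L−6 starting at base 3) and `renormalize` (all bases; available-tetramer
weights rescaled to sum 1). Bases within 3 positions of an N are masked and
propagate as missing values. Coordinates are 0-based half-open everywhere;
1-based positions appear only in report columns explicitly labeled as such.

## Periodogram and Fisher significance

On an interval of n profile values, mean-centered x̃ⱼ (j = 1..n):

    c = Σ x̃ⱼ cos(2πj/T),  s = Σ x̃ⱼ sin(2πj/T),  σ̂² = (1/n) Σ x̃ⱼ²
    P = (c² + s²) / (n σ̂²),   R = (2/n) √(c² + s²),   phase = atan2(s, c)

This divisor-n variance normalization is the unique least-squares-amplitude
form under which both classical significance formulas hold at a fixed Fourier
frequency: exact p = (1 − P/n)ⁿ⁻¹ and approximate p = exp(−P). The package
verifies the calibration by simulation: over 10⁴ Gaussian-noise windows of
n = 180 at T = 3, P matches Exp(1) with Kolmogorov–Smirnov distance < 0.02,
so exp(−P) is a uniform p-value. A pure period-3 cosine forces P = n/2 = 90
regardless of amplitude, and E[R] → the planted amplitude as noise vanishes.

The exact and approximate formulas deviate by a factor exp(P/n − P²/2n + …):
about 4% at P = 5 and 21% at P = 10 for n = 180. Both are reported; the
approximate form is what the fixed thresholds P ≥ 6 (p < 0.00248) and P ≥ 10
(p < 4.54e-5) refer to. T = 3 with n = 180 is a Fourier frequency, where the
projection equals the best harmonic fit; for non-Fourier T the same
projection formula is used and should be read as approximate. Phase is
reported but enters no significance computation. Constant (zero-variance)
windows are an error in single-window scoring and NaN in scans.

Window scans use step 1 with ties broken toward the smallest start; the
whole-gene score is the maximum windowed power, reported with its nominal
single-window p and no multiplicity correction, because downstream decisions
use fixed power thresholds rather than corrected p-values.

### Periodic-interval calling and its false-positive behavior

Periodic intervals are runs of ≥ 80 consecutive positions whose centered
100-bp window has P ≥ 1.8 (window [i−50, i+50); sequence ends without a full
window are excluded; the run [first, last] of centers is emitted as the
half-open interval [first, last+1)). Two empirical properties, measured by
the Monte-Carlo oracle in the test suite, should temper interpretation:

* Step-1 windows are strongly correlated (~100-bp decorrelation), so
  qualifying runs of ≥ 80 centers do arise in pure noise — in about 14% of
  600-point noise profiles. The rule is scale-invariant, so no noise level
  avoids this; treat isolated calls on long sequences accordingly.
* Around a strong planted segment, windows with only ~40% signal coverage
  already pass P ≥ 1.8, so call endpoints extend tens of bp (up to ~110 bp
  at high signal-to-noise) beyond the true segment. The caller is a
  detector, not a precise localizer; the window-maximum scan localizes a
  planted 180-bp block to within ±3 bp at high SNR and is the right tool for
  positioning.

## Homeobox search

The 58-residue consensus homeodomain
`RRRKRTAYTRYQLLELEKEFLFNRYLTRRRRIELAHSLNLTERHIKIWFQNRMKWKEN` is aligned by
local Smith–Waterman against the three forward-frame translations of each CDS
(BLOSUM62; BLAST-convention affine gaps: a gap of length g costs 11 + g,
i.e. open −12 / extend −1 in per-column terms; stop codons score −4 against
everything so alignments never cross them). Significance uses the gapped
Karlin–Altschul expectation E = K·m·n·exp(−λS) with the standard
BLOSUM62/11/1 constants λ = 0.267, K = 0.041 and search space = consensus
length × translated length. Hits require E ≤ 0.001 and ≥ 47 aligned consensus
columns (3 × 47 = 141 ≥ 140 nt — the decisive filter, which is exact). The
180-bp homeobox window is anchored so consensus residue 1 maps to window
nucleotide 1, extrapolating left when the local alignment starts inside the
consensus, clamped to the CDS and rejected below 140 bp. When several hits
pass, all are reported and downstream scoring uses the lowest-E hit. Reverse
strands are not searched: CDS are given on the coding strand.

## Synonymous-shuffle null

To ask whether a window's HRC3 signal is forced by its protein or chosen by
its codons, n = 1000 sequences encoding the identical protein are drawn, each
site independently, from a background codon-usage table's conditional
distribution P(codon | amino acid); stop codons are never sampled. Observed
and simulated windows are scored through the identical path (same flanks when
available — the observed profile is computed over the gene and sliced — same
edge policy, same T). The reported fraction f counts sims with sim_P ≥
observed_P (ties count, conservative) out of n, with no pseudo-count. When
the window is itself a draw from the background, f is uniform on (0,1)
(tested by KS); codon-optimized windows give f < 0.05. Codon-usage bias is
summarized as per-codon overall-frequency ratios between a foreground and a
background table, with Pearson correlation across codons between ratio
profiles; infinite ratios (zero background) are flagged and excluded.

One caveat measured during development: a codon arrangement optimized for
periodicity under one per_offset table remains mildly enriched for
periodicity under *any* per_offset table (a near-periodic base arrangement
yields a somewhat periodic profile whatever the table values), so f under a
mismatched table sits below 0.5 even with no shared signal structure.

## Cohort statistics

Regional GC uses the whole CDS upstream of the homeobox window as the 5′
region and everything downstream as the 3′ region, the latter entering
averages only when ≥ 60 bp; G+C fractions exclude masked bases and are
invariant under reverse complement. Directional hypotheses (flank GC >
homeobox GC) use one-sided Welch t-tests; group score comparisons offer Welch
t and Wilcoxon rank-sum. Anterior vs posterior partitions paralog groups 1–7
vs 8–13, with paralog numbers parsed from trailing digits of gene ids unless
supplied. The neighborhood association groups genes by nearest interval gap
to another homeobox gene (0 for overlap; infinite across chromosomes) at a
300-kbp radius, reports both tests, and accepts an exclusion list (e.g.
dropping Hox-cluster genes) applied after distances are computed on the full
set. Type-I error of the comparisons is verified at ≈ 0.05 on null cohorts.

## Overlap enrichment

A peak counts as overlapping if it shares ≥ 1 base with ≥ 1 locus (half-open;
bookended intervals do not overlap), each peak at most once — the counting is
deliberately peak-centric and not symmetric. The null re-places every peak
uniformly on its own chromosome with length preserved (no exclusion regions),
100 times by default; fold = observed / simulated mean, matching the
reference arithmetic (e.g. 2028/333.2 = 6.0864). An empirical p-value
(1 + #{sim ≥ obs})/(n+1) is reported as an extension beyond the reference
protocol's shuffle summary. Peaks on chromosomes absent from the locus set
count as non-overlapping with a warning.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (spec, seed). The structured tetramer table
plants a leading/covered-base effect of amplitude `planted_amplitude`
(default 0.5 cleavage units over Normal(1, 0.15) noise) so codon choice
controls profile periodicity. Homeobox genes are ~300 codons with the
consensus (+2 filler residues = 60 codons = 180 bp) at a recorded offset;
`optimize` ∈ {max, min, random} chooses window codons by a single greedy
left-to-right pass maximizing/minimizing P_HRC(3) (exhaustive search over 60
codon sites is infeasible; greedy demonstrably separates the three regimes),
falling back to random with a warning on flat tables. Cohorts default to 60
genes on two 10-Mbp chromosomes — clustered pairs 50 kbp apart, isolated
genes 310 kbp apart, straddling the 300-kbp radius — with Exp(3) baseline
scores, +3 for clustered genes and +3.5 for the ANTP class (mirroring the
reported contrast of class means ≈ 6.6 vs ≈ 3). GC cohorts draw bases
per-position Bernoulli at GC 0.64 (flanks) vs 0.53 (homeobox), n = 39. Peak
sets hit a planted fold by mixture placement (overlap-conditioned with
probability α = (F−1)p₀/(1−p₀) where p₀ is the uniform overlap probability;
non-overlap-conditioned for F < 1), which reproduces the target fold exactly
in expectation under the per-chromosome shuffle null.

What synthetic data does **not** emulate: real codon-usage tables and
dicodon/GC-isochore structure, experimentally calibrated cleavage intensities
and their units, evolutionary correlation between genes, chromatin context,
and realistic chromosome-scale locus density. Passing tests therefore
demonstrate correctness and statistical calibration of the machinery, not the
biological effect sizes of any real genome; per-gene values on real data
require user-supplied CDS and cleavage tables.

## Problem sizes and numerical choices

Default analysis/test scales were chosen to make every stage's statistics
meaningful at interactive run times: 10⁴ replicates for the Exp(1)
calibration; 200–1000 sims per shuffle null; 20-seed batteries for planted
recovery; 16-gene bundles with 60 extra genome-wide loci and 1500 peaks so
overlap counts are far from the 0/1 regime. Periodogram assertions guard the
Cauchy–Schwarz bound P ≤ n; degenerate inputs (constant windows, empty
groups, all-masked sequences, peaks longer than their chromosome, infeasible
planted folds) raise informative errors rather than propagating NaN. Scan
ties break toward the smallest start for determinism, and every random draw
flows from an explicit seed.
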