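# Methods

## The problem and the modeling stance

Outlier scans declare the top 1–5% of a genome-wide statistic "selected",
but any demographic history — especially a severe bottleneck like the
aye-aye's — produces such tails under pure neutrality. This package instead
calibrates every scan against an explicit baseline model: a piecewise-
constant demographic history, mutation- and recombination-rate
heterogeneity, and purifying/background selection in functional regions.
A value is a candidate only if it exceeds anything that baseline can
generate.

## Demographic baseline

`PiecewiseDemography` holds epochs of (diploid size, start generation,
backwards in time). The ancestral effective size is 23,706 diploids. The
sizes and times of the two subsequent declines (an ancient reduction
plausibly tied to human colonization of Madagascar 3,000–5,000 years ago,
and a decline over recent decades) were fitted in separate work and are not
re-derived here; the shipped defaults — 23,706 → 3,000 at 200 generations
ago → 1,000 at 3 generations ago, with a 20-year generation time for
calendar conversion — are configuration values that reproduce the
qualitative history, clearly marked as placeholders in the code. Every
analysis accepts a custom model.

Neutral baseline replicates are msprime coalescent simulations (binary
mutation model on a discrete physical map; multiallelic collisions dropped),
folded to minor-allele counts, polymorphic sites only, with μ = 1.52e-8 per
bp per generation and r = 1 cM/Mb.

## Scan statistics

Both statistics composite over sites and use the pooled empirical folded
spectrum G as the null; both include the null in the maximized parameter
grid, so CLR ≥ 0 identically.

**Sweep CLR.** The sweep-perturbed spectrum at escape probability p_e is
generated by the star-like sweep approximation: each of n lineages escapes
independently with probability p_e; the e escapees plus the single sweeping
lineage form j = e+1 ancestral lineages whose derived count is drawn from
the background projected hypergeometrically to size j; the sweeping
ancestor's allele is copied by all n−e hitchhikers. Folded data are handled
by symmetrizing G onto derived counts (mass split between k and n−k; the
self-symmetric class is not split), perturbing, and re-folding conditioned
on polymorphism. α is maximized over a 48-point log grid on [1e-8, 1e-1]
per bp plus the neutral limit. Because the spectrum depends on α and d only
through q = α·d, per-class log-likelihoods are tabulated on a 160-bin log
grid over q ∈ [1e-9, 30] (nearest-bin lookup); q ≥ 30 is treated as exactly
unlinked, i.e. the site contributes its null likelihood — this doubles as
the distance cutoff. The scan core is a numba kernel (~1 s per 1-Mb
chromosome with ~3,000 SNPs).

**Balancing CLR (polymorphism-only, folded).** The balanced-class spectrum
is f_B(k) ∝ Binom(k; n, x_eq) + Binom(k; n, 1−x_eq) over minor-count
classes k = 1..n/2 — both allelic-class terms are kept at every class, so a
perfectly balanced polymorphism (x_eq = 0.5) has its modal class at n/2.
Mixture weights decay as exp(−A·r·d) with fixed r = 1e-8 per bp and
physical distances from the window center (midpoint of first and last SNP).
Grids: x_eq ∈ {0.05, …, 0.50}; A log-spaced on [1e-2, 1e6] plus A = ∞ (the
exact null). Windows of W consecutive SNPs at step S; trailing partial
windows are dropped so all windows have comparable likelihood dimension.
No substitution/fixed-difference terms are used.

Exact numeric parity with the released implementations of either statistic
is not claimed; the likelihood structure is as documented above.

## Threshold calibration and candidate calling

One threshold per statistic/window scheme: the maximum CLR pooled over all
neutral replicates and chromosomes. Candidate calling is a strict
inequality, so re-applying a threshold to its own training data flags
nothing by construction, and on fresh neutral replicates the per-replicate
false-positive probability is ≈ 1/(R+1) for R training replicates.
Composite CLR magnitudes grow with the number of sites per chromosome, so
null replicates must match the length of the chromosomes being scanned (the
analysis scripts default to matched sizes). Candidates are intersected with
gene and structural-variant intervals as 1-based closed intervals (BED
input converted on read). The 5%-tail comparator uses the
linear-interpolation empirical quantile and counts values strictly above it.

## Forward Wright–Fisher simulator

Diploid, discrete generations, multiplicative fitness across sites with
genotype factors (1, 1+hs, 1+s), h = 0.5 everywhere, fitness floored at 0.
The simulated region is the 91,161-bp architecture: 3 genes of 9 × 130-bp
exons separated by 8 × 1,591-bp introns, each gene followed by one
16,489-bp intergenic block (one block per gene is forced by the arithmetic;
two separators would total 74,672 bp). Exonic mutations draw 2Ns from four
bins [0,1), [1,10), [10,100), [100, 2N), uniform within bins, with
reference N = 23,706; the default class proportions (0.25, 0.49, 0.04,
0.22) follow published human/aye-aye DFE estimates and are configuration
values, not quantities derived here. Intron and intergenic mutations are
neutral. Per-1-kb rate maps are drawn uniform within the stated bounds
(0.01–10 cM/Mb; 0.61e-8–3.8e-8); because neither uniform's mean equals the
fixed genome-wide rate, a `mean_matched` mode (default) rescales draws so
the chromosome average matches the fixed rate within 1%, and a literal
`uniform` mode is also provided.

Runs: 10N-generation burn-in at the ancestral size (verified to reach
neutral equilibrium diversity within Monte-Carlo error), then 10N (sweep)
or 85N (balancing) generations, with the recent demographic declines
applied at their (scaled) times before sampling; sampling returns 5
diploids' folded polymorphic sites plus the haplotype matrix. A single
selected mutation is introduced τ·N generations before sampling at the
center of the middle gene's middle exon (configurable). Sweeps are retained
only if fixed by sampling; balanced alleles only if still segregating; any
failure restarts the run from a saved copy of the introduction-time state
(capped, default 300–1,000 restarts; exceeding the cap marks the scenario
infeasible, as for weak sweeps with very recent introduction).

**Rescaling.** A factor Q divides population sizes and durations and
multiplies μ, r, and DFE/sweep selection coefficients, preserving
population-scaled parameters. The frequency-dependent balancing coefficient
S_bp = F_eq − F_bp is *not* multiplied by Q: it is already O(1), and
scaling it by Q = 100 drives heterozygote fitness negative so the allele is
lost immediately; leaving it unscaled keeps the dynamics in-domain, and the
restoring force still dwarfs drift at desk scale (N·S ≫ 1 for realized
deviations). Strongly deleterious mutations with Q-scaled s < −1 become
effectively lethal, which only shortens their (already brief) sojourn.
Q = 1 reproduces the full scale and needs cluster-level time and memory;
Q = 100 is the desk default used by the tests, and neutral diversity at
Q = 50 and Q = 100 agrees within Monte-Carlo error.

The engine stores the population as a (2N × sites) genotype matrix with
numba kernels; monomorphic columns are pruned in a cache-friendly row-wise
pass every 8 generations, and an occupancy bitmap enforces the
infinite-sites approximation (collided mutation positions are redrawn-or-
skipped; a focal introduction displaces any standing variant at its
position). Random draws come from one seeded generator per replicate;
restarts continue the stream, so retries are independent but the whole
replicate is reproducible from its seed.

## Power analysis

Each replicate draws its own rate maps, burns in, and is evaluated under
matched conditions: the neutral comparator and every introduction-time
branch start from the same post-burn-in snapshot (the model is
time-homogeneous between burn-in and the recent declines, so the neutral
stretch between burn-in and introduction is statistically redundant and is
not simulated; branches still traverse the demographic tail). Scores are
the replicate's maximum windowed CLR — a detection framing ("was anything
found in this region") — with per-SNP sweep CLRs aggregated to 100-bp/1-kb/
10-kb windows by maximum (the replicate maximum is invariant to that
refinement) and balancing scored on its SNP-count windows. ROC curves sweep
a common threshold over pooled scores; power is read at FPR = 0.05 by
conservative step interpolation.

At this scale the sweep footprint s/(2·r·ln 2N) reaches hundreds of
kilobases for 2Ns ≥ 1,000 — larger than the 91-kb region — so strong sweeps
erase variation region-wide and cannot be localized *within* the region;
the simulator's sweeps are therefore validated by detection (sweep vs
neutral separation, and power decaying from τ = 0.2 to τ = 2) rather than
by argmax position. Balancing power increases with the age of the balanced
polymorphism (τ = 10N → 75N), matching expectation: linked intermediate-
frequency variation takes coalescent timescales to accumulate.

## Synthetic datasets

`make_fixture` writes miniature datasets in the empirical formats — VCF
(5 diploids assembled by random pairing of the 10 sampled haplotypes,
unphased; REF/ALT are placeholder A/T since the simulators track biallelic
state only), GFF3 gene rows tiling the architecture, BED structural
variants (one synthetic interval is placed around each implanted selected
site), matched freq files, and a ground-truth manifest. Output is
byte-identical for identical config and seed. The generator emulates the
empirical inputs' formats and allele-frequency structure; it does not
emulate sequencing error, genotype likelihoods, missingness, or reference
bias, so passing tests demonstrate pipeline correctness on clean genotypes,
not robustness to calling artifacts.

## Problem sizes used by the test suite

The suite runs entirely at desk scale, chosen once as the smallest sizes
with adequate Monte-Carlo resolution: 100 constant-N coalescent replicates
of 300 kb for the neutral-SFS checks; 20 training + 100 fresh neutral 1-Mb
replicates for threshold conservativeness and the outlier contrast; Q = 100
with 50 replicates per scenario for the power orderings (balancing
τ ∈ {10N, 50N, 75N}; sweeps 2Ns = 1,000 at τ ∈ {0.2, 2}); 1,000 random
datasets for the nested-model checks; N = 1,000 diploids and 25,000
generations for the balancing-equilibrium check. Full-scale runs (Q = 1,
100 replicates per scenario, 14 chromosome-length replicates) use the same
code paths via the documented parameters.

## Known limitations

- The non-ancestral demographic epochs are placeholders, not the fitted
  companion model; absolute threshold values from the default model should
  not be quoted.
- The sweep model is star-like (no partial/soft sweeps, no invariant-site
  terms); the balancing model has no substitution terms and a binomial
  balanced class (no dispersion refinement).
- CLR magnitudes depend on chromosome length; thresholds are only valid for
  matched lengths.
- The forward simulator's strongly deleterious class saturates at lethality
  under aggressive rescaling.
- Empirical-mode inputs assume complete, correct diploid genotypes
  (AN = 2×samples); no genotype-likelihood handling.
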