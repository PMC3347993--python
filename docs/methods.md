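# Methods

This note documents the models, conventions and numerical choices behind
`foldeval`, and what the synthetic benchmarks do and do not demonstrate.

## Energy model

The model is a deliberately small additive nearest-neighbor model
(~100 parameters): stacked-pair energies as a full 6×6 table over the
allowed pairs {AU, UA, CG, GC, GU, UG}; hairpin, bulge and internal-loop
penalties tabulated by loop size 0..30 with logarithmic extrapolation
`ΔG(len) = ΔG(30) + c·ln(len/30)` beyond; an affine multiloop cost
`a + b·(branches incl. closing pair) + c·unpaired`; and a terminal AU/GU
penalty.  The exterior loop is free, so the open chain has energy exactly
0 and the partition function is always ≥ 1.

Excluded on purpose: dangles, coaxial stacking, sequence-dependent loop
terms (mismatches, special hairpins), internal-loop asymmetry, temperature
dependence beyond a fixed RT = 0.6163 kcal/mol.  The packaged `toy37` and
`toy37_alt` files are illustrative fixtures — plausible magnitudes, not
measured thermodynamic values; `toy37_alt` is a deterministic perturbation
of `toy37` so comparisons across parameter sets can be exercised.  The
point of the abstraction is that every estimator is defined relative to a
pluggable parameter set, which is the property the analyses depend on.

**Terminal-penalty bookkeeping.**  An AU/UA/GU/UG pair pays `terminal_au`
once for every adjacent loop that is not a stack.  A mid-helix pair pays
nothing; each helix-end pair pays once per exposed side (a lone pair pays
twice).  This convention was chosen because it is exactly additive over
the loop decomposition, which lets `free_energy`, the MFE recursion, the
partition function and the enumeration oracle agree to machine precision
rather than "up to convention".

**Minimum hairpin loop** is fixed at 3 unpaired bases (the standard
convention), enforced at structure construction, so no parser, predictor
or generator can produce a violating structure.

## Folding recursions

MFE folding and the partition function share one decomposition:
`V/Zb(i,j)` over the loop closed by (i,j) (hairpin, stack,
bulge/internal up to a configurable 30-unpaired-base span cap, or
multiloop), `WM1/ZM1` for a multiloop segment whose branch starts at its
left end, `WM/ZM` for ≥1-branch segments, and an exterior accumulator.
Partition quantities are carried in log space with `logsumexp`, so
sequences up to several hundred nucleotides stay finite.  Base-pair
probabilities come from the matching outside recursion;
`p(i,j) = exp(logZb + logZout − logZ)`, clipped to [0,1].  Position-wise
conservation `q(i) + Σ_j p(i,j) = 1` holds to 1e−9 and is tested beyond
enumeration range.

Tracebacks are deterministic: prefer leaving a base unpaired, then the
pair with smaller i, then smaller j; candidate orders inside `V` are
fixed (hairpin, stack, internal loops by (k,l), multiloop splits by k).
Equality checks in tracebacks recompute the identical floating-point
expressions used in the fill, so no tolerance is needed.

MEA maximises `Σ 2γ·p(i,j) + Σ q(i)` and the γ-centroid maximises
`Σ ((γ+1)·p(i,j) − 1)`, both by a Nussinov-style DP over the probability
matrix only.  Pseudo-expected accuracy treats `eTP = Σ_{(i,j)∈S} p(i,j)`
as a true-positive count against the total pair mass (pseudo-sensitivity)
and the prediction size (pseudo-PPV); pseudo-MEA scans γ over
2^−5..2^10 and keeps the smallest γ attaining the best pseudo-F.  The
grid is a documented choice; its span covers the full
sensitivity/PPV trade-off of the centroid threshold 1/(γ+1).

Correctness is defined against exhaustive enumeration: for random
sequences of length ≤ 12, MFE energy, Z, every p(i,j) and the MEA and
centroid objective optima agree with brute force to 1e−9 relative
tolerance (at this scale the observed deviations are ≤ 1e−15).

## Accuracy layer

A predicted pair is correct only on exact index match — no ±1 slippage;
this is the strictest, fully reproducible reading.  Corner conventions
(the measures are otherwise undefined): both structures empty → (1,1,1);
exactly one empty → the undefined ratio is 0 and F = 0.

The three averages are implemented exactly as stated in the README; the
two limit identities of the S-weighted average (all s=0 → weighted, all
s=1 → unweighted) are asserted to 1e−12.  The S-weighted average is *not*
required to lie between the other two for heterogeneous s_i — that is not
a theorem, and counterexamples arise naturally (a large, high-similarity
class is discounted harder than size-weighting alone would suggest).

**Normalized structure similarity.**  A full tree-alignment similarity is
out of scope; the package uses a documented stand-in.  Two records are
aligned by a banded edit alignment (edlib) over a combined 12-symbol
alphabet — 4 bases × {paired-open, paired-close, unpaired} — and the
score is `0.5·F_pairs + 0.5·identity`, where `F_pairs` is the F-measure
of pairs mapped through the aligned columns and `identity` counts
matching aligned residues over the mean of the two lengths.  Design
rationale, found the hard way: aligning structure strings alone lets the
alignment wander as soon as a few pairs differ, and normalising identity
by the longer length lets edit alignments cherry-pick matches across
large length gaps; the combined alphabet and mean-length denominator make
the score smooth and monotone in the mutation rate, which the generator's
calibration requires.  Exact symmetry is guaranteed by ordering the two
inputs canonically before alignment.  The measure is 1.0 for identical
records and stays in [0,1].  Wherever a class similarity s_i is consumed,
an externally computed value (e.g. from a dedicated structural-alignment
tool) can be supplied instead; single-record classes take s = 1 by
convention.

## Resampling statistics

The resampling unit is the individual RNA record.  Bootstrap CIs use
10⁴ resamples by default, drawn with replacement at the original sample
size; bounds are empirical percentiles with linear interpolation (the
numpy default), so results are bit-stable under a fixed seed.  For
class-aware averages the class labels ride along and the average is
recomputed per resample; a resample that misses a class entirely simply
averages over the classes present.  The Anderson–Darling normality check
(statsmodels' approximate p-value) is attached to every result as a
diagnostic; constant distributions are flagged degenerate, not crashed on.

The permutation test compares mean F between two sets by re-splitting the
pooled values into the original sizes, 10⁴ times by default, or exactly
over all C(n_A+n_B, n_A) splits when that count is ≤ 10⁵.  The one-sided
orientation must be stated explicitly (`A_less` / `A_greater`) because
"difference ≤ observed" alone does not fix the roles of the two sets;
small p under `A_less` is evidence that A's mean is genuinely below B's.
The default p-value is the plain proportion, which can be exactly 0;
a `plus_one` flag switches to the (k+1)/(N+1) estimator.  Tie comparisons
use a 1e−12 guard so float noise in recomputed means cannot flip a
boundary count.

Calibration, measured by the acceptance script at reduced size (1000
resamples for coverage, 2000 permutations per null trial — the rates are
properties of the rules, not of the resample count): 95% bootstrap
coverage lands at 93–96% over 300 trials, and two-sided permutation
type-I error at 4–7% over 500 null trials with 50 records per arm.

## Synthetic data

A class is grown from one ancestor: random sequence at the class GC
content (default 0.5), reference structure drawn from the Boltzmann
ensemble by stochastic traceback (so references share the thermodynamic
structure the predictors assume; a flag switches to model-free random
nested structures for robustness checks).  Ancestors are redrawn (up to
20 times, keeping the densest) until the structure has at least one pair
per ~12 nt, since real reference structures are never empty.  Members
draw their lengths from the class's normal distribution (clamped to
[20, 700]) and reach them by indels at unpaired loop positions —
insertions anywhere, deletions only of unpaired bases not sitting in
minimum-size hairpins — then substitutions at rate μ; pairs whose bases
are no longer complementary are dropped.  μ is calibrated by bisection
against the within-class similarity target on a pilot subset sharing the
final member random stream (mutation draws are pre-drawn per member so
similarity responds monotonically to μ).  If an ancestor's length draws
cap the achievable similarity below target, generation deterministically
retries with fresh draws (up to 5 attempts) and fails loudly if the
achieved value still misses by more than 0.1.  Classes with fewer than
four members are calibrated but not checked — their mean pairwise
similarity is a single noisy draw.

Simulated predictors perturb the reference: keep a random subset of true
pairs sized by the sensitivity target, insert compatible false pairs to
meet the PPV target.  On short or dense references the insertion may fall
short; the default is best-effort (the achieved accuracy is what the
record table reports), with a `strict` flag that raises instead.  Per
record the target F is drawn from the configured normal, clipped to
[0.05, 1]; achieved mean F lands within ~0.05 of the target minus a small
upward quantization bias on references with very few pairs.

What the synthetic benchmark emulates: the class structure of a mixed
RNA benchmark — eight classes whose sizes (89, 27, 309, 16, 3, 6, 91,
484), length distributions and within-class similarities (0.53–0.96)
follow the published table the generator defaults mirror — plus
predictors with controlled accuracy separation.  What it does not
emulate: family covariation and phylogeny, pseudoknots, real
thermodynamic parameters, or any correlation between a record's class
and how hard it is to predict beyond what the energy model induces.
Passing tests therefore validate the *evaluation machinery* (metrics,
averages, intervals, tests, reports) and the predictors against their own
model — they do not certify prediction accuracy on real RNA.

## Problem sizes and defaults

Tests and the acceptance script run everything at desk scale, chosen as
the package's own defaults for quick, deterministic runs: enumeration
oracles at sequence length ≤ 12 (150–200 sequences), conservation checks
to length 60, the end-to-end benchmark at size scale 0.1 and length scale
0.2 of the eight-class layout (104 records, lengths ~20–150 nt), 500–2000
resamples/permutations in orchestrated runs.  Library defaults remain the
full-size ones (10⁴ resamples and permutations, full class sizes); all
scaling knobs are explicit configuration.

## Known limitations

* The energy model is a teaching-scale reduction; its numbers are not
  comparable to Turner-parameter predictions.
* The similarity stand-in is alignment-based, not a tree alignment; its
  absolute values should not be compared against published similarity
  columns, only used as a consistent within-package weighting signal.
* `perturb_structure` quantizes hard on references with few pairs, biasing
  achieved F slightly upward on very short sequences.
* Folding cost grows as O(n²·cap²) + O(n³); pure-Python/numpy throughput
  makes lengths beyond a few hundred nucleotides slow in bulk runs.
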