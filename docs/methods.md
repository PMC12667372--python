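# Methods

`obliphase` implements reference-based diploid haplotype phasing under a
data-oblivious computation contract: every step that touches the target's
genotypes runs with control flow and memory-access patterns that depend only
on public shape parameters, and all secret-dependent arithmetic is integer
fixed point.  This note records the model, the numerical choices, and the
design decisions taken where the design was genuinely open.

## The phasing model

**Genotype graph.**  The target's heterozygous sites are split into
consecutive segments of at most `H_seg` hets (default 3).  A segment with
*h* hets has 2^h *phase options*: assignments of the het alleles to
haplotype A (haplotype B is the complement at het sites; both haplotypes
equal the genotype at homozygous sites).  Option *m* encodes its pattern in
binary, so the global A/B swap maps option *m* to `2^h − 1 − m`.  Every path
through the segment chain is a haplotype pair consistent with the genotypes.

**Diploid Li–Stephens HMM.**  Conditional on a panel of K reference
haplotypes, the site-level state is `(k1, k2, option)`: haplotype A copies
from reference haplotype `k1`, B from `k2`.  Emissions are `1 − eps` per
matching allele and `eps` per mismatch (default `eps = 1e-4`).  Between
adjacent sites each copy state switches with probability
`rho_i = 1 − exp(−0.04 · Ne · d_i / K)` where `d_i` is the genetic distance
in cM (from a genetic map, or a flat 0.01 cM per interval without one) and
`Ne = 15,000` — the standard 4·Ne·r/K scaling.  Within a segment the option
is fixed; at segment boundaries the option transitions freely under a
uniform prior and the joint posterior over adjacent options is accumulated.
These option-transition posteriors drive Gibbs-style resampling of the
phase.  With one reference haplotype the het phase is unidentifiable (both
options mismatch symmetrically), so K = 2 is the smallest informative panel.

**MCMC schedule.**  Default: 5 burn-in, then prune/burn-in alternation
(3 prunes), then 5 main iterations.  Burn-in samples a new phase estimate
from the posteriors (backward sampling on the boundary chain).  Pruning
merges an adjacent segment pair when the swap-symmetrised joint mass of its
best option transition exceeds `prune_threshold` (default 0.999); the merged
segment keeps only the chosen pattern and its complement and is never
re-split, so the segment count is non-increasing.  Main iterations run a
max-product Viterbi decode; the best decode across main iterations (by
fixed-point likelihood, ties to the earliest) is the output.  Merge
decisions are revealed between iterations: the obliviousness contract is
per-iteration, conditional on the current (public-shape) graph — the segment
layout derives from het-site positions, which this artifact treats as shape.

**Windows.**  Windows are sized so the expected het count covers
`window_min_segments` segments at the minimum het rate
(`H_seg · window_min_segments / min_het_rate`, default 600 sites), processed
independently and stitched over a 100-site overlap; the next window's
orientation is flipped when flipping increases het agreement in the overlap,
and the hand-over happens at the overlap midpoint.

## Compressed panels and neighbour selection

The reference panel is tiled into blocks grown greedily site by site under
two caps (width ≤ 32 sites, unique rows ≤ 256); each block stores only its
unique haplotype rows plus an index map.  Blocks do not overlap; cross-block
match continuity is handled by explicit carryover (below).  Per block, a
PBWT prefix tree is built once from the public panel: one level per prefix
length, nodes in positional prefix order (lexicographic by reversed prefix)
with divergence values — the longest common suffix of adjacent nodes'
prefixes.  Trees are reused across iterations and samples.

Each phase-estimate haplotype is inserted obliviously: per level the
insertion rank is maintained by counting scans, the divergences to the
neighbouring nodes by oblivious reads, and — as the linear-scan embodiment
of the divergence chains — the full vector of block-level match lengths per
node (updated as `match+1` where the edge allele equals the target allele,
else 0; a full-array operation with no secret indexing).

A neighbour query at search position *p* ranks haplotypes by the match
length ending immediately before *p* (sites p−1, p−2, …).  Candidate search
lowers a threshold until the nodes at or above it hold at least S original
haplotypes, keeping all ties — since match length is non-increasing walking
outward from the insertion point, this is the contiguous node run the
outward walk would visit, and it provably contains the true top-S.  Matches
spanning the whole in-block prefix are extended by the *global* match length
carried across preceding blocks, updated only at block starts
(`g' = full + g` if the block matched end to end, else `full`).  Ranking
takes the S best by (total match length, then smaller haplotype id) via S
oblivious full-scan maximum passes.  One search position is drawn per
segment, uniformly among its het sites; both haplotypes of the pair are
inserted independently and queried at every position (S = 4 per query).

The union of all neighbour sets becomes the conditioned panel: selection
counts are accumulated in a bitmap by one-hot scans, and a fixed public
number of slots `K_cap = min(n_sets · S, k_max, n_hap)` is filled by
repeated oblivious maximum selection on (count, smaller id).  `k_max`
(default 32) bounds the O(K²) HMM; when the union fits, the result is
exactly the plain set union.  Unused slots repeat the first selected
haplotype and are flagged as padding, hiding the true union size; padded
rows get zero prior weight in the HMM (`w = 1/K_eff` on real rows), so they
never carry probability mass.  Row contents are gathered by one-hot matrix
contraction — a linear scan over the whole panel per slot.

## Dynamic fixed point

Values are signed 64-bit mantissas with F fractional bits and one
power-of-two exponent per row: `value = mantissa · 2^(exp − F)`.  After
normalisation the largest magnitude in each non-zero row lies in [0.5, 1);
all-zero rows carry a reserved exponent.  Addition aligns rows to the larger
exponent plus one headroom bit; multiplication adds exponents and shifts the
double-width product down by F; row/column sums shift by ⌈log2 n⌉ headroom
bits first.  Rounding is truncation via arithmetic right shift (floor),
branch-free; shift amounts come from bit-length computations and are applied
uniformly per row.  Exact division (for posterior normalisation, state
priors and sampling) is restoring long division with exactly F iterations;
an all-zero distribution renormalises to uniform — the convention that keeps
the sampling stage total, and exactly the failure mode static fixed point
exhibits when everything underflows.

The generic layer defaults to F = 60 and forms the 128-bit product from
31-bit limbs.  The phasing engine runs at **F = 31**, where the product of
two normalised mantissas fits a single 64-bit word: per-operation precision
2⁻³¹ leaves the forward–backward posteriors within ~1e-8 total variation of
exhaustive float enumeration, orders of magnitude inside every tolerance
used here, at several-fold lower cost.  The static baseline (`dynamic=False`)
freezes exponents at zero with F = 52 — the best single-scale choice for
64-bit words — and demonstrably collapses: a 200-step chain of ~2⁻¹⁰ factors
drives every mantissa to zero, flattening distributions to uniform, while
dynamic scaling preserves the distribution's ordering with the exponent
tracking the true magnitude (~2⁻²⁰⁰⁰).

Inside the per-site transition kernel, all entries of an option row share
one exponent, so the kernel is fused in the integer domain (sums with
headroom, single-multiply products) and rows are renormalised once per site.
Per-site renormalisation is the power-of-two row rescale only — the
row-constant factor cancels when posteriors are formed, where the exact
constant-time division is applied.

## Obliviousness contract

The contract is *algorithmic*, at the level of an instrumented access trace:
linear-scan ORAM reads/writes, branch-free multiplexers, a bitonic sorting
network (stability via composite keys), oblivious filtering to a fixed
public length with sentinel padding, and constant-iteration long division.
The trace harness records (operation, shape, index) events — element-wise
for scalar primitives, one event per fixed-shape vectorised operation — and
the tests assert byte-identical traces across resampled secrets for every
primitive and for a full phasing iteration.  No claim is made about
microarchitectural timing (caches, ports, speculation), which a high-level
language cannot control; the `Secret` wrapper enforces, at run time, that
secrets cannot be branched on or used as subscripts, with `expose()` the
single declassification point.

## Synthetic data

The generator emulates the local haplotype-sharing structure real panels
have: 20 founders drawn site-wise from allele frequencies uniform on
[0.05, 0.5], 200 panel haplotypes built as founder mosaics (switch rate
0.005/interval, mutation rate 0.001/site), 500 sites.  Targets are panel
mosaics with exactly 3 uniformly placed recombinations per haplotype and
0.2% genotype-dosage errors (resampled uniformly among the other two
dosages).  It does not model coalescent genealogy, linkage-disequilibrium
decay with distance, allele-frequency spectra, genotyping-array site
ascertainment, or population structure — so passing benchmarks show the
algorithm recovers mosaic structure under noise at desk scale, not that it
matches the accuracy published for biobank-scale panels.

The switch error rate is the fraction of consecutive heterozygous site
pairs whose relative phase differs from the truth, invariant under swapping
the estimated pair.  Scoring covers sites heterozygous in both the observed
genotypes and the truth: a genotype error that fabricates a het where the
truth is homozygous leaves the true phase undefined there, so such sites are
excluded (counted, logged); with fewer than two scoreable hets the rate is
undefined and reported as 0 with a warning flag.

## Numerical and degenerate-input conventions

- Out-of-range oblivious reads return sentinel 0; division by zero returns
  all-ones — data-dependent exceptions would themselves leak.
- Sort/filter padding uses a reserved maximal key class, so real keys are
  never compared against it.
- All-homozygous targets return the forced phase immediately; zero shared
  sites between target and panel is an ingest error.
- Blocks always accept their first site, so a width-1 block may exceed the
  unique-row cap when a single site already does (progress guarantee).
- Site matching across files is exact on (chrom, pos, ref, alt); allele
  swaps and strand flips are rejected, not repaired.
- Ties everywhere break toward smaller indices (haplotype id, option index,
  earliest iteration) for determinism; a fixed seed yields byte-identical
  output.

## Known limitations

- The per-iteration trace contract treats het-site positions (hence graph
  shape and window layout) as public; hiding het counts would require
  fixed-capacity segment layouts.
- Pruning reveals merge decisions between iterations (see above).
- O(K²) diploid state space: `k_max` bounds the conditioned panel at 32
  haplotypes; very large unions are truncated by selection frequency.
- Rare variants, missing-genotype imputation and multi-sample amortisation
  are out of scope.
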