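# Methods

## Design spaces and counting

A design space is a list of discrete factors plus a gene-order factor.
Factors are categorical (promoter identity, backbone, chassis) or ordinal
(plasmid copy number, with an integer rank per level). The space's
cardinality is the product of level counts times the number of admissible
gene orderings and is always computed symbolically; materialization is
guarded by a cap (default 10⁶ points) so that a mistyped template cannot
silently enumerate millions of constructs. Enumeration order is
lexicographic over factor levels in declaration order with orderings
innermost, which makes construct streams and their hash-derived IDs
bit-identical across runs and platforms. IDs are a SHA-1 prefix of the
canonical serialization of the assignment and ordering, so the same design
always receives the same ID regardless of how it was produced; registry
IDs of any particular laboratory cannot be reproduced and are not
attempted.

The first-round flavonoid space models expression tuning the way such
libraries are built in practice: a single composite 4-level backbone
factor (origin × first promoter: pSC101/p15a crossed with P_lacUV5/P_trc)
rather than two crossed 2-level factors, because the backbone arrives as
one physical part and the 4-level column of the orthogonal array drives it
directly; three intergenic slots each carry none/P_lacUV5/P_trc; four
genes permute freely (24 orderings). Total 4 × 3 × 3 × 3 × 24 = 2592.

Constraints (fixed levels, trimmed menus, pinned gene positions, explicit
ordering whitelists) produce a *new* space whose enumeration equals the
filtered enumeration of the old one; contradictory constraints raise an
error instead of yielding an empty space, because a silent empty library
is the costlier failure in an automated pipeline. Constraint application
is idempotent and commutes across disjoint constraints (property-tested).

## Orthogonal-array reduction

The 16-run array over five 4-level columns is constructed from GF(4)
(irreducible polynomial x² + x + 1): runs are pairs (a, b) ∈ GF(4)²,
columns the five linear forms u·a + v·b with (u, v) one representative per
line through the origin. Linear independence of any two forms gives
strength 2 — every ordered level pair appears exactly once per column
pair — which is verified exhaustively in the tests rather than assumed.
The construction was chosen over a table lookup because it is
self-contained, testable, and extends to other 4^k cases.

Factors with fewer than four levels are driven through level collapsing:
for a 3-level promoter factor the two lowest column indices map to the
first level (the no-promoter state), indices 2 and 3 to the weak and
strong promoter, giving the 8/4/4 balance in 16 runs; 2-level factors
collapse pairwise. Collapsing preserves orthogonality between columns
while intentionally over-sampling the collapsed level. The two collapsed
indices are always the two lowest — an arbitrary but documented and
deterministic choice.

Gene order is reduced from n! permutations to the n rows of the cyclic
Latin square grid[i][j] = (i + j) mod n, in which every gene occupies
every position exactly once across the set. The literature does not
single out a canonical square for this use; the cyclic square is the
simplest deterministic choice and any Latin square gives the same
positional balance. The array's last column selects the row. For the
four-gene pathways this reduces 2592 to 16 constructs, compression 162:1,
tracked in exact rational arithmetic (`Fraction`), never floats.

Regular 2^(k−p) fractional factorials are built from defining words
("D=ABC"); the defining relation is the group generated by the words, the
resolution its shortest word length, and generator sets that would alias a
main effect with the identity are refused. `choose_strategy` picks the
full factorial whenever the (possibly constrained) space fits the build
budget — inclusive at the boundary — and the orthogonal array otherwise.

## Construct compilation and sequence IO

Templates are slot lists: one backbone slot, per gene position an optional
promoter slot and a gene slot, optional fixed parts (terminators). A
promoter level of `none` omits the slot entirely. Concatenation is
seamless because ligase cycling reaction (LCR) assembly leaves no junction
scars; all features sit on the plus strand (pathway genes co-oriented),
internally in 0-based half-open coordinates. GenBank output converts to
the format's 1-based closed convention via Biopython and emits join-style
compound locations for features spanning the origin of a circular record;
reading inverts both conversions, and round-trips are tested to preserve
sequence, topology and every feature interval.

## LCR planning

Melting temperatures come from unified nearest-neighbor thermodynamics
(ΔH/ΔS stack summation with duplex initiation and terminal-AT penalties)
with the entropic monovalent-salt correction
ΔS′ = ΔS + 0.368·(N−1)·ln[Na⁺], evaluated through Biopython's
`MeltingTemp.Tm_NN`. Default conditions: 50 mM Na⁺, 0 mM Mg²⁺, 250 nM
oligo; all configurable per call and reported by
`TmConditions.describe()`. The tests pin the model to an independent
hand summation of the published parameter table to 0.05 °C.

A bridging oligo spans one junction: its left half is the 3′-terminal
subsequence of the upstream part, its right half the 5′-initial
subsequence of the downstream part. Each half grows from 15 nt (a floor
kept for annealing specificity) until its Tm reaches the 70 °C assembly
target, capped at 60 nt; the stored sequence is the sense-strand junction
context (left + right), and `order_sequence()` returns its reverse
complement — the strand actually synthesized, which anneals across both
single-stranded part termini. Shortest-qualifying-length tie-breaking
makes the oligo a pure function of the junction context, which is also the
deduplication key: a junction shared by several constructs is pooled
once per library. A circular n-part record yields exactly n oligos
(closure junction included); one oligo per junction is used uniformly —
whether vector–insert junctions warrant a second bridge is left to the
user, as nothing in the model distinguishes them.

Worklists are emitted in three stages — part dilution to the 75 nM
working concentration (4× stock assumed), per-construct oligo pooling,
and LCR setup where each destination well receives its part instances,
its oligo pool, and a master-mix top-up summing exactly to the 25 µL
reaction volume. Destinations are 96-well row-major (A1–H12, plates
added as needed); CSV is comma-separated, header row, UTF-8, LF. The
only randomized element is the analytics injection order, a permutation
drawn from the explicit seed; everything else is deterministic, so equal
seeds give byte-identical files.

## Effect model

Replicate-level titers are fitted by OLS with main effects only:

log₁₀(y) = μ + Σ_f β_f(x_f) + ε

Categorical factors use sum-to-zero contrasts (effects per factor sum to
zero); ordinal factors enter as integer ranks, so their coefficient is a
per-rank-unit slope whose sign is the direction of effect; gene order
enters as a categorical factor over the orderings present in the library
(for an OA library, the four Latin-square rows) — how gene order is best
parameterized is genuinely open, and this is the least-structured choice.
Each factor's p-value is the F-test of zero effect from the drop-one
nested comparison (equivalent to type-II ANOVA for a main-effects model;
the implementation is plain numpy least squares and is pinned in the
tests both to an explicit normal-equations computation and to
statsmodels' `anova_lm`). Raw p-values are reported, no multiplicity
adjustment — factor *ranking*, not family-wise error, drives the rules.

The log₁₀ response reflects titers spanning orders of magnitude with
multiplicative factor action; identity is available as an option. An
offset of one tenth of the smallest positive titer is added **only when
non-positive titers occur** — an unconditional offset would bias the
noise-free case, which the tests require to be recovered exactly.
Factors constant within a library are reported with NaN statistics
(inestimable there) rather than raised, since a constrained round
legitimately fixes factors; a genuinely rank-deficient design raises an
error naming the aliased factors. Whether replicate-level or
construct-median responses should be fitted is unstated in the field's
practice; replicate-level is the default here (more residual df), medians
are used for construct summaries.

## Rule propagation

`propagate_rules` maps an effect table onto a candidate next-round space
through an explicit policy (α = 0.05 default): (a) every significant
ordinal factor is fixed at the extreme of the *candidate* menu in its
beneficial direction — deliberately allowing extrapolation beyond the
screened levels, e.g. to a high-copy ColE1 origin never present in round
1; (b) the most significant promoter factor loses its no-promoter level
and its gene is pinned to the operon front, directly downstream of a
promoter; (c) other promoter factors keep full menus; (d) genes flagged
non-limiting by an auxiliary indicator (not by the F-test — e.g. an
accumulated upstream intermediate shows the enzyme is not the bottleneck
even when its promoter tests significant) are pinned last with their
promoter fixed to none. For the flavonoid case this produces
1 × 2 × 3 × 3 × 1 × 2 = 36 designs. The mapping of the final "2" between
the two defensible encodings (CHI promoter menu of two vs. presence of a
promoter before the last gene) is configurable: both the gene-view policy
route and a slot-view constraint encoding are shipped and both reach 36.

## The synthetic generator

`simulate_titers` draws titer = 10^(baseline + Σ effects + N(0, σ)) per
replicate — exactly the model the Learn stage assumes, with log-normal
noise as the single noise assumption (positivity plus the observed
orders-of-magnitude spread). Defaults for the flavonoid ground truth:
baseline −1.9 log₁₀ mg L⁻¹, copy-number effects −0.45/0/+0.9 for
pSC101/p15a/ColE1, promoter effects ordered CHI > CHS > 4CL ≫ PAL ≈ 0,
σ = 0.2, 3 replicates — chosen once to place round-1 titers in the
10⁻³–10⁻¹ mg L⁻¹ decade with the copy-number and CHI-promoter effects
dominant. Random parts are uniform sequences at a requested GC (exact to
the nearest base); because roughly 8% of uniform 60-nt termini at GC 0.5
cannot reach the 70 °C bridge target, the generator emulates the upstream
parts-design step by resampling until both terminal windows support a
bridge half (`junction_tm=None` disables the screen, producing the
adversarial parts used to exercise the planner's error path).

What the simulator does *not* emulate — and therefore what passing tests
cannot show about real screens: assembly and cloning failures, batch and
position effects, heteroscedastic or non-log-normal measurement error,
factor interactions and epistasis, intermediate-metabolite dynamics, and
any mechanistic link between sequence and expression. Conclusions about
the statistical machinery (calibration, power, rule propagation) transfer;
conclusions about biology do not.

## Problem sizes and determinism

The shipped simulation suites use 500 null screens for type-I
calibration, 200 screens for power and factor-ranking checks, and 200
end-to-end DBTL cycles — sizes at which the binomial noise on the
estimated rates is a fraction of the margins being asserted, while the
whole suite stays desk-scale. Every stochastic path flows from one
explicit seed (numpy `default_rng`; child seeds drawn below 2³¹), and the
end-to-end demo is byte-reproducible, which the tests enforce with a
directory-tree comparison.

## Known limitations

- Only the 16-run GF(4) array is constructed; other run sizes require the
  fractional-factorial route or an external catalog (out of scope).
- The OA gene-order column assumes at most four genes (one Latin-square
  row per column level).
- LCR bridge design treats each junction independently; it does not check
  cross-hybridization between bridges or repeated junction contexts
  within one construct.
- The Learn stage fits main effects only; interactions are aliased into
  residual by design of the strength-2 array.
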