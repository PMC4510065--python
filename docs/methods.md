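# Methods

## Model

`coalgrow` implements the standard (Kingman) coalescent for a sample of n
alleles from a constant-size, panmictic, neutrally evolving population,
with infinite-sites mutation. Looking backwards in time, while i lineages
remain ancestral to the sample the waiting time to the next coalescence is
exponential and an unordered pair of lineages is chosen uniformly to merge;
mutations fall on the genealogy as a Poisson process along branches.

**Units.** All times are in coalescent units of 4N generations, so the
epoch with i lineages has mean 1/(i(i−1)), E(t_MRCA) = (n−1)/n, and the
per-lineage mutation rate per unit time equals θ = 4Nu. N and u never
appear separately anywhere in the package; `TheoryTable.to_generations`
rescales time quantities by a user-supplied 4N when generations are wanted.
With this convention every closed form is parameter-free except for θ.

**Infinite sites.** Each mutation gets a fresh site position drawn uniformly
on [0, 1). Position collisions are probability-zero events and are not
handled. A mutation's size (derived-allele count) is never stored; it is
recomputed from the current tree as the number of tips below its branch,
which is what makes the growth bookkeeping exact by construction rather
than by careful state updates.

## Tip-extension growth

`grow_tree` converts an n-sample mutated genealogy into an (n+1)-sample one:

1. a uniformly random tip (the *-tip) becomes an internal node with two
   zero-length children;
2. all n+1 tips are extended downward by a shared increment e drawn
   exponential with mean 1/(n(n+1)) — the distribution of t_{n+1};
3. each of the n+1 extension segments receives Poisson(θ·e) new mutations,
   independently, with heights uniform on the segment; all are singletons;
4. the tree is re-normalized so tips sit at height 0 again (all old heights
   shift up by e), keeping growth composable and the ultrametric invariant.

This is deliberately *not* implemented as "sample an (n+1)-th lineage and
let it coalesce into the tree" — that is a different construction, and the
test suite checks the one implemented here against direct simulation
distributionally (`run_equivalence_experiment`).

Draw order per step is fixed (star tip, extension length, per-segment
mutation counts in new-tip order, then heights and positions) so a step is
reproducible from its stream. `grow_tree` also accepts an explicit
`star_tip` for audits and fixtures; the uniform draw is what realizes the
coalescent distribution and is the default.

**Labels.** Tip labels are 1-based integers rendered `t1..tn`. When a tip
is split its label is retired and its two children receive the two smallest
unused labels (max+1, max+2), recorded in the `StarRecord`; labels are
therefore unique across the life of a grown tree and never silently reused.

**Star bookkeeping.** The `StarRecord` of each step stores the per-size
counts s_{i,*} of mutations on the *-tip's root path, the realized
extension length and the number of new extension mutations.
`check_recurrence` then verifies, with zero tolerance,

    s_i^(n+1) = s_i^(n) − s_{i,*} + s_{i−1,*}   (i = 2..n, s_n := 0)
    s_1^(n+1) = s_1^(n) − s_{1,*} + (realized extension-mutation count)

on the actual spectra. These identities hold deterministically; any failure
is treated as an internal bug (`ConsistencyError`), never as noise.

## Analytic side

`coalgrow.theory` evaluates the closed forms directly (harmonic sums by
ascending direct summation — ample precision at these scales).
`expected_sfs_by_induction` instead *re-executes* the induction numerically:
starting from the n = 2 base case E(s_1) = θ, each step applies only the
star-mutation flow, E(s_{i,*}) = (i/n)·E(s_i), and recovers the singleton
class by subtracting the i ≥ 2 classes from E(S). That this lands on θ/i to
machine precision for n up to 100 is asserted in the test suite; the
cancellation is observed, not assumed.

## Monte-Carlo harness

`coalgrow.verify` distinguishes two kinds of check:

* **exact identities** (SFS conservation, t_MRCA = Σ t_i, the growth
  recurrence) asserted on every replicate with zero tolerance;
* **stochastic checks**: Monte-Carlo means with standard errors
  (sample SD/√R) and z-scores against the closed forms.

The default z threshold is 4. A report carries at most a few dozen
simultaneous z-tests, so under the null the familywise false-alarm
probability is well below 1%; the report exposes the exceedance count
rather than collapsing on a single borderline value, and the threshold is
configurable. Two-sample comparisons (direct vs grown arm) use a
pooled-variance z on means. Degenerate statistics (zero variance, e.g.
everything at θ = 0) pass only on exact equality.

Each replicate uses an independently seeded substream spawned from
(seed, replicate index) via numpy's `SeedSequence`, so reports are
bit-reproducible given (parameters, seed) and independent of execution
order. Experiments require R ≥ 100 so that standard errors are meaningful.

**Problem sizes.** The shipped verification runs use n = 10 with 10^5
replicates for the direct checks, 10^4 replicates for the n = 2 → 10 growth
audit (8 × 10^4 exactly-checked growth steps), 10^5 per arm for the n = 6
equivalence comparison, and 10^5 replicates for the n = 3 hand-oracle
check — sizes at which each 4-SE band is a few percent of the target value
and the whole batch completes in a few minutes on one CPU.

## Numerical and design choices

* Pair choice at a coalescence is uniform over unordered pairs by index;
  the draw order (interval first, then pair) is fixed for reproducibility.
* Newick output carries 6-decimal branch lengths. On input, read through
  dendropy, trees must be strictly binary and ultrametric; the allowed
  tip-depth deviation scales as 1e-6 per edge on the root path, exactly the
  accumulation bound of 6-decimal rounding, so write∘read round-trips are
  stable while genuinely non-ultrametric input is rejected with the
  offending tip named.
* The ms-style haplotype block orders sites by position and rows by sample
  label; column sums equal mutation sizes by construction.
* θ = 0 is allowed everywhere (mutation-free trees for topology-only
  work); n = 2 is the minimum sample size; growth refuses trees whose tips
  are not at height 0 (`InvalidStateError`) rather than guessing a
  normalization.
* Mutations are tagged with the growth step that created them (0 for the
  initial simulation), so audits never need geometric inference.

## What the tests do and do not show

The simulator and the growth construction are verified against each other,
against the closed forms, and against msprime as an independent
implementation of the same limit process. All of it lives strictly inside
the standard neutral model: no recombination, migration, selection,
population-size change, or multiple mergers, and no finite-N Wright–Fisher
comparison — the coalescent limit is treated as the model itself, and the
closed forms are limit statements for large N and moderate n. Estimation of
θ from data is out of scope. Passing tests certify the mathematics of this
model and the correctness of this implementation, not the fit of the model
to any real data set.
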