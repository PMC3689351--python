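# Methods

`mtprov` implements an mtDNA-based provenance pipeline for species in
which maternally inherited markers disperse far less than nuclear ones.
In African elephants, females are matrilocal — they stay with their natal
herd — so mitochondrial haplotypes are tied to the herd's range while
male dispersal homogenizes nuclear variation.  The two marker classes
therefore carry nearly independent geographic signals, and combining
them ("triangulation") can confirm or rule out a nuclear-based
assignment of a sample such as confiscated ivory.

## Haplotype collapsing

A haplotype is a distinct aligned sequence; individuals carrying the
same sequence collapse to one haplotype.  Identity is decided on the
alignment's *variable columns*: a column is variable iff at least two
distinct states among `{A, C, G, T, -}` occur there.  The gap character
is a fifth state (indels distinguish haplotypes; aligned input lengths
that differ by a few bases imply exactly such indels), and `N` is
missing data that never creates variability.  Two sequences differing
only at invariant columns can differ only by `N`-versus-consensus, so
representative haplotype sequences are emitted full length with `N` at
invariant columns filled by the column consensus.

Missing data at variable columns is handled by an explicit dual-mode
policy.  Under `strict`, such sequences are excluded and reported; under
`resolve` (the default) a sequence is merged into an existing haplotype
iff exactly one haplotype matches all of its non-`N` columns, otherwise
excluded.  The default is `resolve` because partial sequences (e.g. a
fragment missing its 3′ end) remain usable for subclade assignment, but
haplotype identity requires an explicit merging rule; the rule is
deliberately conservative (a unique match, never a guess).  Haplotype
ids are assigned deterministically — descending carrier count, then
lexicographic sequence — so all downstream outputs diff stably.

## Diagnostic-site key

The classifier is a two-level flowchart.  Level one assigns the F or S
clade by majority over the usable *fixed* clade-level sites; ties or
zero usable sites abstain and stop.  Level two, within the assigned
clade, requires all usable fixed subclade sites to agree; contradictory
fixed sites declare a `conflict`, and when no fixed site is usable the
non-fixed (subclade-associated but not exception-free) sites vote, with
a strict plurality required.  A site is *fixed* for a split when every
child group is monomorphic at that column in the training data; a
single within-group exception demotes the site to voting-only.  All
failure modes are assignment states, not errors: in a forensic setting,
abstention is always preferred to a false assignment.

The key is a first-class, serializable artifact (JSON/TSV) derived from
labeled training haplotypes with `derive_key` rather than a hard-coded
constant, because diagnostic columns are a property of the reference
alignment in use.  Masking any single diagnostic column cannot flip an
assignment supported by two or more fixed sites; it can only degrade it
to `unassigned`.

## Geographic specificity

For each haplotype, the *spread* is the number of geographic units
(localities or countries) where it is observed.  The specificity report
gives, for each spread value k, the fraction of unique haplotypes and
the fraction of individuals carrying them; private (spread-1)
haplotypes are the strongest provenance evidence.  Individuals excluded
at collapsing are excluded from all denominators and counted
separately.  Internally all fractions are kept at full precision;
rendered percentages round half away from zero.

## Haplotype F_ST and permutation test

Differentiation between two localities uses mean pairwise distances
among individuals,

    F_ST = (d_b − (d_w(A) + d_w(B))/2) / d_b,

with haplotype identity (0/1) as the default distance — the
"conventional", frequency-based F_ST — because the quantity of interest
is differences in haplotype frequencies; a sequence-mismatch (Hamming)
distance is available behind a flag.  `d_b = 0` defines F_ST = 0, and
negative estimates are reported as computed, never clamped.

Significance comes from pooling the two units' individuals and
re-partitioning them at random into the original sizes (default 10 000
permutations).  The p-value uses the add-one estimator
`(1 + #{F_ST* ≥ F_ST}) / (1 + N)`, which is a valid permutation p-value
and never exactly zero; its resolution is 1/(N+1).  The test
canonicalizes the unit order internally so p is invariant to label
swaps, and the all-pairs matrix derives per-pair sub-seeds
deterministically from the master seed and the sorted pair, so any
single pair can be reproduced in isolation.  No multiple-testing
correction is applied by default (the significance threshold and a
Bonferroni option are caller-configurable).  The permutation engine
evaluates all permutations of a pair as one vectorized batch, which is
what makes matrix-scale testing and calibration studies cheap.

## Median-joining networks

The network construction follows the median-joining algorithm of
Bandelt, Forster & Röhl (1999), re-implemented from the method
description.  Haplotypes are reduced to their variable columns
(sequences with `N` at a variable site are rejected — medians over
missing states are ill-defined, so the collapsing policy must exclude
or resolve them first).  Each round builds the ε-relaxed minimum
spanning network: an edge is admitted iff its length is within ε of the
bottleneck (minimax-path) cost of connecting its endpoints, which for
ε = 0 yields the union of all minimum spanning trees.  For every
connected triple (two links sharing a node) the majority-consensus
median is computed — on three-way ties each parental state is kept,
branching into multiple candidates — and all new medians whose triple
connection cost λ is within ε of the round minimum are added as
frequency-0 nodes.  Obsolete medians are pruned each round and at the
end: a median is removed when its removal lowers the minimum-spanning
cost of the node set, or keeps it unchanged while the median has degree
≤ 2.  ε defaults to 0 (the customary default; the analyses this package
reproduces state no non-default setting), and character weights are
uniform.

The `connection_cost` of the result is the minimum spanning length over
the final node set.  On instances generated by mutation accumulation
along a genealogy — including recurrent mutation — this cost matched an
exhaustive Steiner-minimal-tree search (Dreyfus–Wagner over the full
state lattice) on 4 000/4 000 random instances with ≤ 5 haplotypes over
≤ 6 sites.  On *uniformly random* state vectors, which carry no
genealogical signal and maximal homoplasy, the heuristic exceeds the
optimum on roughly 0.25% of such instances regardless of ε; this is a
known property of median-joining and the reason the optimality check is
run on genealogy-derived instances.  No claim is made that a
control-region-only network recapitulates deep clade relationships;
fast-evolving segments are unreliable for that purpose.

## Triangulation

Given per-sample nuclear assignments (true locality vs assigned
locality), each record is categorized in priority order:
`nuclear_correct` (localities agree); `mtdna_precludes` (the two
localities share zero haplotypes, so sequencing the sample would have
ruled out the wrong locality); `mtdna_distinguishes` (haplotypes are
shared but the pair's permutation p < α, so haplotype frequencies could
still separate them); else `unresolved`.  α defaults to 0.05 on raw
permutation p-values.  The improvement count is the number of
mis-assignments falling in the two mtDNA-informative categories.

`batch_frequency_support` extends the idea to batches (seizures often
contain many samples from one source): each candidate unit receives the
log-product over batch samples of the add-one-smoothed haplotype
frequency `(n_unit,h + 1) / (n_unit + H)`, with `H` the global
haplotype inventory size, plus a flag when the batch contains a
haplotype private to the unit.  The likelihood form and smoothing are
this package's own construction, motivated by, but not specified in,
the underlying study design.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at the scale
of a continental voucher survey.  Defaults: a 4 258-column alignment;
two clades split 5 + 3 into eight subclades; 22 two-letter localities
(one subclade each, cycled, so every subclade spans ≥ 2 localities),
grouped two per country; 30 samples and 5 haplotype-pool slots per
locality; private-haplotype fraction 0.72; 4 extra mutations per
haplotype; geometric within-locality frequency skew with ratio 0.5
(a common-plus-rare mix); no missing data unless requested; nuclear
mis-assignment rate 0.45, independent of mtDNA subclade.

Mutations are infinite-sites: every mutation hits a previously unused
column, so the planted diagnostic sites are exception-free and the
generating key is exactly recoverable by `derive_key` (the generator
emits that key as ground truth).  Three fixed sites are planted per
internal branch (clade and subclade splits).  Privacy is decided per
pool slot: with probability `private_fraction` the slot's haplotype is
locality-exclusive; otherwise it is also injected into one partner
locality of the same subclade region, so every slot is a distinct
haplotype and the pool-level spread-1 fraction is exactly binomial in
the configured parameter.  All randomness derives from a single seed;
identical configurations produce byte-identical datasets.

What the generator does *not* emulate: coalescent genealogies within
subclades, recombination (absent in mtDNA anyway), homoplasy
(switchable only via the network stress tests), hybrid-zone localities
under the default map, haplotypes spanning more than two localities,
and within-country spatial autocorrelation (partner localities are
drawn within subclade regions, not within countries, so country-level
specificity roughly tracks locality-level specificity instead of
exceeding it as real surveys find).  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data misalignment, reticulation or numt artifacts.

## Problem sizes and numerical choices

The bundled checks run at sizes chosen to keep a laptop run
comfortable: the type-I calibration uses 500 null replicates of 20 + 20
individuals with 999 permutations (the 99% binomial envelope around
0.05 is the pass band); network optimality uses 200 instances against
the exhaustive oracle; recovery studies use 16-locality configurations
with a 1 500–2 000-column alignment.  The specificity-recovery study
deliberately runs in the estimator's convergence regime (80 samples per
locality, skew ratio 0.85): with the default steep skew, tail pool
haplotypes are rarely drawn, and a shared haplotype observed in only
one locality inflates the apparent private fraction — a sampling
property of real surveys too, worth remembering when interpreting
private-haplotype percentages.  Permutation comparisons use
`F_ST* ≥ F_ST − 1e-12` to guard against floating-point ties; Hamming
and MST computations are exact integer arithmetic.
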