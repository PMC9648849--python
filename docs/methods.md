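# Methods

This note documents the model implemented by `invwalk`, the numerical
choices behind it, and what the package's tests do and do not establish.

## Genomes and operators

A genotype is a binary sequence x ∈ {0,1}^N, N ≥ 2, standing in for a
double-stranded molecule whose two digital nucleotides are complementary
(x̄_i = 1 − x_i).  The chromosome is circular by default (indices modulo
N), optionally linear.  Loci are 1-based in all public interfaces and
converted centrally (`segment_indices`), since every formula users will
compare against is 1-based.

An inversion between loci i and j reverse-complements the forward
segment i, i+1, …, j: position t of the segment receives the complement
of the bit at the mirrored position.  It factors into two commuting
involutions, conjugation (complement the segment) and permutation
(reverse it), so the inversion is itself an involution.  With i = j it
is a single bit flip, i.e. a point mutation; hence every point mutant is
also an inversion mutant.  On circular genomes (i, j) and (j, i) denote
the two complementary arcs and are distinct operations, giving exactly
N² ordered-pair operations; linear genomes require i ≤ j (N(N+1)/2
operations) and reject i > j loudly rather than silently swapping.

Three combinatorial phenomena matter downstream and are kept explicit:

* **degenerate** inversions: distinct (i, j) yielding the same mutant
  (parallel edges of the mutation multigraph);
* **invariant** inversions: operations fixing the genome, possible only
  for even segment lengths (an odd segment always flips its middle
  locus) and exactly when the segment is anti-palindromic.  Averaged
  over all genomes their fraction is (1 − 2^(−⌊N/2⌋))/N, converging to
  1/N.  They are excluded from accessible-mutant sets but counted as
  self-loops and kept in roughness denominators;
* a mutant can differ from its origin at up to N loci, versus exactly 1
  for point mutations — the source of "jumps" across the landscape.

The exhaustive census enumerates all 2^N genomes (guarded by a
configurable cap, default N ≤ 20) and tallies the distinct-mutant count
D_ν(x); its maximum, N² − N + 1, is attained exactly by the two uniform
genomes.

## Graph objects

The mutation multigraph m(x) has one directed edge per operator
application (self-loops for invariant, parallel edges for degenerate
applications); its reduced simple graph M(x) is a star with D_ν(x)
leaves.  The mutational network M(X) is the union of the M(x) over the
genotype space: the Hamming graph H(N,2) for point mutations, a denser
graph for inversions (node degree = D_ν(x); mean degree ⟨κ⟩ > N).  The
fitness network orients edges strictly uphill in fitness, so it is
acyclic and its sinks are precisely the operator's local optima.  Ties
in fitness produce no edge; with continuous components they have
probability zero, but crafted equal values degrade gracefully (no edge,
no cycle).  The layered drawing assigns each node the earliest layer
with all predecessors strictly earlier (longest-path layering, via
topological generations).  Graphs are networkx objects with genome
bit-strings as nodes; GraphML export preserves the (i, j) labels and
Hamming-distance edge attributes.

## NK landscapes

f(x) = (1/N) Σ_i f_i(x_i, x_{i1}, …, x_{iK}), with each component
depending on its own locus plus K others — consecutive loci (modulo N)
in the adjacent model, or K distinct loci drawn uniformly from the other
N − 1 in the random model.  Whether random neighbourhoods should be
drawn with or without replacement is a modelling choice; we draw
without replacement ("K *other* loci", distinct), and the neighbourhood
draw is separately seeded so it is reproducible.

Component values are i.i.d. uniform on the half-open interval [0, 1),
realised by a counter-free keyed generator rather than stored tables:
each landscape draws random 64-bit words T[i, t, b] (component i, input
position t, bit value b) from a seeded PCG64; the component key is the
XOR of the selected words (tabulation hashing) and a splitmix64
finalizer maps it to a uniform deviate.  Consequences:

* evaluation is a pure function of (seed, component, substate) and
  works unchanged at K = 99, where explicit tables (N·2^(K+1) values)
  are impossible;
* the optional table backend simply memoises the same function for
  small K (auto-selected under a 2^22-value budget), so backends agree
  bit-for-bit;
* flipping locus j XORs a precomputed delta word into the key of every
  component reading j, making incremental evaluation exact (not
  approximate) and O(N) per flipped locus irrespective of K.  A full
  inversion scan evaluates all N² applications by vectorising over
  segment start for each length.

Marginal uniformity and independence were checked empirically (mean,
variance, E[max of pairs] = 2/3) and the analytical K = 0 diagnostics
hold: a single global optimum, and mean optimum fitness 2/3 (order
statistics of two uniforms), which the test-suite verifies over seeds.

## Adaptive walks (SSWM)

A walk starts from a uniform random genome, proposes operator
applications uniformly at random — (i, j) uniform over the N² ordered
pairs for circular inversions, over the allowed pairs for linear or
size-limited variants, uniform loci for point mutations — and accepts
iff strictly fitter.  Invariant inversions are proposable but never
acceptable (wasted proposals), and degenerate inversions bias proposals
toward their shared mutant; both are features of the operator model, so
proposals are uniform over *applications*, not distinct mutants.

Termination must certify that **all** accessible mutants are strictly
less fit.  Random proposals alone cannot certify this in finite time,
so each step tries a batch of random proposals and, if none is
accepted, scans every application exhaustively.  If the scan finds no
strictly fitter mutant the walk stops, certified; otherwise one of the
fitter applications is chosen uniformly at random.  Conditioned on
eventual acceptance, a uniform random proposal *is* uniform over the
fitter applications, so the fallback is distributionally identical to
continuing rejection sampling — an exactness argument, not an
approximation.  The batch size (default: the number of applications)
affects speed only.

Experiments are paired: replicate r of condition (K, model) derives a
landscape seed and a start genome from (master seed, model, K, r), both
shared by the point and inversion arms; walk randomness is per-arm.
Start genomes are redrawn per (K, replicate) rather than recycled
across K.  Reported are the mean final fitness ⟨f_ν⟩_K, its standard
error across replicates, and Δf_K = ⟨f_I⟩_K − ⟨f_P⟩_K.  The reference
experiment size is N = 100 with n = 100 replicates per condition;
shape and supplementary tests (size-limit s, linear chromosomes) run at
N = 20 with n = 50, sizes chosen so the full suite exercises every
pathway at meaningful statistical resolution.

At K = 0 the landscape has a single peak and inversion-certified optima
are also point-certified, so both arms end at the same global optimum
and the paired Δf is exactly zero — a strong internal consistency check
used in the tests.

## Local roughness

ξ_ν(x) is the root-mean-square fitness change over *all* operator
applications at x — the edge set of the mutation multigraph, so the
denominator is N² for circular inversions and N for point mutations,
and invariant inversions contribute zero terms while remaining counted.
This literal multigraph convention matters: variants that average over
distinct mutants give slightly different values, and the invariant-
inversion padding implies that at K = N − 1 (where all mutants have
independent fitness) inversion roughness is a factor ≈ √(1 − 1/N)
*below* point roughness, while at every smaller K it is markedly above
it, already at K = 0.  The tests treat the K = N − 1 comparison as an
equality within sampling error and require strict excess elsewhere.

Landscape averages draw n_genomes uniform random genomes (default 10)
per landscape instance (default 100 instances) — the genotype space
cannot be enumerated at realistic N, and uniform sampling is the
neutral choice absent a canonical alternative.  Instances and sample
genomes are shared across operators so contrasts are paired; standard
errors are across instances.

## Synthetic data and scope

All inputs are generated: genomes are uniform random bit strings (or
exhaustive enumerations at small N) and landscapes are the seeded NK
construction above.  The generator realises exactly the model's stated
conditions — binary alphabet, constant length, uniform components —
and none of the complications of real sequence evolution: no 4-letter
alphabet (where inversions conserve the AT/GC ratio and fragment the
mutational network), no coding structure, indels, duplications,
translocations or recombination, no population dynamics beyond SSWM,
and a static environment.  Passing tests therefore validate the
operator combinatorics and the landscape/walk machinery, not any claim
about real genomes.

## Known limitations

* Exhaustive constructions (census, networks, certification) scale as
  2^N or N² per genotype; the default caps make misuse loud.
* Mean-fitness and roughness comparisons are Monte-Carlo estimates;
  tests use 3-standard-error bands (√2-inflated when comparing against
  an external value that is itself an n = 100 estimate).
* The keyed generator's component values are pseudo-random functions of
  the seed; different seeds give independent landscapes, but values are
  reproducible only through the package's own keying scheme (the JSON
  landscape spec records N, K, model, seed, backend for replay).
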