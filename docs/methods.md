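# Methods

## The signature index

Let a community be an ordered list of reference genomes g₁ … g_G and let
*F* be an array of *m* signed entries, initially zero, with a family of
*n* seeded hash functions h₁ … h_n mapping a k-mer to entries of *F*.
Every k-mer x of genome g is hashed to the entries h₁(x) … h_n(x).
During construction each entry takes one of three values: 0 (never
touched), −1 (dirty), or a genome id.

A k-mer x of genome g is a **signature** of g when no k-mer of any other
genome in the community shares any of x's n hash values. Note this is a
property of hash footprints, not of sequences alone: a k-mer whose
sequence is unique to g can still fail to be a signature through hash
collisions, and the set of signatures depends on m, n and the seeds.

### Construction

Genomes are processed sequentially in recorded order. For each k-mer,
the n entries are read; if any holds a value outside {0, own id} the
k-mer is marked non-unique and **all n of its entries are set to −1**,
otherwise all are stamped with the genome id. The whole sweep is run
twice (the "two-phase" build): after the first pass, entries stamped by
early genomes may mark k-mers that later turned out to collide, and the
second pass re-examines every genome against the fully populated array
and dirties those stale marks.

A k-mer lookup aggregates its n entries as: any 0 → *absent* (a stored
signature always stamped all n entries, so absence is definitive — the
Bloom-filter no-false-negative property); all equal to the same positive
id → that genome; anything else → *dirty*. The aggregation rule is ours
to choose (only the entry semantics are fixed by the construction); the
unanimous rule is the one consistent with the signature definition.

### What the construction guarantees — and what it does not

These properties are verified by the test suite on seeded random
communities (5 × 2 kb, m = 2¹⁶ … 2²⁰, n ∈ {1,2,3}, k = 31) against a
brute-force oracle that enumerates every genome's full hash footprint:

- **Soundness is exact.** After a two-phase build, every k-mer that
  classifies to genome g is a true signature of g. Equivalently: the
  index never attributes a k-mer to the wrong genome, and false
  presence calls on error-free reads are impossible. The proof sketch:
  an entry shared with a foreign k-mer is marked non-zero by the foreign
  genome's pass and can never return to the home genome's id, because
  any home k-mer that would re-stamp it must first pass the uniqueness
  check against that very entry.
- **Completeness is exact only for n = 1.** For n ≥ 2, a true signature
  x can be lost: if a *non-unique* k-mer y **of the same genome** shares
  one of x's entries, y's marking as non-unique dirties all of y's
  entries, including the shared one, and x then classifies as dirty.
  This "dirty chaining" affects roughly 2–5% of signatures at the test
  load factors and its victims always degrade to dirty — never to
  absent, never to a foreign genome. With n = 1 chaining cannot occur
  (a same-genome k-mer sharing x's only entry has the same footprint
  status as x), and classification equals the oracle exactly.
- **One-phase builds.** After a single pass, classification soundness
  already holds for *every* genome, and the first-processed genome's
  classifications equal the oracle exactly. What the second pass repairs
  is at the entry level: earlier genomes retain entries holding their id
  that belong only to non-unique k-mers (stale stamps from before the
  colliding genome was seen). Such entries cannot produce a wrong
  *classification* under the unanimous rule, but they waste index
  capacity and break the entry-value invariant; the second pass dirties
  all of them (verified: 100% removed on every tested instance).
- **Order sensitivity.** Because chaining depends on which dirty marks
  are present when a genome is swept, per-k-mer classifications after a
  two-phase build can differ on a handful of k-mers when the genome
  order is permuted (only between "own id" and "dirty", by soundness).
  At n = 1 classifications are exactly order-invariant.

### Signature thinning (ω)

An optional pass over each genome's kept signature positions (run per
contig, inside the second phase) selects the first position and then
every position more than ω beyond the last selected one; dropped
positions have their entries dirtied, selected positions are re-stamped
with the genome id afterwards. The dirty-then-restamp order is applied
literally as specified by the construction, with a documented
consequence: an entry shared between a dropped and a kept k-mer ends up
re-stamped, so a dropped k-mer whose footprint coincides with kept ones
can still classify to the genome. Selected signatures always classify to
their genome on single-contig genomes (their entries are foreign-free by
soundness and nothing later overwrites them); on multi-contig genomes a
later contig's sweep can in principle chain-dirty an earlier contig's
kept signature. ω = 0 disables thinning entirely; the command-line
default is ω = k, the smallest spacing at which kept signatures cannot
overlap each other.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| m | index entries | required | entries, not bytes; `entries_for_bytes("8GB", width)` converts |
| n | hash functions | 2 | more hashes → fewer, more specific signatures; `optimal_num_hashes(m, elements)` gives the false-positive-minimizing (m/elements)·ln 2 |
| k | k-mer length | 31 | 1–32; k-mers are 2-bit packed into one 64-bit word |
| phases | sweeps over the community | 2 | 1-phase builds are cheaper but keep stale entry marks |
| ω | thinning spacing (bp) | 0 in the library, k in the CLI | 0 disables |
| entry width | bits per entry | 32 | 16-bit mode halves memory for G ≤ 32,767 |
| canonical | strand-insensitive k-mers | on | without it, reverse-strand reads systematically miss |
| sample_fraction | fraction of reads queried | 1.0 | seeded Bernoulli per read |
| min_reads | reads required to call a genome present | 1 | the permissive regime: one read suffices |

Hashing is a seeded splitmix64-style finalizer applied to the 2-bit
encoding of the (canonical) k-mer, reduced mod m; the n seeds are
derived from one master seed recorded in the index header, so an index
file fully determines its hash family. Determinism across runs and
platforms is required for serialization and is property-tested
(scalar and vectorized paths agree bit-for-bit; occupancy of 2¹⁶ buckets
by 10⁵ random k-mers passes a chi-square uniformity check at the 99.9%
band).

## Read assignment

For a read, V is the multiset of its k-mers' calls in scan order.
Majority assigns the genome holding strictly more than 50% **of the
positive calls** — thinning makes positives deliberately sparse, so a
denominator over all k-mers would discard nearly every read; exact ties
discard. First-hit stops at the first positive call. One-or-nothing
requires a single distinct positive genome, with multiplicity
irrelevant. All strategies discard a read with no positive call, and
reads shorter than k are discarded (counted in the query log). Algebra
verified by property tests: a one-or-nothing assignment is always the
majority assignment; when V has one distinct positive genome all three
strategies agree; sequences exist on which the three strategies return
three different verdicts.

Per-read classification is a pure function of (index, read), so
multi-threaded querying is a contract, not a correctness concern: the
thread pool yields results in input order and is asserted identical to
a serial run. Paired-end mates are treated as independent reads.

## Synthetic data

The community generator emulates related strains by copying a chosen
fraction of each genome, in 300 bp blocks, from a shared pool sequence
(pool blocks taken in cycling order into non-overlapping destination
slots, so the shared k-mer fraction tracks the requested fraction
directly); the remainder is i.i.d. uniform over {A,C,G,T}. The read
simulator draws uniformly positioned, uniformly stranded reads to a
requested coverage (ceil(coverage·L/read_length) reads per genome) and
applies independent per-base substitutions; no indels, no quality-score
model, no chimeras, and no abundance skew beyond per-genome coverage.
Consequences for interpretation: passing tests show the index and
strategies behave correctly for substitution-type divergence between
sample and reference, but say nothing about indel-rich divergence,
low-complexity or repeat-heavy genomes (real genomes share far more
k-mer content than i.i.d. sequence), or base-quality-aware filtering.

The standard desk-scale study conditions used by the tests and the
acceptance script: oracle checks on 5 genomes × 2 kb (small enough to
enumerate footprints exactly); recovery experiments on 20 genomes ×
10 kb at 2× coverage with 100 bp reads (a mid-range short-read length),
m = 2²⁰, n = 2, k = 31, error-free and at a 2% substitution rate —
at these sizes a full build-query-evaluate cycle takes a few seconds.

## Numerical and design choices

- k ≤ 32 so a k-mer packs into one uint64; lexicographic order of
  k-mer strings equals numeric order of packed codes, so canonical
  selection is a single integer min.
- Windows containing any non-ACGT character are skipped entirely;
  ambiguity codes cannot be hashed consistently.
- Positions are 0-based contig-local k-mer starts; thinning never spans
  a contig junction.
- Genome ids are assigned 1..G from input order and recorded in the
  index header, because one-phase semantics depend on processing order.
- The index file is little-endian with a CRC-32 over the whole payload;
  read(write(x)) is asserted bit-exact including seeds, and corrupt
  magic / truncation / bit flips raise distinct errors.
- Duplicate k-mers within a genome are processed literally as the
  pseudocode dictates (each occurrence is tested and stamped; thinning
  re-selects duplicates beyond ω) rather than de-duplicated.

## Known limitations

- Signature completeness degrades with n ≥ 2 through dirty chaining
  (above); the loss is a few percent at moderate load factors and only
  ever produces dirty calls, but per-genome signature counts are
  therefore lower bounds on the oracle-ideal counts.
- Presence calling with min_reads = 1 maximizes recall at the cost of
  precision under read errors; the threshold is exposed but no
  error-model-driven calibration is provided.
- No taxonomy awareness, abundance estimation, or LCA-style rollup:
  the unit of detection is the reference genome.
- The index is static: no insertion or deletion after build.
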