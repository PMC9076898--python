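# Methods

## Species as environment-count vectors

A proteome is encoded by counting, for every target residue *X* of the 20
standard amino acids, how often each residue *i* occurs at each signed
offset *j* ∈ {−r…−1, +1…+r} from an occurrence of *X*.  The flattened
vector has dimension 800·r under a fixed canonical ordering: target
outermost (A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P, S, T, W, Y, V),
neighbor next, offset innermost (−r…−1 then +1…+r).  All implemented
metrics are invariant to coordinate permutations, so the ordering affects
only serialization; fixing it makes vector dumps diffable across
implementations.

Conventions that the counting obeys:

* **Termini truncate.**  Offsets falling outside a sequence contribute
  nothing; no padding characters are introduced, and sequences are hard
  boundaries (counting a proteome never equals counting the concatenation
  of its sequences).
* **Offset 0 is excluded** — the environment is the flanking window, not
  the target itself.
* **Placeholders occupy positions.**  Non-standard characters (B, Z, J,
  X, U, O, gaps) are kept in the sequence so the offsets of flanking
  standard residues are unchanged, but they are never counted as target
  or neighbor.  Deleting them instead would silently shift every
  neighborhood that straddles one.
* **Overlapping targets each count.**  A methionine inside another
  methionine's window is both a target and a neighbor.
* Counts are stored as 64-bit integers; whole-proteome inputs with tens
  of millions of residues are far from overflow.

Internally the per-species count is a single vectorized pass: sequences
are joined with runs of `radius` placeholder positions (which reproduces
per-sequence counting exactly, since no window can bridge a separator)
and each of the 2r offsets becomes one 400-bin histogram of
(target, neighbor) code pairs.  A `vector_sum_check` report recomputes
the vector total with an independent position-by-position scan.

## Metrics

* **Cosine dissimilarity** d = −ln((1 + cos θ)/2) on the raw count
  vectors.  It deliberately violates the coincidence axiom — collinear
  vectors are at distance 0 regardless of magnitude — which is the right
  behaviour when proteome *size* (e.g. a genome duplication) should not
  register as divergence.  The cosine is clamped to [−1 + 10⁻¹², 1]
  before the logarithm so the function stays finite on antipodal inputs;
  for count vectors cos θ ≥ 0 anyway and the clamp is never active.
* **Jensen–Shannon divergence**: raw (not square-rooted), base-2
  logarithms, computed on sum-normalized vectors, hence bounded in
  [0, 1].  Base 2 with no square root is the common convention in the
  alignment-free literature; only symmetry, non-negativity and
  coincidence are asserted for it (the triangle inequality holds for its
  square root, which is not what is computed here).
* **Chebyshev** and the remaining registry entries (euclidean, manhattan,
  canberra, braycurtis, hellinger) operate on sum-normalized vectors:
  without normalization, absolute proteome size would dominate every
  norm-based metric, whereas the signal of interest is the preference
  profile.  The registry is a plain name→callable mapping so further
  metrics can be added.

Distance matrices are computed on the upper triangle in fixed (i < j)
order and mirrored, so symmetry is bit-exact.  Import/export is provided
as labeled TSV and PHYLIP square format (read tolerantly: rounding
asymmetries below 10⁻⁹ are symmetrized away).

## Neighbor joining

Standard Saitou–Nei agglomeration with the Studier–Keppler criterion
Q(i, j) = (N−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), canonical branch-length
formulas, and a final three-way join.  On additive matrices this is exact
(topology and branch lengths), which the tests exercise against random
binary trees.  Numerical/degenerate-input policies:

* **Ties** in Q (identical species produce them) are broken toward the
  smallest (i, j) in input order — determinism over an arbitrary choice.
* **Negative branch lengths**, possible on non-additive input, are by
  default clamped to zero with the deficit moved to the sibling edge
  (the usual convention); `negative_branches="keep"` disables this.
* A 2×2 matrix degenerates to a single edge; an all-zero matrix yields a
  resolved topology with all branch lengths 0.
* The dense O(N³) loop is deliberate: the method targets tens of taxa,
  where heuristic NJ variants buy nothing.

## Tree representation and Robinson–Foulds

Trees are unrooted; rooted Newick input is accepted and its basal
bifurcation collapsed (topology comparisons in this field are on
unrooted trees).  The Newick writer is canonical — the tree is anchored
at the internal node adjacent to the lexicographically smallest leaf,
children are ordered by the smallest leaf beneath them, and branch
lengths are printed with 10 significant digits — so equal topologies
serialize to identical bytes and round-trips preserve lengths to 10⁻⁹.

RF is the cardinality of the symmetric difference of the two split sets
(one nontrivial bipartition per internal edge, stored canonically as the
side containing the smallest leaf); nRF divides by |T₁| + |T₂|.
Multifurcating inputs are handled by counting only the internal edges
actually present.  Zero-length internal edges still contribute splits —
a resolved edge is a resolved edge — though `splits(..., collapse_below=ε)`
can discard them.  When both trees are stars the normalization is 0/0;
this returns 0 with a warning rather than raising.

## SVD k-mer comparator

Protein *k*-mer counts (default k = 4, windows containing placeholders
skipped, proteins shorter than k dropped) form a k-mer × protein matrix
A = UΣVᵀ.  Protein p's latent representation is row p of VΣ truncated to
⌈rank_fraction × rank⌉ components; a species is the L2-normalized sum of
its proteins' rows; species are compared by cosine dissimilarity and
joined by NJ.  Choices worth recording:

* `rank_fraction` defaults to 1.0 (no truncation).  At full rank the SVD
  is a pure change of basis, so species distances provably equal the
  direct pooled per-species k-mer cosine distances — the property the
  tests verify to 10⁻⁸.  Truncation is where the noise filtering of the
  latent-semantic approach lives, and is left to the caller.
* The SVD sign ambiguity is resolved by making the largest-magnitude
  component of each left singular vector positive, for bit-reproducible
  output.
* The dense SVD is adequate at mitogenome scale; whole-proteome inputs
  would want a sparse/truncated path, which is out of scope here.

## Synthetic proteome evolution

The generator exists so that every stage — I/O, encoding, metrics, NJ,
RF — can be exercised end-to-end against a known generating tree with no
external data.  Two designs:

**Orthologous.**  A root proteome (default 20 proteins × 400 residues,
root composition uniform on the 20 residues) is drawn i.i.d. and evolved
along the tree.  Each site evolves independently as a rate-1 exchange
process: over a branch of length b it experiences Poisson(b) replacement
events, each drawing the new residue from the root composition excluding
the current one.  Consequences: P(≥1 substitution over b) = 1 − e^(−b);
branch lengths are expected substitutions per site; and — because the
process is a proper continuous-time chain — the pairwise leaf kernel
depends only on path length, so expected divergence grows monotonically
along the tree.  (A single replacement opportunity per branch, an
alternative reading, is *not* a semigroup: the pair kernel then depends
on how a path splits into branches, and measured distances stop being
monotone in path length.  This was verified empirically on a star tree
with unequal tip lengths and is why the event-based process is used.)
The model is intentionally minimal — uniform exchange, no WAG/LG rates,
no indels, no domain structure, no rate heterogeneity — because the
artifact tests topology recovery, not biological realism; closed-form
checks (substitution fractions, kernel identities) stay available.

**Non-orthologous.**  Every species receives its own independently
generated protein set (default 180 × 400, mirroring a five-species
disjoint-sampling design); no sequence shares ancestry across species,
and cross-species duplicate strings are checked for (with ~10⁵²⁰
possible length-400 sequences they do not occur).  Lineage signal lives
only in first-order neighbor preferences: residues are emitted by a
Markov chain whose 20×20 conditional logits perform Brownian-style drift
along the tree (independent Gaussian increments per branch, standard
deviation = bias_strength × branch length).  At bias_strength 0 all
species draw from the same chain and no tree is recoverable (the null
the tests confirm); at bias 0.5 the dipeptide preferences alone recover
the generating topology.  The bias is first-order by design — the
minimal structure an environment-based method should detect — so radius
1 is the matched analysis radius and larger radii merely dilute.  How
much neighborhood-preference signal *real* non-orthologous protein sets
carry is an empirical question this generator does not answer; passing
these tests shows the pipeline detects such signal when present, not
that real proteomes provide this much of it.

**Seeding.**  A master seed plus stable string tags (crc32-keyed
`SeedSequence` substreams) drive every draw: one stream per branch
(keyed by the branch's descendant leaf set), one per species for
sequence emission.  Identical configs produce byte-identical FASTA
output; grafting a new species changes only the streams on its ancestral
path, and other species' emissions are untouched.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at the design scales above: 20 replicate
8-taxon orthologous datasets (20 proteins × 400 aa, branch lengths drawn
in 0.05–0.2 on a balanced topology) for median-nRF and rank-correlation
estimates, and 5-taxon non-orthologous datasets (180 × 400) at bias 0.5
with the median over five replicates reported.  Oracle-equivalence
checks use randomized proteomes of ≤5 sequences × ≤30 residues at r ≤ 3
and random trees of ≤12 leaves.  The whole suite and the acceptance
script each complete in seconds on a single CPU.

## Known limitations

* Real-data benchmark validation (mitogenome and whole-proteome
  datasets) requires the corresponding public downloads; the package
  ships no fetcher, and the two tests covering those benchmarks report
  failure until the data are placed under `data/`.
* The cosine-based dissimilarity is not a metric (by design) and NJ on
  non-additive matrices carries no optimality guarantee; no bootstrap or
  other support values are produced.
* The environment representation ignores position weighting and reduced
  alphabets; the simulator ignores indels and rate variation.  Both are
  deliberate scope boundaries, not oversights.
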