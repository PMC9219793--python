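# Methods

This note documents the models, the numerical choices and the design
decisions behind `selfsim`, and what the synthetic-data tests do and do not
establish about real data.

## Ancestral reconstruction (Mk(5) with gap as a state)

Each alignment column is an independent discrete character on a fixed
rooted tree whose branch lengths are expected substitutions per site.  The
substitution process is the symmetric k-state Markov (Mk) model with k = 5:
the four bases plus the alignment gap as an ordinary fifth state.  Coding
the gap as a substitutable state is the simplest treatment consistent with
reconstructing full-length chains in which a site may be absent in the
ancestor (rendered `N`); it is not an insertion/deletion model, and branch
lengths are taken as given — tree inference and branch-length optimisation
are out of scope.

With rate multiplier *r* (default 1, i.e. branch lengths are trusted as
given) the transition probabilities are

    p_stay(t)   = 1/5 + (4/5) exp(-(5/4) r t)
    p_change(t) = (1 - p_stay(t)) / 4

which satisfy p_stay + 4 p_change = 1 and approach the uniform 1/5 as
t → ∞.

Reconstruction is **marginal**, per site: an inside (pruning) pass computes
conditional likelihoods below every node, and an outside pass carries the
contribution of the rest of the tree, so the marginal at any node — root or
internal MRCA of named tips — is inside × outside under a uniform root
prior.  The outside recursion is equivalent to rerooting at the focal node
(the model is reversible with uniform stationary distribution) but avoids
mutating the tree.  The reported sequence is the per-site argmax; ties are
broken by the fixed state order A < U < G < C < gap, which makes
reconstruction deterministic (an all-unknown column yields the uniform
vector and the letter A).

Numerics: partial likelihood vectors are rescaled per node to a maximum of
1 per site, which keeps the computation in the linear domain without
underflow at the chain lengths involved (thousands of sites, tens to
hundreds of taxa); final vectors are normalised to sum to 1 and validated
to 1e-9.  Pruning is checked against a brute-force enumeration of all joint
internal-state assignments on trees of up to 4 tips at 1e-10.

Unknown tip states (`?`/`X`) contribute an all-ones partial.  A zero total
likelihood (possible only with degenerate inputs such as conflicting
zero-length branches) raises rather than silently renormalising.

## Repeat ("self-similarity") search

The three reconstructed chains are concatenated in 16S, 5S, 23S order.  Two
alphabet levels are supported: RY (A,G → R; U,C → Y — transitions are
invisible, so this level tolerates 4 Gyr of transition turnover) and AUGC
(identity, stricter).  A *fragment* is one occurrence of a k-mer whose
symbol arrangement occurs at least twice among the candidate windows;
windows containing `N` or crossing a molecule junction are never
candidates, because `N` is a reconstructed gap rather than a base and every
fragment must be attributable to a single molecule.  Type identifiers group
identical arrangements within one (level, k) and are shared across
molecules.

Overlap filtering removes redundant ("pseudo-positive") occurrences by a
greedy left-to-right scan in concatenation coordinates: a candidate is
discarded iff it overlaps an already-retained fragment by strictly more
than `threshold · k` nucleotides (default threshold 0.4; an overlap of
exactly 40% of k keeps both).  Keeping the leftmost of a conflicting pair
makes the result deterministic and independent of input order, since the
scan order is fixed.  A type whose occurrence count falls below 2 after
filtering is dropped entirely — it is no longer a repeat.

Length sweeps report, per k, the unfiltered occurrence and type counts, the
product k × n (flagged when it exceeds the concatenation length — a crude
redundancy indicator), and whether any repeat exists; the largest k with a
repeat is derived from the sweep.  A shared (k+1)-mer necessarily forces
its prefix and suffix k-mer pairs, which the suite asserts as a property.

The optional treatment intersection (keep focal-ancestor fragments whose
arrangement is also a repeat type in the archaeal and bacterial ancestor
sets) defaults to *off*: the source procedure's wording is ambiguous about
what the "three treatments" are, so the step is configurable and logged
rather than guessed.

## Conservation mapping

Fragments are projected onto extant species through pairwise global
alignments (affine gaps; the first gap residue costs `gap_open`, later ones
`gap_extend`; defaults 2 / −1 / −5 / −1 — a standard nucleotide scheme
tight enough to keep rRNA orthologous columns aligned).  Alignment is
delegated to Biopython's `PairwiseAligner`; optimal scores are verified in
the suite against an exhaustive enumeration of all gapped alignments on
short pairs.  Pre-aligned pairs are accepted as-is ('-' marks alignment
gaps; `N` stays a sequence state).

A coordinate map keeps one (source, target) position pair per alignment
column with no gap in either row; it is strictly monotone.  A fragment's
orthologous arrangement in a species is defined only when every fragment
position maps and the mapped span has length k (no deletion or insertion
inside the fragment); the species *matches* when that arrangement equals
the fragment's.  A kingdom matches when any of its supplied species does —
requiring all species would conflate within-kingdom divergence with loss.
Kingdoms with no supplied species are excluded from evaluation and the
profile is flagged partial, so missing data are visible rather than
silently counted in the denominator.  Tiers: `universal` at ≥ 5 matched
kingdoms, else `AB_conserved` when archaea and bacteria both match, else
`none`.  Universality does not imply AB-conservation by construction, and
the code asserts only the stated invariants.

## Enrichment test

The observed statistic is the number of unique catalogued functional
positions (distinct (molecule, position) pairs; a position listed under
several function categories counts once) covered by the union of fragment
intervals in the catalogue's species coordinates.  The null samples the
same number of positions uniformly **without replacement** from the
concatenated extant chains and recounts; the count is hypergeometric with
mean n·K/N, which the Monte-Carlo mean must approach (asserted within
3·sd/√reps; SciPy's hypergeometric distribution is the independent
cross-check, never the implementation).  At the study conditions
(N = 4566, K = 230, n = 805) the analytic mean is 40.55, rounding to 41.
The empirical p-value uses the add-one permutation estimator
(1 + #{null ≥ obs}) / (reps + 1), which cannot return zero.  The sampled
count n is derived from the fragment set's union span, never hard-coded.
The RNG is NumPy's default Generator; the seed is recorded in the result.

The bundled `ecoli_functional_sites.tsv` is a partial catalogue (the sites
known to fall inside the reported fragment set plus the GTPase-factor
contacts, compiled from ribosome structural literature); full reproduction
runs need the complete 230-position catalogue supplied by the user.

## Synthetic-data generators

The generators exist to give every pipeline stage inputs with known ground
truth:

- `simulate_mk_tips` evolves a root sequence down a tree by drawing each
  branch transition from the closed-form Mk(5) matrix (per-branch state
  changes are recorded, not the latent multiple-hit events).  Default study
  condition for recovery experiments: an 8-tip balanced tree of depth
  ≤ 0.1 expected substitutions/site, 1000–2000 sites — shallow enough that
  marginal reconstruction should recover ≥ 90% of root states, which the
  suite asserts.
- `plant_repeats` draws an iid background (default uniform A/U/G/C, no N;
  composition and N-fraction configurable to exercise the N-exclusion
  rules) and writes arrangements at declared coordinates; RY plants realize
  R as A/G and Y as U/C independently per occurrence.  With rejection
  enabled the background is redrawn (≤ 1000 attempts) until the search
  recovers exactly the planted truth at each planted (level, k), so the
  generator's rejection rule doubles as the test oracle.  Fixture
  sizes are chosen so that chance k-mer collisions are improbable (e.g.
  k = 15 at AUGC in a few hundred nucleotides); an iid background at RY
  level and full 4428-nt scale would carry hundreds of chance 15-mer
  repeats, so full-scale fixtures are only used without rejection to test
  coordinate bookkeeping.
- `mutate_variant` applies exact counts of transitions, transversions and
  single-base indels at distinct positions, returning the edit list;
  transitions leave the RY encoding unchanged by construction, which is the
  lever for testing RY-level tolerance.

What passing these tests shows — and does not.  The generators emulate the
*contracts* of real inputs (alphabets, coordinates, repeat structure,
conservation signals), not their biology: real rRNA evolves under strong
secondary-structure constraints, non-uniform composition, and
rate heterogeneity, and real alignments carry correlated gaps.  Green
synthetic tests therefore certify the machinery (coordinates, filtering,
likelihoods, sampling), not the biological conclusions drawn from any
particular empirical dataset.

## Problem sizes and defaults

Representative fragment lengths default to k = 11 (RY) and k = 6 (AUGC) in
the run configuration, the lengths at which the fragment sets remain
concise while covering the known functional-site classes.  The enrichment
null uses 10,000 repetitions (standard deviation of the mean ≈ 0.06 hits at
the study conditions, ample for a mean printed to integer precision).
Recovery experiments use 1000–2000 sites; oracle comparisons use trees of
≤ 4 tips and alignments of ≤ 8 nt where enumeration is exact.

## Known limitations

- No rate heterogeneity across sites, no partitioned or structure-aware
  models; the gap-as-state treatment ignores insertion/deletion dynamics.
- Repeat matching is exact (edit distance 0) and forward-strand only.
- The greedy overlap filter is order-deterministic but not globally
  optimal (it does not maximise retained count).
- The "overlapped or adjacent" percentage depends on an adjacency gap
  parameter (default 0 = abutting) for which no canonical definition
  exists; it is reported as a descriptive statistic only.
- The enrichment null is uniform over positions; it does not stratify by
  base composition or structural context.
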