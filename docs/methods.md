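# Methods

## The model

Let S be a DNA text of length n over {A, C, G, T}, terminated by a unique
sentinel `$` that is lexicographically smallest. Symbols are coded
`$=0, A=1, C=2, G=3, T=4`; the codes double as base-5 digits so that the
integer encoding used by Strategy 2 preserves character order. `N` is
normalized to `A` on input; any other character is rejected. Multi-record
FASTA inputs are concatenated with no separator symbol — record boundaries
are kept as metadata for coordinate reporting only. (A separator-free join
can create spurious matches across a record boundary; callers who care can
index records separately.)

A **k-ordered suffix array** SA' is a permutation of text positions such
that the first min(k, |suffix|) characters are non-decreasing along the
array; ties within equal k-prefixes are unconstrained. Where a normative
order is needed (strategy equivalence, serialization comparisons) the
package imposes the *stable rule*: ascending text position within each
equal-k-prefix group. The **Schindler transform** is the last column of
the rotation matrix sorted to depth k, `ST[i] = S[(SA'[i] + n − 1) mod n]`;
at unbounded k it is the BWT.

## Construction

1. **Typing.** Position i is S-type iff `S[i] < S[i+1]`, or
   `S[i] = S[i+1]` and i+1 is S-type; the sentinel is S-type. Implemented
   as a vectorized backward fill: positions where `S[i] ≠ S[i+1]` are
   decided locally, runs of equal characters inherit the nearest decision
   to their right. LMS positions are S-type positions with an L-type left
   neighbour (never position 0, always the sentinel).

2. **LMS k-order sort.**
   *Strategy 1* sorts LMS positions with the key
   (first-k characters, position). Because symbol codes are single bytes
   with the sentinel smallest, the key is a plain bytes slice and
   comparison is memcmp. The bucket-split variant partitions by a leading
   l-mer (default 10 characters) before sorting within buckets — an
   implementation split with identical output.

   *Strategy 2* compacts the text first. Each LMS substring (from one LMS
   position to the next, inclusive) is cut into ⌈L/l⌉ consecutive l-mers
   read from the original text starting at the LMS position; a short final
   l-mer is completed by the characters that follow (equivalently,
   prefixes of subsequent LMS substrings) and sentinel-padded past the
   text end. Each l-mer becomes one integer Σ digit(c)·5^(l−1−j). The
   concatenation is the *reduced reference*; the offset of each LMS suffix
   in it is recorded. Prefix doubling then ranks the reduced suffixes:
   initial ranks from single symbols; each round sorts the still-ambiguous
   positions by (rank[i], rank[i+h]) with out-of-range treated as smallest,
   refines ranks (a rank is the index of its group's first slot in global
   order, so refinement is monotone — groups only split), retires new
   singletons, and doubles h. Rounds stop when no ambiguity remains or,
   for bounded k, when h·l ≥ k — after at most ⌈log₂⌈k/l⌉⌉ + 1 rounds.
   The default segment length is l = 3; the base-5 encoding (sentinel
   included in the digit set) is what keeps chunks well defined near the
   text end.

   **Exactness pass.** Consecutive-substring chunking overlaps at LMS
   boundaries, so h symbols cover *at least* h·l characters of one
   suffix's stuttered rendering but the character coverage at a given
   symbol distance varies by position. Consequently the doubling order can
   be finer than the k-prefix partition (decided by characters past k) or,
   for segment lengths much larger than typical LMS gaps, coarser (rank
   ties spanning distinct k-prefixes). Cross-rank order is always
   consistent with true lexicographic order, so both defects are strictly
   local: a finalization step resolves residual rank-tie groups by direct
   k-prefix comparison and re-sorts maximal runs of equal k-prefixes by
   ascending position. This makes Strategy 2 output bit-identical to
   Strategy 1 under the stable rule while leaving the doubling machinery
   (and its round bound) untouched; at unbounded k all final ranks are
   distinct and the pass is skipped.

3. **Induced sort.** The ordered LMS positions are placed at the tails of
   their first-character buckets in reverse order; a left-to-right scan
   induces L-type predecessors into bucket heads; a right-to-left scan
   induces S-type predecessors into bucket tails, overwriting the
   provisional LMS placements. Each induced placement extends a decided
   prefix by one character, so a k-ordered LMS input yields a k-ordered
   array. Intra-group tie order of the final array is whatever induction
   yields; an optional stabilization pass (position-sort within
   equal-k-prefix groups) is provided for reproducible element-wise
   comparisons and is *not* applied by default.

## The index and its queries

The index stores the transform (one byte per symbol in container v1),
cumulative symbol counts C, occurrence checkpoints every
`checkpoint_stride` rows (default 64; occ(c, r) is a checkpoint plus a
bounded scan), and the value-sampled suffix array: a flag per row marking
`SA'[i] mod vd = 0`, plus the marked values in row order and a prefix-count
index mapping rows to sample slots. The full suffix array is not retained.
Subscript sampling (`sd`) is carried as metadata only: walking LF until a
sampled row is hit requires LF validity beyond the pattern's context,
which a k-ordered index does not guarantee, so locate is built entirely on
value sampling.

**count(P)** is the right-to-left fold of LF extension steps
`[b, e) → [C[c] + occ(c, b), C[c] + occ(c, e))`, valid while the extended
length stays within k; patterns longer than k are rejected. The empty
pattern maps to the full range by convention.

**locate(P)** requires |P| ≤ k − vd + 1 (each occurrence q is reached
through the left extension s = S[q−d .. q) with d = q mod vd ≤ vd − 1, and
|s| + |P| must stay within k). Uniqueness of that d means every occurrence
is reported exactly once; position 0 is always sampled, so every
occurrence is reachable. The enumeration scheme explores extensions
depth-first, pruning empty ranges. The multiway-tree scheme proceeds
breadth-first by depth: it harvests every node's marked rows as one
contiguous block, then merges sibling ranges that abut in row space
(`end = next begin`) before LF-extending — extension of a contiguous union
telescopes, so merged extension is exact and strictly saves LF calls.
The merge rule here is adjacent-run fusion after sorting by range start;
equality with the enumeration output is the normative contract and is
asserted, together with an instrumented LF-call comparison, in the tests.

Defaults k = 256, vd = 4 balance seed length (patterns to 253 bp),
construction cost, and index size; both are configurable per build.

## Synthetic data

The generator produces three regimes: `uniform_random` (i.i.d. ACGT —
few long shared prefixes, the easy case), `self_concatenated` (a random
genome followed by its exact copy — every suffix of the first half shares
an ≈n/2-character prefix with its twin, the worst case for direct prefix
sorting and the motivating case for Strategy 2), and `tandem_repeat`
(a short unit cycled to length — maximal local periodicity, dense LMS
structure). Same spec + seed always yields the same sequence; the
construction pipeline itself uses no randomness at all.

What these fixtures do *not* emulate: real-genome composition bias,
interspersed repeat families at intermediate divergence, chromosome-scale
inputs, or IUPAC ambiguity beyond N. Passing tests therefore demonstrate
algorithmic correctness of the order/transform/query contracts across the
structural regimes that stress them, not performance claims at gigabase
scale — the implementation is sequential Python/numpy and makes no
wall-clock claims.

## Verification design and problem sizes

Correctness is anchored to independent brute-force oracles (stable naive
sorts of byte slices; direct text scans) that share no machinery with the
pipeline. The acceptance suite runs, on one CPU in well under a minute:
210 seeded genomes (70 per regime, n up to ≈900) against the naive
k-order partition for k ∈ {1, 2, 4, 8, 16, 32, unbounded} and both
strategies; exact three-way strategy equality for l ∈ {2, 3, 8}; count
checks over every distinct substring up to length 12 plus 200 random
patterns per index; locate checks for vd ∈ {1, 2, 4, 8} including the
boundary length k − vd + 1 and rejection one past it; the doubling round
bound on self-concatenated genomes of n ≈ 4000; and field-exact
serialization round trips. `scripts/acceptance.py` recomputes the same
families of quantities from fresh seeds and writes them as JSON.

## Numerical and degenerate-input choices

* Segment length l is validated against the int64 width (5^l must fit).
* A text of a single character plus sentinel has exactly one LMS position
  (the sentinel); every stage handles the singleton path.
* Bucket boundaries are exact cumulative counts; occ reconstruction never
  scans more than one checkpoint stride.
* `vd = 1` disables sampling (every row marked); `k − vd + 1 < 1` is
  rejected at build time since no pattern could ever be located.
* Pattern symbols outside ACGT are rejected per query; the sentinel is
  never a valid pattern or extension character.

## Known limitations

* Sequential construction: no parallel sorting, SIMD, or O(1)-workspace
  induction; large genomes are out of intended scope.
* The on-disk transform is one byte per symbol (no bit-packing) and the
  container is uncompressed.
* Locate by subscript sampling is intentionally unsupported (see above).
* Separator-free record concatenation can match across record boundaries.
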