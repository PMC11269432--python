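# kfmindex

Construction and querying of **k-ordered FM-indexes** for DNA references.

Read mappers only ever search for short seeds — typically under 32 bp — yet
a classical FM-index pays the full price of sorting every suffix of a
multi-gigabase genome to unlimited depth, which is exactly where the
ubiquitous long repeats make suffix sorting hard. A *k-ordered* suffix
array relaxes this: suffixes are ordered only by their first *k*
characters, ties beyond depth *k* are left unresolved. The corresponding
index replaces the Burrows-Wheeler transform with the **Schindler
transform** (last column of the rotations sorted to depth *k*) and still
supports exact backward search for any pattern with |P| ≤ k, and locate —
via a value-sampled suffix array with sampling distance *vd* — for
|P| ≤ k − vd + 1.

`kfmindex` implements the whole pipeline in Python/numpy:

* **Suffix typing** — each suffix is classified L- or S-type and the
  left-most S-type (LMS) positions are extracted, as in SA-IS.
* **LMS k-order sorting**, two interchangeable strategies:
  * *Strategy 1*: direct stable sort of the LMS suffixes by their first-k
    characters, optionally bucket-split by a leading l-mer;
  * *Strategy 2*: each LMS substring is cut into l-mers, every l-mer
    encoded as one base-5 integer (sentinel included as digit 0), and the
    concatenated *reduced reference* is ranked by prefix doubling with
    singleton exclusion — at most ⌈log₂⌈k/l⌉⌉ + 1 doubling rounds, robust
    even when a genome is concatenated with itself.
* **Induced sorting** — the classic two-scan induction derives the
  k-order of *all* suffixes from the ordered LMS set.
* **k-ordered FM-index** — Schindler transform, C array, strided
  occurrence checkpoints, and a value-sampled suffix array
  (rows with SA[i] mod vd = 0 retained). `count` is LF-mapping backward
  search; `locate` comes in two flavours: depth-first enumeration of left
  extensions s with |s| < vd (the sBWT scheme) and a breadth-first
  |Σ|-ary multiway-tree walk that merges contiguous sibling ranges before
  extending them (the FMtree scheme) — identical output, never more LF
  operations.

Both strategies produce bit-identical arrays under the package's stable
position tie rule, and with unbounded k the pipeline degenerates to an
ordinary suffix-array/BWT construction.

## Worked example

```sh
$ printf '>chrTest\nCATTAGCATGACCTAAGCAT\n' > demo.fa
$ kfmindex build demo.fa -o demo.kfm -k 16 --vd 4
$ kfmindex count demo.kfm CAT TAG GGG
CAT	3
TAG	1
GGG	0
$ kfmindex locate demo.kfm CAT
CAT	3	0,6,17
$ kfmindex locate demo.kfm CAT --format bed
chrTest	0	3
chrTest	6	9
chrTest	17	20
```

`count` prints one TSV row per pattern with its occurrence count. `locate`
prints the 0-based occurrence positions (TSV: pattern, count,
comma-separated positions; BED: record name and half-open interval per
hit). With `-k 16 --vd 4` the index answers `count` for patterns up to 16
characters and `locate` up to 16 − 4 + 1 = 13; longer patterns are
rejected with a message citing the bound. The defaults, `-k 256 --vd 4`,
balance seed length against construction speed and index size. A built-in
validation suite is available as `kfmindex selftest`.

Library use mirrors the CLI:

```python
from kfmindex import Sequence, build_fm_index

seq = Sequence.from_string("CATTAGCATGACCTAAGCAT", name="chrTest")
idx = build_fm_index(seq, k=16, vd=4, strategy=2)
idx.count("CAT").size        # 3
idx.locate_fmtree("CAT")     # array([ 0,  6, 17])
```

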