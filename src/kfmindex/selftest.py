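"""Built-in oracle-backed validation suite (backs the ``selftest`` command).

Runs the core correctness properties on freshly generated synthetic genomes:
strategy equivalence, suffix-array oracle agreement, the transform's
permutation property, count/locate agreement with direct text scans, and
index serialization round trips.  Returns a list of human-readable failure
strings; empty means every check passed.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np

from .fm_index import build_fm_index, indexes_equal, schindler_transform
from .induced_sort import build_korder_sa, stabilize
from .lms_sort import UNBOUNDED
from .oracles import kprefix_group_ids, naive_find, naive_korder_sa
from .reference_io import load_index, save_index
from .synthetic import SyntheticSpec, generate_sequence

__all__ = ["run_selftest"]

_K_GRID = (1, 2, 4, 8, 16, 32, UNBOUNDED)


def _random_patterns(rng, n_pat, max_len):
    pats = []
    for _ in range(n_pat):
        ln = int(rng.integers(1, max_len + 1))
        pats.append("".join("ACGT"[int(c)] for c in rng.integers(0, 4, ln)))
    return pats


def run_selftest(seed: int = 0, cases: int = 12, log=None) -> list[str]:
    """Execute the validation grid; ``cases`` seeded genomes per run."""
    failures: list[str] = []
    rng = np.random.default_rng(seed)
    modes = ("uniform_random", "self_concatenated", "tandem_repeat")

    def note(msg):
        if log:
            log(msg)

    for case in range(cases):
        mode = modes[case % len(modes)]
        length = int(rng.integers(40, 600))
        spec = SyntheticSpec(
            length=length,
            mode=mode,
            seed=int(rng.integers(0, 2**31 - 1)),
            repeat_unit="ACGT"[: 1 + case % 3] if mode == "tandem_repeat" else "AT",
        )
        seq = generate_sequence(spec)
        k = _K_GRID[case % len(_K_GRID)]
        label = f"{mode} n={seq.n} k={'unbounded' if k is None else k}"
        note(f"checking {label}")

        oracle = naive_korder_sa(seq, k)
        sa1 = build_korder_sa(seq, k, strategy=1)
        sa1b = build_korder_sa(seq, k, strategy=1, l_bucket=4)
        sa2 = build_korder_sa(seq, k, strategy=2, l=3)
        for tag, sa in (("s1", sa1), ("s1-bucket", sa1b), ("s2", sa2)):
            if not np.array_equal(
                kprefix_group_ids(seq, sa.order, k),
                kprefix_group_ids(seq, oracle, k),
            ):
                failures.append(f"{label}: {tag} partition differs from oracle")
            if not np.array_equal(stabilize(seq, sa).order, oracle):
                failures.append(f"{label}: stabilized {tag} != oracle array")
        tr = schindler_transform(seq, sa1)
        if not np.array_equal(
            np.bincount(tr, minlength=5), np.bincount(seq.text, minlength=5)
        ):
            failures.append(f"{label}: transform is not a permutation of the text")

        k_idx = 32 if k is None else max(k, 4)
        vd = (1, 2, 4)[case % 3]
        if k_idx - vd + 1 < 1:
            vd = 1
        idx = build_fm_index(seq, k_idx, vd=vd, checkpoint_stride=16)
        max_pat = min(8, k_idx - vd + 1)
        pats = _random_patterns(rng, 25, max_pat)
        pats += [seq.body_string()[: max_pat]]
        for p in pats:
            hits = naive_find(seq, p)
            if idx.count(p).size != hits.size:
                failures.append(f"{label}: count({p}) != naive scan")
            le = idx.locate_enumerate(p)
            lf = idx.locate_fmtree(p)
            if not np.array_equal(le, hits):
                failures.append(f"{label}: locate_enumerate({p}) != naive scan")
            if not np.array_equal(lf, le):
                failures.append(f"{label}: locate_fmtree({p}) != locate_enumerate")

        with tempfile.TemporaryDirectory() as td:
            path = os.path.join(td, "idx.kfm")
            save_index(idx, path)
            if not indexes_equal(load_index(path), idx):
                failures.append(f"{label}: save/load round trip not exact")
    return failures
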