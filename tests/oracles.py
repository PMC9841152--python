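"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: variant normalization
is checked against a brute-force enumeration of every single-replacement
representation of an edited sequence, and SNV genotyping against
scipy.stats' binomial log-pmf.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import binom


def enumerate_representations(ref: str, alt_seq: str) -> List[Tuple[int, str, str]]:
    """All parsimonious single-replacement edits turning `ref` into `alt_seq`."""
    dlen = len(alt_seq) - len(ref)
    reps = []
    for p in range(len(ref) + 1):
        if ref[:p] != alt_seq[:p]:
            break
        for lr in range(0, len(ref) - p + 1):
            la = lr + dlen
            if la < 0:
                continue
            if ref[p + lr :] != alt_seq[p + la :]:
                continue
            r, a = ref[p : p + lr], alt_seq[p : p + la]
            if not r and not a:
                continue
            if r == a:
                continue
            if r and a and (r[0] == a[0] or r[-1] == a[-1]):
                continue  # trimmable, not parsimonious
            reps.append((p, r, a))
    return reps


def leftmost_parsimonious(ref: str, alt_seq: str) -> Tuple[int, str, str]:
    """The leftmost parsimonious representation of the ref->alt_seq edit."""
    reps = enumerate_representations(ref, alt_seq)
    if not reps:
        raise ValueError("sequences are identical or differ by no single edit")
    return min(reps, key=lambda t: (t[0], len(t[1]) + len(t[2])))


def random_single_edit(rng: np.random.Generator, max_ref_len: int = 50):
    """A random reference (<= max_ref_len) with one interior edit applied.

    Returns (ref, alt_seq, pos, ref_allele, alt_allele, cigar, read_seq)
    where the CIGAR aligns the full edited sequence back to the reference
    with the edit as an interior operation.
    """
    bases = "ACGT"
    n = int(rng.integers(10, max_ref_len + 1))
    ref = "".join(rng.choice(list(bases), size=n))
    kind = rng.choice(["SNV", "INS", "DEL"])
    if kind == "SNV":
        pos = int(rng.integers(1, n - 1))
        alt = str(rng.choice([b for b in bases if b != ref[pos]]))
        ref_a, alt_a = ref[pos], alt
        alt_seq = ref[:pos] + alt + ref[pos + 1 :]
        cigar = [(0, n)]  # one M span with an internal mismatch
    elif kind == "INS":
        pos = int(rng.integers(1, n))
        k = int(rng.integers(1, 7))
        ins = "".join(rng.choice(list(bases), size=k))
        ref_a, alt_a = "", ins
        alt_seq = ref[:pos] + ins + ref[pos:]
        cigar = [(0, pos), (1, k), (0, n - pos)]
    else:
        pos = int(rng.integers(1, n - 1))
        k = int(rng.integers(1, min(7, n - pos)))
        ref_a, alt_a = ref[pos : pos + k], ""
        alt_seq = ref[:pos] + ref[pos + k :]
        cigar = [(0, pos), (2, k), (0, n - pos - k)]
    return ref, alt_seq, pos, ref_a, alt_a, cigar, alt_seq


def genotype_argmax_scipy(alt: int, depth: int, eps: float = 0.01) -> int:
    """Index (0: hom-ref, 1: het, 2: hom-alt) of the max binomial likelihood."""
    lls = [
        binom.logpmf(alt, depth, p) for p in (eps, 0.5, 1.0 - eps)
    ]
    best = 0
    for i in (1, 2):
        if lls[i] > lls[best]:
            best = i
    return best
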