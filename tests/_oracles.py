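"""Independent brute-force oracles used across the test suite.

Each oracle is written against the rules directly (nested loops, explicit
recursion) and stays independent of the package code paths it checks.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def hamming_alignments(
    read: str, refs: list[tuple[str, str]], max_mm: int
) -> set[tuple[str, int, int, int]]:
    """All ungapped placements as (ref_id, start, end, mismatches), 1-based.

    T/U identical, N mismatches everything; exhaustive sliding-window scan.
    """
    read = read.replace("U", "T")
    out = set()
    for ref_id, ref_seq in refs:
        ref_seq = ref_seq.replace("U", "T")
        for start in range(len(ref_seq) - len(read) + 1):
            mm = 0
            for a, b in zip(read, ref_seq[start : start + len(read)]):
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm <= max_mm:
                out.add((ref_id, start + 1, start + len(read), mm))
    return out


def window_sites(
    trf: str,
    utr: str,
    max_nonseed_mm: int = 6,
    seed_lo: int = 2,
    seed_hi: int = 7,
) -> list[tuple[int, int]]:
    """Qualifying windows as (1-based start, nonseed mismatches): exhaustive
    scan, Watson-Crick only, antiparallel (tRF pos p faces window pos L-p+1)."""
    L = len(trf)
    hits = []
    for start in range(len(utr) - L + 1):
        window = utr[start : start + L]
        seed_ok = True
        nonseed = 0
        for p in range(1, L + 1):
            facing = window[L - p]
            ok = _COMP.get(trf[p - 1]) == facing
            if seed_lo <= p <= seed_hi:
                seed_ok = seed_ok and ok
            elif not ok:
                nonseed += 1
        if seed_ok and nonseed <= max_nonseed_mm:
            hits.append((start + 1, nonseed))
    return hits


def count_structures(seq: str, min_hairpin: int = 3) -> int:
    """Number of pseudoknot-free structures, by an independent recursion
    that never materializes the structures themselves."""
    s = seq.replace("U", "T")
    pairs = {"GC", "CG", "AT", "TA", "GT", "TG"}
    memo: dict[tuple[int, int], int] = {}

    def n(i: int, j: int) -> int:
        if j - i < min_hairpin:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = n(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if s[i] + s[k] in pairs:
                total += n(i + 1, k - 1) * n(k + 1, j)
        memo[(i, j)] = total
        return total

    return n(0, len(s) - 1)


def shape_masses_by_enumeration(seq: str, temperature_scale: float = 1.0):
    """Shape -> probability by exhaustive enumeration + per-structure collapse."""
    from trfkit.fold import enumerate_structures, shape_of

    agg: dict[str, float] = {}
    for db, energy in enumerate_structures(seq):
        sh = shape_of(db)
        agg[sh] = agg.get(sh, 0.0) + math.exp(-energy / temperature_scale)
    total = sum(agg.values())
    return {sh: w / total for sh, w in agg.items()}


def stack_sum(trf: str, site: str, table: dict[str, float]) -> float:
    """Direct nearest-neighbor table sum over adjacent complementary positions."""
    L = len(trf)
    paired = [
        _COMP.get(trf[p]) == site[L - 1 - p] for p in range(L)
    ]
    return sum(
        table[trf[p : p + 2]]
        for p in range(L - 1)
        if paired[p] and paired[p + 1]
    )
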