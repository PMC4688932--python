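"""Abstract-shape probabilities of RNA secondary structure.

Some tRNA transcripts can trade the cloverleaf for a long pre-miRNA-like
hairpin, which makes them Dicer substrates and hence tRF precursors.  This
module quantifies that propensity: every pseudoknot-free structure of a
transcript is weighted by its Boltzmann factor, structures are collapsed to
abstract shapes (each helix-nested unit becomes ``[]``, unpaired stretches
are dropped; a hairpin is ``[]``, a cloverleaf ``[[][][]]``, the open chain
``_``), and the probability of a shape is the summed probability of all
structures that fall into it.

The energy model is deliberately simple and self-contained — additive
per-pair energies (GC −3, AU −2, GU −1, arbitrary units), hairpin loops of
at least 3 nt, no loop penalties — because the point is the shape-probability
mechanism, verified against exhaustive enumeration, not the reproduction of
any full thermodynamic parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .seqio import normalize_sequence

ENERGY_MODEL_ID = "additive-pair-v1"
PAIR_ENERGY: dict[str, float] = {
    "GC": -3.0, "CG": -3.0,
    "AT": -2.0, "TA": -2.0,
    "GT": -1.0, "TG": -1.0,
}
MIN_HAIRPIN = 3
ORACLE_MAX_LEN = 30
OPEN_CHAIN = "_"


def _pair_energy(a: str, b: str) -> float | None:
    return PAIR_ENERGY.get(a + b)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (oracle scale)
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq: str, min_hairpin: int = MIN_HAIRPIN, max_len: int = ORACLE_MAX_LEN
) -> list[tuple[str, float]]:
    """Every pseudoknot-free structure of a short sequence with its energy.

    Structures are dot-bracket strings; allowed pairs are AU/UA, GC/CG,
    GU/UG and every pair encloses at least ``min_hairpin`` unpaired-or-paired
    positions (which reduces to the usual minimum hairpin-loop size).  This
    is the brute-force oracle for :func:`shape_distribution`; sequences
    longer than ``max_len`` are refused with a pointer to the DP.
    """
    s = normalize_sequence(seq)
    n = len(s)
    if n > max_len:
        raise ValueError(
            f"enumeration is capped at {max_len} nt; use shape_distribution's DP"
        )

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i > j:
            return ((),)
        out = []
        for rest in enum(i + 1, j):
            out.append(rest)
        for k in range(i + min_hairpin + 1, j + 1):
            if _pair_energy(s[i], s[k]) is None:
                continue
            for inner in enum(i + 1, k - 1):
                for rest in enum(k + 1, j):
                    out.append(((i, k),) + inner + rest)
        return tuple(out)

    results = []
    for pairs in enum(0, n - 1):
        db = ["."] * n
        energy = 0.0
        for i, k in pairs:
            db[i], db[k] = "(", ")"
            energy += _pair_energy(s[i], s[k])
        results.append(("".join(db), energy))
    enum.cache_clear()
    return results


# ---------------------------------------------------------------------------
# Shape abstraction
# ---------------------------------------------------------------------------

def shape_of(structure: str) -> str:
    """Collapse a dot-bracket structure to its abstract shape.

    Each maximal helix-nested unit (a stack, bulges included) becomes
    ``[]``; unpaired stretches are dropped; sibling units concatenate; the
    open chain is ``_``.  Unbalanced input raises ValueError.
    """
    root: list = []
    stack = [root]
    for c in structure:
        if c == "(":
            node: list = []
            stack[-1].append(node)
            stack.append(node)
        elif c == ")":
            stack.pop()
            if not stack:
                raise ValueError("unbalanced dot-bracket: unmatched ')'")
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if len(stack) != 1:
        raise ValueError("unbalanced dot-bracket: unmatched '('")

    def collapse(node: list) -> str:
        if not node:
            return "[]"
        if len(node) == 1:
            return collapse(node[0])
        return "[" + "".join(collapse(c) for c in node) + "]"

    if not root:
        return OPEN_CHAIN
    return "".join(collapse(c) for c in root)


def _close_shape(forest: str) -> str:
    """Shape of a forest once enclosed by an outer pair."""
    if not forest:
        return "[]"
    depth = 0
    for i, c in enumerate(forest):
        depth += 1 if c == "[" else -1
        if depth == 0 and i < len(forest) - 1:
            return "[" + forest + "]"  # >= 2 sibling units: a branch point
    return forest  # single unit: the pair extends its helix


# ---------------------------------------------------------------------------
# Partition function over shapes
# ---------------------------------------------------------------------------

def _shape_partition(
    s: str, min_hairpin: int, kT: float
) -> dict[str, float]:
    """Log-space interval DP: for each shape, log of the summed Boltzmann
    weight of the structures realizing it."""
    n = len(s)
    # Z[(i, j)]: shape-forest -> log total weight over s[i..j]
    Z: dict[tuple[int, int], dict[str, float]] = {}

    def get(i: int, j: int) -> dict[str, float]:
        if i > j:
            return {"": 0.0}
        return Z[(i, j)]

    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            acc = dict(get(i + 1, j))  # i unpaired
            for k in range(i + min_hairpin + 1, j + 1):
                e = _pair_energy(s[i], s[k])
                if e is None:
                    continue
                lw = -e / kT
                rest = get(k + 1, j)
                for forest, lf in get(i + 1, k - 1).items():
                    closed = _close_shape(forest)
                    base = lw + lf
                    for g, lg in rest.items():
                        key = closed + g
                        prev = acc.get(key)
                        val = base + lg
                        acc[key] = val if prev is None else np.logaddexp(prev, val)
            Z[(i, j)] = acc
    return get(0, n - 1)


@dataclass
class ShapeDistribution:
    """Boltzmann probability mass over abstract shapes of one transcript."""

    sequence_id: str
    shapes: dict[str, float]
    partition_function: float
    energy_model_id: str = ENERGY_MODEL_ID
    temperature_scale: float = 1.0

    def probability(self, shape: str) -> float:
        return self.shapes.get(shape, 0.0)

    def top_shapes(self, n: int = 5) -> list[tuple[str, float]]:
        return sorted(self.shapes.items(), key=lambda kv: -kv[1])[:n]


def shape_distribution(
    seq: str,
    temperature_scale: float = 1.0,
    sequence_id: str = "",
    min_hairpin: int = MIN_HAIRPIN,
) -> ShapeDistribution:
    """Shape probabilities from the partition function.

    ``temperature_scale`` is kT in the energy model's arbitrary units; as it
    approaches 0 the minimum-energy structure's shape takes all the mass.
    The DP aggregates Boltzmann weight per shape in log space, so low
    temperatures do not overflow.
    """
    if temperature_scale <= 0:
        raise ValueError("temperature_scale must be > 0")
    s = normalize_sequence(seq)
    if not s:
        raise ValueError("empty sequence")
    logw = _shape_partition(s, min_hairpin, temperature_scale)
    log_total = float(np.logaddexp.reduce(np.array(list(logw.values()))))
    shapes = {
        (OPEN_CHAIN if shape == "" else shape): math.exp(lw - log_total)
        for shape, lw in logw.items()
    }
    try:
        pf = math.exp(log_total)
    except OverflowError:
        pf = math.inf
    return ShapeDistribution(
        sequence_id=sequence_id,
        shapes=shapes,
        partition_function=pf,
        temperature_scale=temperature_scale,
    )


HAIRPIN_SHAPE = "[]"
STRONG_HAIRPIN_PROBABILITY = 0.7


@dataclass(frozen=True)
class HairpinCall:
    probability: float
    hairpin_prone: bool  # P("[]") beats every other single shape
    strong: bool  # P("[]") > 0.7


def classify_hairpin(dist: ShapeDistribution) -> HairpinCall:
    p = dist.probability(HAIRPIN_SHAPE)
    others = max(
        (q for s, q in dist.shapes.items() if s != HAIRPIN_SHAPE), default=0.0
    )
    return HairpinCall(
        probability=p,
        hairpin_prone=p > others,
        strong=p > STRONG_HAIRPIN_PROBABILITY,
    )


def hairpin_propensity(seq: str, temperature_scale: float = 1.0) -> float:
    """P of the pure hairpin shape ``[]`` for a transcript."""
    return shape_distribution(seq, temperature_scale).probability(HAIRPIN_SHAPE)
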