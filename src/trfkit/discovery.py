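"""tRF discovery: ungapped alignment, abundance/dominance calling and
fragment-end classification.

The identification rule mirrors how the zebrafish fragments were found:
collapsed reads are aligned to mature tRNAs allowing up to two mismatches
(so sequencing errors and post-transcriptional modifications do not discard
real fragments), and a fragment is called a tRF when it was cloned more than
``min_count`` times *and* it dominates the read mass aligned to its mature
tRNA — the signature of specific cleavage, which a random-degradation null
cannot produce.  Calls are classified 5'/3'/internal by where they sit on
the mature sequence and flagged for the non-templated CCA tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache

import numpy as np

from .seqio import CollapsedReadTable, TRNAReference

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_COUNT = 3  # strict: "more than three times" => >= 4 reads
DEFAULT_DOMINANCE = 0.5
DEFAULT_END_SLACK = 1
DEFAULT_LENGTH_RANGE = (15, 30)
MATURE_LIKE_COVERAGE = 0.9


class EndClass(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    INTERNAL = "internal"
    MATURE_LIKE = "mature_like"


_SERIES_PREFIX = {
    EndClass.FIVE_PRIME: "5′tRF",
    EndClass.THREE_PRIME: "3′tRF",
    EndClass.INTERNAL: "itRF",
}


@dataclass(frozen=True)
class UngappedAlignment:
    """A sense-strand, indel-free placement of a read on a mature tRNA.

    ``start``/``end`` are 1-based inclusive reference coordinates (CCA
    included in the reference)."""

    read_sequence: str
    reference_id: str
    start: int
    end: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.read_sequence):
            raise ValueError("ungapped alignment must span exactly the read length")


@dataclass(frozen=True)
class TRFCall:
    name: str
    sequence: str
    source_reference_id: str
    end_class: EndClass
    read_count: int
    dominance: float
    has_cca_signature: bool

    @property
    def length(self) -> int:
        return len(self.sequence)


_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@lru_cache(maxsize=8192)
def _encoded(seq: str) -> np.ndarray:
    return np.frombuffer(
        bytes(_ENCODE[c] for c in seq), dtype=np.uint8
    )


def align_read(
    read: str,
    references: list[TRNAReference],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[UngappedAlignment]:
    """Every ungapped placement of ``read`` with Hamming distance at most
    ``max_mismatches``, over every reference.

    T and U are identical for mismatch counting; N mismatches everything.
    Results are ordered by (reference id, start).  A read longer than every
    reference yields an empty result.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    m = len(read)
    out: list[UngappedAlignment] = []
    r = _encoded(read)
    probe = read.replace("U", "T")
    read_has_n = bool((r == 4).any())
    for ref in sorted(references, key=lambda x: x.id):
        L = ref.length
        if m > L:
            continue
        if max_mismatches == 0 and not read_has_n and "N" not in ref.sequence:
            start = ref.sequence.find(probe)
            while start != -1:
                out.append(
                    UngappedAlignment(read, ref.id, start + 1, start + m, 0)
                )
                start = ref.sequence.find(probe, start + 1)
            continue
        enc = _encoded(ref.sequence)
        windows = np.lib.stride_tricks.sliding_window_view(enc, m)
        mismatch = (windows != r) | (windows == 4) | (r == 4)
        counts = mismatch.sum(axis=1)
        for offset in np.flatnonzero(counts <= max_mismatches):
            out.append(
                UngappedAlignment(
                    read, ref.id, int(offset) + 1, int(offset) + m, int(counts[offset])
                )
            )
    return out


def detect_cca(call_sequence: str) -> bool:
    """True iff the last three residues are C,C,A (non-templated tRNA tail);
    sequences shorter than 3 nt return False."""
    return len(call_sequence) >= 3 and call_sequence.endswith("CCA")


def classify_fragment(
    aln: UngappedAlignment, ref: TRNAReference, end_slack: int = DEFAULT_END_SLACK
) -> EndClass:
    """Classify a fragment by its position on the mature tRNA.

    5' fragments start within ``end_slack`` of the tRNA 5' terminus, 3'
    fragments end within ``end_slack`` of the (CCA-inclusive) 3' terminus;
    1 nt of slack absorbs the non-templated/CCA ambiguity.  A fragment
    covering >= 90 % of the mature tRNA is mature-like, not a tRF.
    """
    coverage = (aln.end - aln.start + 1) / ref.length
    if coverage >= MATURE_LIKE_COVERAGE:
        return EndClass.MATURE_LIKE
    if aln.start <= 1 + end_slack:
        return EndClass.FIVE_PRIME
    if aln.end >= ref.length - end_slack:
        return EndClass.THREE_PRIME
    return EndClass.INTERNAL


@dataclass
class ClassSummary:
    """Per-RNA-class read assignment for a collapsed library."""

    counts: dict[str, float]
    assigned_reads: float
    unassigned_reads: int
    total_reads: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.assigned_reads == 0:
            return {cls: 0.0 for cls in self.counts}
        return {cls: c / self.assigned_reads for cls, c in self.counts.items()}


def partition_by_class(
    table: CollapsedReadTable,
    class_references: dict[str, list[TRNAReference]],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> ClassSummary:
    """Assign each collapsed sequence to the RNA class of its best alignment.

    Ties at the best mismatch count across classes are split fractionally.
    ``class_references`` maps a class label (tRNA, rRNA, snRNA, snoRNA, ...)
    to its reference sequences.
    """
    counts = {cls: 0.0 for cls in class_references}
    assigned = 0.0
    unassigned = 0
    for seq, count in table.rows.items():
        best = None
        best_classes: list[str] = []
        for cls, refs in class_references.items():
            hits = align_read(seq, refs, max_mismatches)
            if not hits:
                continue
            mm = min(h.mismatches for h in hits)
            if best is None or mm < best:
                best, best_classes = mm, [cls]
            elif mm == best:
                best_classes.append(cls)
        if not best_classes:
            unassigned += count
            continue
        share = count / len(best_classes)
        for cls in best_classes:
            counts[cls] += share
        assigned += count
    return ClassSummary(
        counts=counts,
        assigned_reads=assigned,
        unassigned_reads=unassigned,
        total_reads=table.total_sncrna_reads,
    )


@dataclass(frozen=True)
class _MatureGroup:
    """Isodecoders with identical mature sequence, collapsed."""

    sequence: str
    member_ids: tuple[str, ...]
    families: tuple[str, ...]

    @property
    def representative(self) -> TRNAReference:
        return TRNAReference(self.member_ids[0], self.sequence)


def _mature_groups(references: list[TRNAReference]) -> list[_MatureGroup]:
    by_seq: dict[str, list[TRNAReference]] = {}
    for ref in references:
        by_seq.setdefault(ref.sequence, []).append(ref)
    groups = []
    for seq, members in by_seq.items():
        groups.append(
            _MatureGroup(
                sequence=seq,
                member_ids=tuple(r.id for r in members),
                families=tuple(dict.fromkeys(r.family for r in members)),
            )
        )
    return groups


def call_trfs(
    table: CollapsedReadTable,
    references: list[TRNAReference],
    min_count: int = DEFAULT_MIN_COUNT,
    dominance_threshold: float = DEFAULT_DOMINANCE,
    end_slack: int = DEFAULT_END_SLACK,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> list[TRFCall]:
    """Call tRFs from a collapsed library.

    For each mature tRNA (identical-sequence isodecoders collapsed) the modal
    aligned fragment is emitted iff its cloning frequency is strictly greater
    than ``min_count`` and its share of the read mass aligned to that tRNA
    reaches ``dominance_threshold``.  A read whose best alignments reach k
    mature sequences contributes count/k to each (fractional assignment);
    a modal tie between two distinct fragments yields no call for that tRNA
    (neither dominates).  Calls are deduplicated per isoacceptor family.
    """
    lo, hi = length_range
    groups = _mature_groups(references)
    group_reads: list[dict[str, tuple[float, int, UngappedAlignment]]] = [
        {} for _ in groups
    ]
    for seq, count in table.rows.items():
        if not lo <= len(seq) <= hi:
            continue
        hits_per_group = []
        best_mm = None
        for gi, group in enumerate(groups):
            hits = align_read(seq, [group.representative], max_mismatches)
            if hits:
                mm = min(h.mismatches for h in hits)
                hits_per_group.append((gi, mm, hits))
                best_mm = mm if best_mm is None else min(best_mm, mm)
        if best_mm is None:
            continue
        best_groups = [(gi, hits) for gi, mm, hits in hits_per_group if mm == best_mm]
        share = count / len(best_groups)
        for gi, hits in best_groups:
            best_hit = min(hits, key=lambda h: (h.mismatches, h.start))
            group_reads[gi][seq] = (share, count, best_hit)

    calls: dict[tuple[str, str], TRFCall] = {}
    for group, reads in zip(groups, group_reads):
        if not reads:
            continue
        total_weight = sum(w for w, _, _ in reads.values())
        ranked = sorted(reads.items(), key=lambda kv: -kv[1][0])
        if len(ranked) > 1 and ranked[0][1][0] == ranked[1][1][0]:
            logger.info(
                "no call for %s: modal-fragment tie at weight %.2f",
                "/".join(group.member_ids),
                ranked[0][1][0],
            )
            continue
        seq, (weight, count, hit) = ranked[0]
        dominance = weight / total_weight if total_weight else 0.0
        if count <= min_count or dominance < dominance_threshold:
            logger.info(
                "no call for %s: count=%d dominance=%.3f",
                "/".join(group.member_ids),
                count,
                dominance,
            )
            continue
        end_class = classify_fragment(hit, group.representative, end_slack)
        if end_class is EndClass.MATURE_LIKE:
            logger.info("modal fragment on %s is mature-like; skipped", group.member_ids)
            continue
        for family in group.families:
            key = (family, seq)
            name = f"{_SERIES_PREFIX[end_class]}-{family}"
            call = TRFCall(
                name=name,
                sequence=seq,
                source_reference_id=",".join(group.member_ids),
                end_class=end_class,
                read_count=count,
                dominance=dominance,
                has_cca_signature=detect_cca(seq),
            )
            prev = calls.get(key)
            if prev is None or call.dominance > prev.dominance:
                calls[key] = call

    # disambiguate duplicate names (two distinct same-class fragments in one family)
    out = list(calls.values())
    seen: dict[str, int] = {}
    final = []
    for call in sorted(out, key=lambda c: (c.name, -c.read_count)):
        n = seen.get(call.name, 0)
        seen[call.name] = n + 1
        final.append(call if n == 0 else replace(call, name=f"{call.name}-{n + 1}"))
    return final
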