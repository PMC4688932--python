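"""Synthetic small-RNA libraries with known ground truth.

Everything downstream of sequencing is testable without any download: this
module builds a deterministic mature-tRNA reference fixture hosting the
published zebrafish tRF panel, spikes tRFs at chosen cloning frequencies on
top of a uniform tRNA-degradation background and decoy ncRNA fragments, and
draws matched condition/control count tables with negative-binomial noise.

The degradation null is intentionally structureless — fragment start
positions uniform over the reference, lengths uniform over the read-length
window — because the discovery rules exist precisely to reject that null.
Every generated library carries a machine-readable truth record
(:attr:`~trfkit.seqio.ReadSet.truth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import panel as _panel
from .seqio import (
    CollapsedReadTable,
    ReadSet,
    RNAReference,
    TRNAReference,
    collapse_reads,
)

MAX_END_JITTER = 4  # largest observed length variant vs the zebrafish fragments

_FIXTURE_ENTROPY = 20151222  # fixed; the fixture must be byte-stable


class GenerationError(ValueError):
    """A library spec is inconsistent with its references."""


@dataclass(frozen=True)
class SpikeSpec:
    """A tRF spiked into a synthetic library at a known cloning frequency."""

    trf_sequence: str
    source_reference_id: str
    end_class: str  # five_prime | three_prime
    count: int
    end_jitter: int = 0
    jitter_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.count < 0:
            raise GenerationError("spike count must be >= 0")
        if not 0 <= self.end_jitter <= MAX_END_JITTER:
            raise GenerationError(f"end_jitter must be in [0, {MAX_END_JITTER}]")
        if self.end_class not in (_panel.FIVE_PRIME, _panel.THREE_PRIME):
            raise GenerationError(f"unknown end_class {self.end_class!r}")


@dataclass(frozen=True)
class LibrarySpec:
    spikes: tuple[SpikeSpec, ...]
    background_reads: int = 0
    decoy_reads: int = 0
    read_length_range: tuple[int, int] = (15, 30)
    seed: int = 0
    reference_weights: tuple[float, ...] | None = None  # copy-number weights

    def __post_init__(self) -> None:
        lo, hi = self.read_length_range
        if not 1 <= lo <= hi:
            raise GenerationError("invalid read_length_range")


# ---------------------------------------------------------------------------
# Deterministic references
# ---------------------------------------------------------------------------

def _body(tag: str, length: int) -> str:
    """Deterministic pseudo-random nucleotide filler for one reference."""
    rng = np.random.default_rng([_FIXTURE_ENTROPY, *tag.encode()])
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


# reference id hosting each panel tRF; the two Glu-CTC fragments sit on two
# same-anticodon isodecoders so each dominates its own mature sequence
_HOST_REFS: dict[str, str] = {
    "5′tRF-Lys-TTT": "Lys-TTT",
    "5′tRF-Val-CAC": "Val-CAC",
    "5′tRF-Glu-CTC": "Glu-CTC-1",
    "5′tRF-Pro-CGG": "Pro-CGG",
    "3′tRF-Ala-AGC": "Ala-AGC",
    "3′tRF-Lys-CTT": "Lys-CTT",
    "3′tRF-Ile-AAT": "Ile-AAT",
    "3′tRF-Glu-CTC": "Glu-CTC-2",
    "3′tRF-Pro-AGG": "Pro-AGG",
    "3′tRF-Arg-TCG": "Arg-TCG",
}

_FIXTURE_LENGTH = 76


def build_reference_fixture() -> list[TRNAReference]:
    """Deterministic mature-tRNA references hosting the zebrafish panel.

    Each 5'tRF is the exact prefix of its reference and each 3'tRF the exact
    suffix; references are 76 nt and end in CCA except where the embedded
    3'tRF itself lacks the CCA tail (those references end on the fragment's
    own 3' residues, mimicking tRNAs cloned without the non-templated tail).
    """
    refs = []
    for rec in _panel.PANEL:
        ref_id = _HOST_REFS[rec.name]
        body_len = _FIXTURE_LENGTH - len(rec.sequence)
        if rec.end_class == _panel.FIVE_PRIME:
            seq = rec.sequence + _body(ref_id, body_len - 3) + "CCA"
        else:
            seq = _body(ref_id, body_len) + rec.sequence
        refs.append(TRNAReference(id=ref_id, sequence=seq))
    return refs


def host_reference_id(panel_name: str) -> str:
    return _HOST_REFS[panel_name]


_EXTRA_FAMILIES = (
    "Gly-GCC", "Gly-TCC", "Ser-AGA", "Ser-GCT", "Leu-AAG", "Leu-CAA",
    "Thr-AGT", "Thr-TGT", "Asp-GTC", "Asn-GTT", "His-GTG", "Phe-GAA",
    "Tyr-GTA", "Cys-GCA", "Trp-CCA", "Met-CAT", "Gln-TTG", "Gln-CTG",
    "Arg-ACG", "Val-AAC",
)


def random_references(
    n: int, seed: int, length: int = 80
) -> list[TRNAReference]:
    """Deterministic additional mature-tRNA references (unspiked families),
    used to emulate a genome-scale tRNA gene set."""
    rng = np.random.default_rng([seed, 0x7EF5])
    bases = np.array(list("ACGT"))
    refs = []
    for i in range(n):
        fam = _EXTRA_FAMILIES[i % len(_EXTRA_FAMILIES)]
        seq = "".join(bases[rng.integers(0, 4, length - 3)]) + "CCA"
        refs.append(TRNAReference(id=f"{fam}-x{i + 1}", sequence=seq))
    return refs


def decoy_reference_set(seed: int) -> dict[str, list[RNAReference]]:
    """Deterministic non-tRNA ncRNA decoys grouped by RNA class."""
    rng = np.random.default_rng([seed, 0xDEC0])
    bases = np.array(list("ACGT"))
    out: dict[str, list[RNAReference]] = {}
    for cls, n, length in (("rRNA", 2, 140), ("snRNA", 2, 120), ("snoRNA", 2, 110)):
        out[cls] = [
            RNAReference(f"{cls}-{i + 1}", "".join(bases[rng.integers(0, 4, length)]))
            for i in range(n)
        ]
    return out


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _validate_spike(spike: SpikeSpec, refs_by_id: dict[str, TRNAReference]) -> None:
    ref = refs_by_id.get(spike.source_reference_id)
    if ref is None:
        raise GenerationError(f"unknown reference {spike.source_reference_id!r}")
    if spike.end_class == _panel.FIVE_PRIME:
        if not ref.sequence.startswith(spike.trf_sequence):
            raise GenerationError(
                f"spike is not a prefix of {ref.id} (declared five_prime)"
            )
    elif not ref.sequence.endswith(spike.trf_sequence):
        raise GenerationError(f"spike is not a suffix of {ref.id} (declared three_prime)")


def _jitter_deltas(jitter: int) -> tuple[list[int], list[float]]:
    """Symmetric truncated geometric (p=0.5) over {-jitter..+jitter}\\{0}."""
    deltas, weights = [], []
    for k in range(1, jitter + 1):
        for sign in (+1, -1):
            deltas.append(sign * k)
            weights.append(0.5 ** k)
    total = sum(weights)
    return deltas, [w / total for w in weights]


def _jittered_sequence(
    spike: SpikeSpec, ref: TRNAReference, delta: int, length_range: tuple[int, int]
) -> str | None:
    """Length variant of a spike at its free end (3' for 5'tRFs, 5' for
    3'tRFs; the anchored end is the tRNA terminus).  None when the variant
    would leave the reference or the read-length window."""
    new_len = len(spike.trf_sequence) + delta
    lo, hi = length_range
    if not lo <= new_len <= hi or new_len > ref.length:
        return None
    if spike.end_class == _panel.FIVE_PRIME:
        return ref.sequence[:new_len]
    return ref.sequence[-new_len:]


def _spike_reads(
    spike: SpikeSpec,
    ref: TRNAReference,
    length_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[str]:
    reads = [spike.trf_sequence] * spike.count
    if spike.end_jitter > 0 and spike.count > 0:
        deltas, weights = _jitter_deltas(spike.end_jitter)
        jittered = rng.random(spike.count) < spike.jitter_fraction
        picks = rng.choice(deltas, size=spike.count, p=weights)
        for i in np.flatnonzero(jittered):
            var = _jittered_sequence(spike, ref, int(picks[i]), length_range)
            if var is not None:
                reads[i] = var
    return reads


def _fragment_reads(
    sources: list[str],
    n: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> list[str]:
    """Uniform-position fragments of the given source sequences."""
    if n == 0 or not sources:
        return []
    lens = np.array([len(s) for s in sources])
    lo, hi = length_range
    idx = rng.choice(len(sources), size=n, p=weights)
    frag_len = rng.integers(lo, hi + 1, size=n)
    frag_len = np.minimum(frag_len, lens[idx])
    max_start = lens[idx] - frag_len
    starts = (rng.random(n) * (max_start + 1)).astype(np.int64)
    return [
        sources[i][s : s + L] for i, s, L in zip(idx, starts, frag_len)
    ]


def generate_library(
    spec: LibrarySpec, references: list[TRNAReference]
) -> ReadSet:
    """Draw a synthetic read library; deterministic given ``spec.seed``.

    The returned :class:`ReadSet` carries a ``truth`` record with the spiked
    fragments (including the realized jitter variants), background/decoy
    read counts and the decoy source sequences.
    """
    refs_by_id = {r.id: r for r in references}
    if len(refs_by_id) != len(references):
        raise GenerationError("duplicate reference ids")
    for spike in spec.spikes:
        _validate_spike(spike, refs_by_id)
    rng = np.random.default_rng(spec.seed)

    reads: list[str] = []
    truth_spikes = {}
    for spike in spec.spikes:
        ref = refs_by_id[spike.source_reference_id]
        spike_reads = _spike_reads(spike, ref, spec.read_length_range, rng)
        reads.extend(spike_reads)
        variants: dict[str, int] = {}
        for s in spike_reads:
            variants[s] = variants.get(s, 0) + 1
        truth_spikes[spike.trf_sequence] = {
            "reference": spike.source_reference_id,
            "end_class": spike.end_class,
            "count": spike.count,
            "variants": variants,
        }

    weights = None
    if spec.reference_weights is not None:
        w = np.asarray(spec.reference_weights, dtype=float)
        if len(w) != len(references):
            raise GenerationError("reference_weights length mismatch")
        weights = w / w.sum()
    reads.extend(
        _fragment_reads(
            [r.sequence for r in references],
            spec.background_reads,
            spec.read_length_range,
            rng,
            weights,
        )
    )

    decoys = decoy_reference_set(spec.seed)
    decoy_sources = [ref.sequence for group in decoys.values() for ref in group]
    reads.extend(
        _fragment_reads(decoy_sources, spec.decoy_reads, spec.read_length_range, rng)
    )

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = {
        "seed": spec.seed,
        "spikes": truth_spikes,
        "background_reads": spec.background_reads,
        "decoy_reads": spec.decoy_reads,
        "decoy_references": decoys,
    }
    return ReadSet(reads=reads, source_label=f"synthetic-seed{spec.seed}", truth=truth)


# ---------------------------------------------------------------------------
# Condition / control count pairs
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _spike_rows(
    spike: SpikeSpec,
    ref: TRNAReference,
    total: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
) -> dict[str, int]:
    if total == 0:
        return {}
    if spike.end_jitter == 0:
        return {spike.trf_sequence: total}
    deltas, dweights = _jitter_deltas(spike.end_jitter)
    seqs = [spike.trf_sequence]
    probs = [1.0 - spike.jitter_fraction]
    for d, w in zip(deltas, dweights):
        var = _jittered_sequence(spike, ref, d, length_range)
        if var is None:
            probs[0] += spike.jitter_fraction * w
        else:
            seqs.append(var)
            probs.append(spike.jitter_fraction * w)
    counts = rng.multinomial(total, probs)
    rows: dict[str, int] = {}
    for s, c in zip(seqs, counts):
        if c:
            rows[s] = rows.get(s, 0) + int(c)
    return rows


def generate_condition_pair(
    base: LibrarySpec,
    fold_changes: dict[str, float],
    seed: int,
    dispersion: float = 0.05,
) -> tuple[CollapsedReadTable, CollapsedReadTable]:
    """Matched (control, condition) collapsed tables for the spiked tRFs.

    ``fold_changes`` maps a spiked tRF sequence to its condition/control
    expectation ratio; unlisted spikes keep ratio 1.  Counts are negative
    binomial around the spike's expected count.  Background and decoy reads
    enter both totals as untabulated small-ncRNA mass, so normalization to
    total sncRNA reads behaves as it does with real processed datasets.
    """
    spiked = {s.trf_sequence for s in base.spikes}
    for key, ratio in fold_changes.items():
        if key not in spiked:
            raise GenerationError(f"fold change keyed on unspiked tRF {key[:20]!r}")
        if ratio <= 0:
            raise GenerationError("fold-change ratio must be > 0")
    refs_by_id = {r.id: r for r in build_reference_fixture()}
    rng = np.random.default_rng([seed, 0xFA1D])

    tables = []
    for is_condition in (False, True):
        rows: dict[str, int] = {}
        for spike in base.spikes:
            ratio = fold_changes.get(spike.trf_sequence, 1.0) if is_condition else 1.0
            total = _nb_draw(rng, ratio * spike.count, dispersion)
            ref = refs_by_id.get(spike.source_reference_id)
            if ref is None or not (
                ref.sequence.startswith(spike.trf_sequence)
                or ref.sequence.endswith(spike.trf_sequence)
            ):
                # spike hosted outside the fixture: no jitter context needed
                ref = TRNAReference("Und-NNN", spike.trf_sequence)
            for s, c in _spike_rows(
                spike, ref, total, base.read_length_range, rng
            ).items():
                rows[s] = rows.get(s, 0) + c
        other_mass = _nb_draw(rng, base.background_reads, dispersion) + _nb_draw(
            rng, base.decoy_reads, dispersion
        )
        tables.append(
            CollapsedReadTable(
                rows=rows, total_sncrna_reads=sum(rows.values()) + other_mass
            )
        )
    return tables[0], tables[1]


def panel_library_spec(seed: int = 0, background_reads: int = 0, decoy_reads: int = 0,
                       end_jitter: int = 0) -> LibrarySpec:
    """LibrarySpec spiking each published zebrafish tRF at its printed
    cloning frequency onto the deterministic reference fixture."""
    spikes = tuple(
        SpikeSpec(
            trf_sequence=rec.sequence,
            source_reference_id=_HOST_REFS[rec.name],
            end_class=rec.end_class,
            count=rec.reads,
            end_jitter=end_jitter,
        )
        for rec in _panel.PANEL
    )
    return LibrarySpec(
        spikes=spikes,
        background_reads=background_reads,
        decoy_reads=decoy_reads,
        seed=seed,
    )


def collapse_library(spec: LibrarySpec, references: list[TRNAReference]) -> CollapsedReadTable:
    return collapse_reads(generate_library(spec, references))


def write_truth_tsv(path, truth: dict) -> None:
    """Flat TSV ground-truth ledger for a generated library."""
    with open(path, "w") as fh:
        fh.write("record\tname\tvalue\n")
        fh.write(f"meta\tseed\t{truth['seed']}\n")
        fh.write(f"meta\tbackground_reads\t{truth['background_reads']}\n")
        fh.write(f"meta\tdecoy_reads\t{truth['decoy_reads']}\n")
        for seq, info in truth["spikes"].items():
            fh.write(
                f"spike\t{seq}\t{info['reference']},{info['end_class']},{info['count']}\n"
            )
            for var, c in info["variants"].items():
                fh.write(f"variant\t{var}\t{c}\n")


def library_spec_from_config(cfg: dict) -> LibrarySpec:
    """Build a LibrarySpec from a flat YAML/JSON-style mapping."""
    spikes = tuple(
        SpikeSpec(
            trf_sequence=s["trf_sequence"],
            source_reference_id=s["source_reference_id"],
            end_class=s["end_class"],
            count=int(s["count"]),
            end_jitter=int(s.get("end_jitter", 0)),
            jitter_fraction=float(s.get("jitter_fraction", 0.3)),
        )
        for s in cfg.get("spikes", [])
    )
    rlr = cfg.get("read_length_range", (15, 30))
    return LibrarySpec(
        spikes=spikes,
        background_reads=int(cfg.get("background_reads", 0)),
        decoy_reads=int(cfg.get("decoy_reads", 0)),
        read_length_range=(int(rlr[0]), int(rlr[1])),
        seed=int(cfg["seed"]),
    )
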