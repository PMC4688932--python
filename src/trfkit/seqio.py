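"""Sequence I/O, the tRNA reference data model and shared sequence utilities.

Sequences are stored internally in the DNA alphabet (``A C G T N``), as
sequenced cDNA: every fragment sequence printed in small-RNA cloning studies
is written with T.  RNA input is converted on read; the conversion is always
explicit (`normalize_sequence`), never implicit.

Coordinates over reference sequences are 1-based and inclusive throughout the
package, with the 3'-terminal CCA (when present) part of the mature sequence.
"""

from __future__ import annotations

import io as _io
import logging
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


def normalize_sequence(raw: str, alphabet_mode: str = "dna") -> str:
    """Normalize a raw sequence string to the internal DNA alphabet.

    Case-folds, strips whitespace and converts U->T when ``alphabet_mode`` is
    ``"rna"`` (or when U is present and mode is ``"dna"``, in which case the
    conversion is logged rather than silent).
    """
    seq = "".join(raw.split()).upper()
    if alphabet_mode not in ("dna", "rna"):
        raise ValueError(f"unknown alphabet_mode {alphabet_mode!r}")
    if "U" in seq:
        if alphabet_mode == "dna":
            logger.info("converting RNA residues (U) to DNA (T) on read")
        seq = seq.replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence {raw[:30]!r}...")
    return seq


def to_rna(seq: str) -> str:
    """Explicit DNA->RNA conversion (T->U)."""
    return seq.replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement in the same alphabet mode; N maps to N.

    Applying twice returns the input (involution).
    """
    rc = seq.translate(_COMPLEMENT)[::-1]
    if "U" in seq:  # keep RNA input in RNA
        rc = rc.replace("T", "U")
    return rc


@dataclass(frozen=True)
class RNAReference:
    """Any ncRNA reference sequence a read can be aligned against."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TRNAReference(RNAReference):
    """A mature tRNA sequence, the alignment substrate for tRF discovery.

    ``id`` follows the AminoAcid-Anticodon(-locus) convention, e.g. ``Pro-CGG``
    or ``Glu-CTC-2`` for isodecoders.  The sequence is the mature tRNA 5'->3'
    including the 3'-terminal CCA when present.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        aa, anticodon, _ = self.parse_id(self.id)
        if len(anticodon) != 3:
            raise ValueError(f"anticodon {anticodon!r} in {self.id!r} is not 3 nt")

    @staticmethod
    def parse_id(ref_id: str) -> tuple[str, str, str | None]:
        """Split an id into (amino_acid, anticodon, locus-or-None)."""
        parts = ref_id.split("-")
        if len(parts) < 2:
            raise ValueError(f"reference id {ref_id!r} is not AminoAcid-Anticodon(-locus)")
        aa, anticodon = parts[0], parts[1]
        locus = "-".join(parts[2:]) or None
        return aa, anticodon, locus

    @property
    def amino_acid(self) -> str:
        return self.parse_id(self.id)[0]

    @property
    def anticodon(self) -> str:
        return self.parse_id(self.id)[1]

    @property
    def family(self) -> str:
        """Isoacceptor family label (amino acid + anticodon, locus stripped)."""
        aa, anticodon, _ = self.parse_id(self.id)
        return f"{aa}-{anticodon}"

    @property
    def has_cca(self) -> bool:
        return self.sequence.endswith("CCA")


_GTRNADB_AA = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "SeC", "Ser", "Thr", "Trp", "Tyr",
    "Val", "iMet", "Sup", "Und",
}


def map_gtrnadb_id(header: str) -> str:
    """Map a GtRNAdb-style name (e.g. ``tRNA-Pro-CGG-1-1``) onto the internal
    AminoAcid-Anticodon(-locus) convention."""
    name = header.split()[0]
    if name.lower().startswith("trna-"):
        name = name[5:]
    parts = name.split("-")
    if len(parts) < 2 or parts[0] not in _GTRNADB_AA:
        raise ValueError(f"cannot map header {header!r} onto AminoAcid-Anticodon(-locus)")
    return "-".join(parts)


@dataclass
class ReadSet:
    """An ordered small-RNA read collection with an optional ground-truth
    record attached by the synthetic-library generator."""

    reads: list[str]
    source_label: str = ""
    truth: dict | None = None

    @property
    def total_read_count(self) -> int:
        return len(self.reads)


@dataclass
class CollapsedReadTable:
    """Distinct read sequences with their cloning frequencies.

    ``total_sncrna_reads`` may exceed the row sum: the library total can
    include small-ncRNA reads that are not tabulated (e.g. other ncRNA
    classes when mining processed GEO tables).
    """

    rows: dict[str, int] = field(default_factory=dict)
    total_sncrna_reads: int = 0

    def __post_init__(self) -> None:
        row_sum = sum(self.rows.values())
        if any(c < 1 for c in self.rows.values()):
            raise ValueError("collapsed counts must be >= 1")
        if row_sum > self.total_sncrna_reads:
            raise ValueError(
                f"row sum {row_sum} exceeds total_sncrna_reads {self.total_sncrna_reads}"
            )

    def __len__(self) -> int:
        return len(self.rows)


def collapse_reads(reads: ReadSet | Iterable[str]) -> CollapsedReadTable:
    """Collapse a read set to one row per distinct sequence.

    The table total equals the input read count, so the >3-read abundance
    rule downstream operates on cloning frequencies.
    """
    seqs = reads.reads if isinstance(reads, ReadSet) else list(reads)
    counts = Counter(seqs)
    return CollapsedReadTable(rows=dict(counts), total_sncrna_reads=len(seqs))


# ---------------------------------------------------------------------------
# FASTA / FASTQ / TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet_mode: str = "dna") -> list[tuple[str, str]]:
    """Read FASTA records as (header, normalized sequence) pairs, in order.

    Raises :class:`FastaParseError` (naming the line number) when sequence
    data precedes any header line.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"{path}:{lineno}: sequence line before any FASTA header"
            )
        break
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        records.append((rec.description, normalize_sequence(str(rec.seq), alphabet_mode)))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path, alphabet_mode: str = "dna") -> list[tuple[str, str]]:
    """Read FASTQ (Sanger offset-33) as (header, sequence) pairs.

    Quality values are parsed (format validation) but ignored: the upstream
    454 pipeline operates on called sequences.
    """
    return [
        (rec.description, normalize_sequence(str(rec.seq), alphabet_mode))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(
    path: str | Path, records: Iterable[tuple[str, str]], quality_char: str = "I"
) -> None:
    """Write FASTQ (Sanger offset-33) with a uniform placeholder quality:
    called sequences are the unit of analysis here, qualities carry no
    information downstream."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f"@{header}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_reference_fasta(
    path: str | Path, gtrnadb_names: bool = False
) -> list[TRNAReference]:
    """Read a mature-tRNA reference FASTA; headers must follow (or with
    ``gtrnadb_names=True`` be mappable onto) AminoAcid-Anticodon(-locus)."""
    refs = []
    for header, seq in read_fasta(path):
        ref_id = map_gtrnadb_id(header) if gtrnadb_names else header.split()[0]
        refs.append(TRNAReference(id=ref_id, sequence=seq))
    return refs


TOTAL_KEY = "total_sncrna_reads"


def write_count_table(path: str | Path, table: CollapsedReadTable) -> None:
    """Write a collapsed table as TSV: commented total, then sequence/count."""
    with open(path, "w") as fh:
        fh.write(f"# {TOTAL_KEY}={table.total_sncrna_reads}\n")
        fh.write("sequence\tcount\n")
        for seq, count in table.rows.items():
            fh.write(f"{seq}\t{count}\n")


def read_count_table(path: str | Path) -> CollapsedReadTable:
    rows: dict[str, int] = {}
    total = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith(TOTAL_KEY):
                    total = int(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if parts[0] == "sequence":
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            seq = normalize_sequence(parts[0])
            if seq in rows:
                raise ValueError(f"{path}:{lineno}: duplicate sequence {seq}")
            rows[seq] = int(parts[1])
    if total is None:
        total = sum(rows.values())
    return CollapsedReadTable(rows=rows, total_sncrna_reads=total)
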