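"""The published zebrafish tRF panel.

Ten fragments identified by deep sequencing of the zebrafish small-ncRNA
fraction: four 5'tRFs (fragments whose 5' end coincides with the mature
tRNA's 5' terminus) and six 3'tRFs (3'-coterminal fragments, half of which
carry the non-templated CCA tail).  Sequences are stored as sequenced cDNA
(DNA alphabet); read counts are the cloning frequencies reported for the
original 454 libraries.

These records drive the deterministic reference fixture, the discovery
regression and the dataset-mining query panel.
"""

from __future__ import annotations

from dataclasses import dataclass

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class PanelRecord:
    name: str
    sequence: str
    end_class: str
    reads: int
    expression: str


PANEL: tuple[PanelRecord, ...] = (
    PanelRecord("5′tRF-Lys-TTT", "GCCCGGATAGCTCAGTCGGTAGAGCATCAG", FIVE_PRIME, 4, "Adult tissues"),
    PanelRecord("5′tRF-Val-CAC", "GTTTCCGTAGTGTAGTGGTTATCACGTTCG", FIVE_PRIME, 4, "Adult tissues"),
    PanelRecord("5′tRF-Glu-CTC", "TCCCTGGTGGTCTAGTGGTTAGGATTCGGC", FIVE_PRIME, 26, "Development, adult tissues"),
    PanelRecord("5′tRF-Pro-CGG", "TAGGGGTATGATTCTCGC", FIVE_PRIME, 12, "Development, adult tissues"),
    PanelRecord("3′tRF-Ala-AGC", "AGAGGTAGCGGGATCGTTGCCC", THREE_PRIME, 16, "Adult tissues"),
    PanelRecord("3′tRF-Lys-CTT", "CAGGGTCGTGGGTTCGAGCCCC", THREE_PRIME, 4, "Adult tissues"),
    PanelRecord("3′tRF-Ile-AAT", "CAAGGTCGCGGGTTCGTTCCCC", THREE_PRIME, 6, "Adult tissues"),
    PanelRecord("3′tRF-Glu-CTC", "TCGATTCCCGGTCAGGGAACCA", THREE_PRIME, 24, "Development, adult tissues"),
    PanelRecord("3′tRF-Pro-AGG", "TCCCGGACGAGCCCCCA", THREE_PRIME, 13, "Development, adult tissues"),
    PanelRecord("3′tRF-Arg-TCG", "GTCCCTTCGTGGTCGCCA", THREE_PRIME, 7, "Adult tissues"),
)

#: antisense northern-blot probes for the validated fragments
PROBES: dict[str, str] = {
    "5′tRF-Lys-TTT": "CTGATGCTCTACCGACTGAGCTATCCGGGC",
    "5′tRF-Glu-CTC": "GCCGAATCCTAACCACTAGACCACCAGGGA",
    "5′tRF-Pro-CGG": "GCGAGAATCATACCCCTA",
    "3′tRF-Pro-AGG": "TGGGGGCTCGTCCGGGA",
    "3′tRF-Ala-AGC": "GGGCATCGATCCCGCTACCTCT",
}


def by_name(name: str) -> PanelRecord:
    for rec in PANEL:
        if rec.name == name:
            return rec
    raise KeyError(name)


def family_of(name: str) -> str:
    """Isoacceptor family label of a panel name, e.g. 5′tRF-Pro-CGG -> Pro-CGG."""
    return name.split("tRF-", 1)[1]


FIVE_PRIME_PANEL = tuple(r for r in PANEL if r.end_class == FIVE_PRIME)
THREE_PRIME_PANEL = tuple(r for r in PANEL if r.end_class == THREE_PRIME)
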