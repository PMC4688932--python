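"""miRNA-like target prediction and dual-reporter sensor design.

A tRF is treated like a miRNA guide: a 3'UTR window is a candidate site
when the tRF seed (positions 2–7 from the 5' end) pairs perfectly with the
antiparallel site and at most six of the remaining positions mismatch.
Candidate sites are then screened thermodynamically with a nearest-neighbor
stack-sum over the contiguous paired runs (Watson–Crick RNA stack free
energies, kcal/mol at 37 °C) against a configurable threshold.

The sensor designer emits the annealable oligo pair that plants two copies
of the complementary site (separated by an EcoRV spacer) into an XhoI–NheI
cloning site of a dual-fluorescence reporter 3'UTR — reproducing the
published primer pairs byte-exactly, including the 5'- and 3'-end mutant
sensors used to map which tRF positions drive silencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqio import normalize_sequence, reverse_complement

DEFAULT_SEED_RANGE = (2, 7)  # 1-based tRF positions, inclusive
DEFAULT_MAX_NONSEED_MISMATCHES = 6
DEFAULT_ENERGY_THRESHOLD = -15.0  # kcal/mol

#: Watson–Crick nearest-neighbor stack free energies (RNA, kcal/mol, 37 °C),
#: keyed by the guide-strand dinucleotide 5'->3' (T read as U).  Xia et al.
#: 1998 parameters; E(XY) == E(revcomp(XY)) by strand symmetry.
NN_STACK: dict[str, float] = {
    "AA": -0.93, "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08, "AG": -2.08,
    "CA": -2.11, "TG": -2.11,
    "GT": -2.24, "AC": -2.24,
    "GA": -2.35, "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

XHOI_OVERHANG = "TCGAG"
NHEI_OVERHANG = "CTAGA"
SPACER = "GGATATCC"  # carries one internal EcoRV site (GATATC)

#: control sensor site (not derived from any tRF); primer pair E–F
CONTROL_SITE = "TGACGTTCGAACTTACATAACT"

#: shipped mutation maps for the Pro-CGG sensor mutants: tRF position ->
#: replacement base at the complementary sensor-site position
PRO_CGG_MUT5 = {2: "C", 3: "A", 5: "T", 6: "T"}   # disrupts tRF nt 2,3,5,6
PRO_CGG_MUT3 = {13: "G", 14: "A", 16: "A", 17: "T"}  # disrupts tRF nt 13,14,16,17


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in _WC:
        return True
    return allow_gu and (a, b) in _WOBBLE


@dataclass(frozen=True)
class TargetSite:
    """A predicted tRF binding site on a 3'UTR (sense strand)."""

    utr_id: str
    site_start: int  # 1-based inclusive
    site_end: int
    site_sequence: str
    paired_region: tuple[bool, ...]  # per tRF position, 5'->3'
    seed_mismatches: int
    nonseed_mismatches: int
    duplex_energy: float
    confirmed: bool = False


def pairing_profile(
    trf: str, site: str, allow_gu: bool = False
) -> tuple[bool, ...]:
    """Antiparallel pairing states per tRF position: tRF position p (1-based)
    faces site position L-p+1."""
    if len(trf) != len(site):
        raise ValueError("tRF and site must have equal length")
    L = len(trf)
    return tuple(
        _pairs(trf[p], site[L - 1 - p], allow_gu) for p in range(L)
    )


def duplex_energy(
    trf: str,
    site: str,
    mismatch_penalty: float = 0.0,
    allow_gu: bool = False,
) -> float:
    """Nearest-neighbor stack-sum free energy of the antiparallel duplex.

    Adjacent paired positions contribute the Watson–Crick stack for the
    guide dinucleotide; terminal dangles are ignored and mismatches inside
    the paired span add ``mismatch_penalty`` each (0 by default, so a duplex
    with no complementary positions scores exactly 0 and any stacked pair
    gives a negative energy).  More pairing never raises the value.
    """
    paired = pairing_profile(trf, site, allow_gu)
    energy = 0.0
    for p in range(len(trf) - 1):
        if paired[p] and paired[p + 1]:
            energy += NN_STACK[trf[p : p + 2].replace("U", "T")]
    if mismatch_penalty:
        idx = [i for i, x in enumerate(paired) if x]
        if idx:
            energy += mismatch_penalty * sum(
                1 for i in range(idx[0], idx[-1] + 1) if not paired[i]
            )
    return energy


def find_target_sites(
    trf: str,
    utrs: list[tuple[str, str]],
    max_nonseed_mismatches: int = DEFAULT_MAX_NONSEED_MISMATCHES,
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
    allow_gu: bool = False,
) -> list[TargetSite]:
    """Scan 3'UTR sense strands for miRNA-style tRF binding sites.

    A window of tRF length qualifies when antiparallel pairing is perfect at
    the seed positions and has at most ``max_nonseed_mismatches`` elsewhere;
    G:U wobble counts as a mismatch unless ``allow_gu``.  UTRs shorter than
    the tRF are skipped.  Windows are reported in (utr, position) order with
    their stack-sum energies; run :func:`confirm_targets` to set the
    thermodynamic flag.
    """
    trf = normalize_sequence(trf)
    if len(trf) < 8:
        raise ValueError("tRF must be at least 8 nt for seed scanning")
    s_lo, s_hi = seed_range
    if not 1 <= s_lo <= s_hi <= len(trf):
        raise ValueError(f"seed range {seed_range} outside tRF positions")
    L = len(trf)
    seed_idx = range(s_lo - 1, s_hi)
    sites = []
    for utr_id, utr in utrs:
        utr = normalize_sequence(utr)
        if len(utr) < L:
            continue
        for start in range(len(utr) - L + 1):
            window = utr[start : start + L]
            paired = pairing_profile(trf, window, allow_gu)
            seed_mm = sum(1 for p in seed_idx if not paired[p])
            if seed_mm:
                continue
            nonseed_mm = sum(
                1 for p in range(L) if p not in seed_idx and not paired[p]
            )
            if nonseed_mm > max_nonseed_mismatches:
                continue
            sites.append(
                TargetSite(
                    utr_id=utr_id,
                    site_start=start + 1,
                    site_end=start + L,
                    site_sequence=window,
                    paired_region=paired,
                    seed_mismatches=0,
                    nonseed_mismatches=nonseed_mm,
                    duplex_energy=duplex_energy(trf, window, allow_gu=allow_gu),
                )
            )
    return sites


def confirm_targets(
    sites: list[TargetSite],
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
) -> list[TargetSite]:
    """Set the thermodynamic-confirmation flag: confirmed iff the duplex
    energy reaches the threshold.  Unconfirmed sites are retained (flagged)
    so callers can inspect what the screen removed."""
    return [
        replace(site, confirmed=site.duplex_energy <= energy_threshold)
        for site in sites
    ]


# ---------------------------------------------------------------------------
# Sensor cassettes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorCassette:
    """An annealable oligo pair planting two tRF-complementary sites into the
    XhoI–NheI site of a dual-fluorescence reporter 3'UTR."""

    trf: str
    site: str  # sensor site, sense strand of the reporter 3'UTR
    mutation_map: dict[int, str] = field(default_factory=dict)

    @property
    def top_strand(self) -> str:
        return XHOI_OVERHANG + self.site + SPACER + self.site + "T"

    @property
    def bottom_strand(self) -> str:
        rc = reverse_complement(self.site)
        return NHEI_OVERHANG + rc + SPACER + rc + "C"


def design_sensor(trf: str, mutation_map: dict[int, str] | None = None) -> SensorCassette:
    """Build the sensor cassette for a tRF.

    The site is the reverse complement of the tRF; ``mutation_map`` replaces
    the site base complementary to each given tRF position (position p of an
    L-nt tRF faces site position L-p+1), disrupting pairing there.
    """
    trf = normalize_sequence(trf)
    if len(trf) < 15:
        raise ValueError("tRF must be at least 15 nt for sensor design")
    mutation_map = dict(mutation_map or {})
    site = list(reverse_complement(trf))
    L = len(trf)
    for pos, base in mutation_map.items():
        if not 1 <= pos <= L:
            raise ValueError(f"mutation position {pos} outside 1..{L}")
        base = base.upper()
        idx = L - pos  # 0-based site index of site position L-pos+1
        if site[idx] == base:
            raise ValueError(
                f"replacement at tRF position {pos} equals the original site base"
            )
        site[idx] = base
    return SensorCassette(trf=trf, site="".join(site), mutation_map=mutation_map)


def audit_mutations(original: SensorCassette, mutated: SensorCassette) -> set[int]:
    """tRF positions whose pairing the mutated sensor disrupts, found by
    comparing the two sensor sites base-by-base (site position p maps to
    tRF position L-p+1)."""
    if original.trf != mutated.trf:
        raise ValueError("cassettes were designed for different tRFs")
    L = len(original.trf)
    return {
        L - i
        for i, (a, b) in enumerate(zip(original.site, mutated.site))
        if a != b
    }


def control_sensor() -> SensorCassette:
    """The shipped control cassette (primer pair E–F); its site is a named
    fixture, not derived from any tRF."""
    return SensorCassette(trf="", site=CONTROL_SITE)
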