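import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import stack_sum, window_sites
from conftest import random_seq
from trfkit import panel
from trfkit.seqio import reverse_complement
from trfkit.targets import (
    CONTROL_SITE,
    NN_STACK,
    PRO_CGG_MUT3,
    PRO_CGG_MUT5,
    SensorCassette,
    audit_mutations,
    confirm_targets,
    design_sensor,
    duplex_energy,
    find_target_sites,
)

PRO = panel.by_name("5′tRF-Pro-CGG").sequence
GLU = panel.by_name("5′tRF-Glu-CTC").sequence

# the published sensor primer pairs, written 5'->3'
PRIMERS = {
    "A": "TCGAGGCCGAATCCTAACCACTAGACCACCAGGGAGGATATCCGCCGAATCCTAACCACTAGACCACCAGGGAT",
    "B": "CTAGATCCCTGGTGGTCTAGTGGTTAGGATTCGGCGGATATCCTCCCTGGTGGTCTAGTGGTTAGGATTCGGCC",
    "C": "TCGAGGCGAGAATCATACCCCTAGGATATCCGCGAGAATCATACCCCTAT",
    "D": "CTAGATAGGGGTATGATTCTCGCGGATATCCTAGGGGTATGATTCTCGCC",
    "E": "TCGAGTGACGTTCGAACTTACATAACTGGATATCCTGACGTTCGAACTTACATAACTT",
    "F": "CTAGAAGTTATGTAAGTTCGAACGTCAGGATATCCAGTTATGTAAGTTCGAACGTCAC",
    "G": "TCGAGGCGAGAATCATATTCACAGGATATCCGCGAGAATCATATTCACAT",
    "H": "CTAGATGTGAATATGATTCTCGCGGATATCCTGTGAATATGATTCTCGCC",
    "I": "TCGAGGTAAAGATCATACCCCTAGGATATCCGTAAAGATCATACCCCTAT",
    "J": "CTAGATAGGGGTATGATCTTTACGGATATCCTAGGGGTATGATCTTTACC",
}


class TestSensorDesign:
    @pytest.mark.parametrize(
        "trf,mutations,top,bottom",
        [
            (GLU, None, "A", "B"),
            (PRO, None, "C", "D"),
            (PRO, PRO_CGG_MUT5, "G", "H"),
            (PRO, PRO_CGG_MUT3, "I", "J"),
        ],
    )
    def test_reproduces_published_primer_pairs(self, trf, mutations, top, bottom):
        cassette = design_sensor(trf, mutations)
        assert cassette.top_strand == PRIMERS[top]
        assert cassette.bottom_strand == PRIMERS[bottom]

    def test_control_cassette_matches_published_pair(self):
        control = SensorCassette(trf="", site=CONTROL_SITE)
        assert control.top_strand == PRIMERS["E"]
        assert control.bottom_strand == PRIMERS["F"]

    def test_annealed_strands_are_complementary_with_cloning_overhangs(self):
        cassette = design_sensor(PRO)
        top, bottom = cassette.top_strand, cassette.bottom_strand
        # XhoI leaves 5'-TCGA, NheI leaves 5'-CTAG; the cores anneal exactly
        assert top.startswith("TCGA") and bottom.startswith("CTAG")
        assert top[4:] == reverse_complement(bottom)[:-4]
        # one EcoRV site per spacer copy
        assert top.count("GATATC") == 1

    def test_mutation_audits(self):
        base = design_sensor(PRO)
        assert audit_mutations(base, design_sensor(PRO, PRO_CGG_MUT5)) == {2, 3, 5, 6}
        assert audit_mutations(base, design_sensor(PRO, PRO_CGG_MUT3)) == {13, 14, 16, 17}
        assert audit_mutations(base, base) == set()

    def test_mutation_position_validation(self):
        with pytest.raises(ValueError, match="outside"):
            design_sensor(PRO, {0: "A"})
        with pytest.raises(ValueError, match="outside"):
            design_sensor(PRO, {19: "A"})
        site = reverse_complement(PRO)
        with pytest.raises(ValueError, match="equals the original"):
            design_sensor(PRO, {2: site[16]})

    def test_short_trf_rejected(self):
        with pytest.raises(ValueError):
            design_sensor("ACGTACGTACGT")

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_audit_recovers_mutation_domain(self, data):
        trf = data.draw(st.text(alphabet="ACGT", min_size=15, max_size=30))
        positions = data.draw(
            st.sets(st.integers(1, len(trf)), min_size=0, max_size=5)
        )
        site = reverse_complement(trf)
        mut = {}
        for p in positions:
            original = site[len(trf) - p]
            mut[p] = data.draw(st.sampled_from(sorted(set("ACGT") - {original})))
        assert audit_mutations(design_sensor(trf), design_sensor(trf, mut)) == set(mut)


class TestDuplexEnergy:
    def test_gc_duplex_more_stable_than_au(self):
        gc = "GCGCGCGCGC"
        au = "ATATATATAT"
        assert duplex_energy(gc, reverse_complement(gc)) < duplex_energy(
            au, reverse_complement(au)
        )

    def test_no_complementarity_scores_zero(self):
        # site pairs nowhere with the tRF
        assert duplex_energy("AAAAAAAAAA", "CCCCCCCCCC") == 0.0

    def test_any_stack_is_negative(self):
        site = list("CCCCCCCCCC")
        # create two adjacent pairs only
        site[-1], site[-2] = "T", "T"
        assert duplex_energy("AAAAAAAAAA", "".join(site)) < 0

    def test_matches_direct_table_sum_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            L = int(rng.integers(8, 25))
            trf = random_seq(rng, L)
            if rng.random() < 0.5:
                site = list(reverse_complement(trf))
                for pos in rng.choice(L, size=int(rng.integers(0, 6)), replace=False):
                    site[pos] = "ACGT"[int(rng.integers(0, 4))]
                site = "".join(site)
            else:
                site = random_seq(rng, L)
            assert duplex_energy(trf, site) == pytest.approx(
                stack_sum(trf, site, NN_STACK), abs=1e-9
            )

    def test_pairing_a_mismatch_never_raises_energy(self):
        rng = np.random.default_rng(13)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(100):
            L = int(rng.integers(10, 22))
            trf = random_seq(rng, L)
            site = list(random_seq(rng, L))
            before = duplex_energy(trf, "".join(site))
            mismatched = [
                p for p in range(L) if site[L - 1 - p] != comp[trf[p]]
            ]
            if not mismatched:
                continue
            p = mismatched[int(rng.integers(0, len(mismatched)))]
            site[L - 1 - p] = comp[trf[p]]
            assert duplex_energy(trf, "".join(site)) <= before + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("ACGTACGT", "ACGTACG")


class TestFindTargetSites:
    def test_printed_sensor_insert_carries_two_perfect_sites(self):
        cassette = design_sensor(PRO)
        sites = find_target_sites(PRO, [("insert", cassette.top_strand)])
        assert len(sites) == 2
        assert all(s.nonseed_mismatches == 0 and s.seed_mismatches == 0 for s in sites)
        assert all(all(s.paired_region) for s in sites)

    def test_seed_substitution_rejects_site(self):
        cassette = design_sensor(PRO)
        utr = list(cassette.top_strand)
        first = find_target_sites(PRO, [("insert", cassette.top_strand)])[0]
        # break pairing opposite tRF position 4 (inside the 2-7 seed)
        idx = first.site_start - 1 + (len(PRO) - 4)
        utr[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[utr[idx]]
        sites = find_target_sites(PRO, [("mut", "".join(utr))])
        assert all(s.site_start != first.site_start for s in sites)

    @pytest.mark.parametrize("n_mm,accepted", [(6, True), (7, False)])
    def test_nonseed_mismatch_boundary(self, n_mm, accepted):
        rng = np.random.default_rng(99)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        trf = PRO
        L = len(trf)
        site = list(reverse_complement(trf))
        nonseed_positions = [p for p in range(1, L + 1) if not 2 <= p <= 7]
        chosen = rng.choice(nonseed_positions, size=n_mm, replace=False)
        for p in chosen:
            idx = L - p
            wrong = sorted(set("ACGT") - {comp[trf[p - 1]], })
            site[idx] = wrong[int(rng.integers(0, len(wrong)))]
        sites = find_target_sites(trf, [("u", "".join(site))])
        assert bool(sites) is accepted
        if accepted:
            assert sites[0].nonseed_mismatches == n_mm

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            trf = random_seq(rng, int(rng.integers(15, 25)))
            utr = random_seq(rng, 300)
            # plant a near-complementary window to make hits likely
            insert = list(reverse_complement(trf))
            for pos in rng.choice(len(trf), size=4, replace=False):
                insert[pos] = "ACGT"[int(rng.integers(0, 4))]
            pos = int(rng.integers(0, 300 - len(trf)))
            utr = utr[:pos] + "".join(insert) + utr[pos + len(trf):]
            got = [
                (s.site_start, s.nonseed_mismatches)
                for s in find_target_sites(trf, [("u", utr)])
            ]
            assert got == window_sites(trf, utr)

    def test_seed_only_depends_on_seed_positions(self):
        """Permuting the tRF tail changes mismatch counts, never seed status."""
        rng = np.random.default_rng(3)
        trf = PRO
        utr = random_seq(rng, 400)
        starts = {s.site_start for s in find_target_sites(trf, [("u", utr)], 999)}
        tail = list(trf[7:])
        rng.shuffle(tail)
        permuted = trf[:7] + "".join(tail)
        starts_p = {
            s.site_start for s in find_target_sites(permuted, [("u", utr)], 999)
        }
        assert starts == starts_p

    def test_short_utr_skipped(self):
        assert find_target_sites(PRO, [("short", "ACGT")]) == []

    def test_short_trf_rejected(self):
        with pytest.raises(ValueError):
            find_target_sites("ACGTACG", [("u", "ACGT" * 20)])


class TestConfirmTargets:
    def test_perfect_complement_confirmed_at_default_threshold(self):
        site = reverse_complement(PRO)
        sites = confirm_targets(find_target_sites(PRO, [("u", site)]))
        assert len(sites) == 1 and sites[0].confirmed
        assert sites[0].duplex_energy <= -15

    def test_weak_au_duplex_not_confirmed(self):
        # an AU-rich guide with a clustered 6-mismatch block leaves only
        # weak short stacks: the site passes the seed/mismatch rule but
        # fails the thermodynamic screen
        trf = "ATATATATATATATATAT"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        site = list(reverse_complement(trf))
        for p in (9, 10, 11, 12, 13, 14):  # non-seed block
            site[len(trf) - p] = "C"
        sites = confirm_targets(find_target_sites(trf, [("u", "".join(site))]))
        assert len(sites) >= 1
        target = next(s for s in sites if s.nonseed_mismatches == 6)
        expected = stack_sum(trf, target.site_sequence, NN_STACK)
        assert target.duplex_energy == pytest.approx(expected)
        assert expected > -15 and not target.confirmed

    def test_infinite_threshold_confirms_everything(self):
        rng = np.random.default_rng(1)
        utr = random_seq(rng, 200)
        # plant a seed-matching site with a heavily mismatched tail
        insert = list(reverse_complement(PRO))
        for p in (1, 9, 10, 11, 12, 14, 16, 18):  # non-seed tRF positions
            idx = len(PRO) - p
            insert[idx] = "C" if insert[idx] != "C" else "A"
        utr = utr[:50] + "".join(insert) + utr[50 + len(PRO):]
        sites = find_target_sites(PRO, [("u", utr)], max_nonseed_mismatches=12)
        confirmed = confirm_targets(sites, energy_threshold=float("inf"))
        assert confirmed and all(s.confirmed for s in confirmed)
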