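import numpy as np
import pytest

from gliadinkit import domain_grammar as dg
from gliadinkit import motif_epitope as me
from tests.conftest import random_protein


@pytest.fixture(scope="module")
def library():
    return me.load_epitope_library()


def brute_force_hits(protein, motifs):
    """Naive all-window exact-match oracle."""
    out = set()
    for motif in motifs:
        for i in range(len(protein) - len(motif) + 1):
            if protein[i : i + len(motif)] == motif:
                out.add((i + 1, motif))
    return out


class TestScan:
    def test_planted_epitope_reported_once_at_its_position(self, library):
        protein = "MKTAVLENW" + "FRPQQPYPQ" + "GSHTLKDE" * 4
        hits = me.scan_epitopes(protein, library)
        a3 = [h for h in hits if "DQ2.5-glia-α3" in h.epitope_names]
        assert len(a3) == 1 and a3[0].start == 10

    def test_overlapping_matches_allowed(self, library):
        hits = me.scan_epitopes("QQQPQQQP", library)
        qqqp = sorted(h.start for h in hits if h.sequence == "QQQP")
        assert qqqp == [1, 5]

    def test_shared_sequence_epitopes_collapse_to_one_hit(self, library):
        hits = me.scan_epitopes("AAAQQPQQPFPQAAA", library)
        (hit,) = [h for h in hits if h.sequence == "QQPQQPFPQ"]
        assert hit.epitope_names == ["DQ2.5-glia-γ4c", "DQ8-glia-γ1a"]

    def test_matches_bruteforce_oracle_on_random_sequences(self, library):
        rng = np.random.default_rng(17)
        motifs = {e.sequence for e in library}
        for _ in range(25):
            protein = random_protein(rng, 500, alphabet="QPFLSYAI")
            got = {(h.start, h.sequence) for h in me.scan_epitopes(protein, library)}
            assert got == brute_force_hits(protein, motifs)

    def test_domain_label_is_the_hit_start_domain(self, family, library):
        for gid in sorted(family.actives)[:8]:
            t = family.truth.genes[gid]
            ann = dg.segment_domains(t.protein, t.gliadin_type, gid)
            for hit in me.scan_epitopes(t.protein, library, ann):
                assert hit.domain_label == ann.domain_of(hit.start)

    def test_planted_epitopes_recovered_from_ground_truth(self, family, library):
        for gid in family.actives:
            t = family.truth.genes[gid]
            found = {
                (n, h.start)
                for h in me.scan_epitopes(t.protein, library)
                for n in h.epitope_names
            }
            for name, pos in t.planted_epitopes:
                assert (name, pos) in found, (gid, name, pos)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            me.scan_epitopes("QQPQPQ", [])


class TestLibrary:
    def test_expected_composition(self, library):
        names = {e.name for e in library}
        assert len(library) == 33
        assert {"DQ2.5-glia-α1a", "DQ8-glia-α1", "DQ2.5-glia-γ4d",
                "DQ2.5-glia-ω2", "tetra-QQQP", "hexa-QQPPQQ",
                "hexa-QQFPQQ"} <= names
        by_seq = {}
        for e in library:
            by_seq.setdefault(e.sequence, set()).add(e.name)
        assert by_seq["QQPQQPFPQ"] == {"DQ2.5-glia-γ4c", "DQ8-glia-γ1a"}
        assert by_seq["QQPQQPYPQ"] == {"DQ2.5-glia-γ3", "DQ8-glia-γ1b"}
        assert by_seq["PQQSFPQQQ"] == {"DQ2.5-glia-γ1", "DQ8.5-glia-γ1"}


class TestNearMiss:
    def test_published_s_for_p_disruption(self):
        # DQ2.5-glia-α2 with serine instead of proline at its 8th residue
        report = me.near_miss_report("AAPQPQLPYSQAA", "PQPQLPYPQ")
        assert (3, 8, "S", "P") in report

    def test_exact_match_windows_excluded(self):
        assert me.near_miss_report("PQPQLPYPQ", "PQPQLPYPQ") == []

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(23)
        motif = "PQPQLPYPQ"
        for _ in range(20):
            protein = random_protein(rng, 200, alphabet="QPLYS")
            expected = []
            for i in range(len(protein) - len(motif) + 1):
                w = protein[i : i + len(motif)]
                diff = [j for j in range(len(motif)) if w[j] != motif[j]]
                if len(diff) == 1:
                    expected.append((i + 1, diff[0] + 1, w[diff[0]], motif[diff[0]]))
            assert me.near_miss_report(protein, motif) == expected


class TestCysteines:
    def test_gamma_skeleton_six_in_iii_two_in_v(self, family):
        gid = next(
            g for g in sorted(family.actives)
            if family.truth.genes[g].gliadin_type == "gamma"
        )
        t = family.truth.genes[gid]
        ann = dg.segment_domains(t.protein, "gamma", gid)
        prof = me.cysteine_profile(t.protein, ann)
        assert prof.total == 8
        assert prof.per_domain["III"] == 6 and prof.per_domain["V"] == 2

    def test_omega_is_cysteine_free(self, family):
        gid = next(
            g for g in sorted(family.actives)
            if family.truth.genes[g].gliadin_type == "omega"
        )
        assert me.cysteine_profile(family.truth.genes[gid].protein).total == 0

    def test_positions_and_totals(self):
        prof = me.cysteine_profile("ACCA")
        assert prof.total == 2 and prof.positions == [2, 3]

    def test_positional_moves_against_reference(self):
        prof = me.cysteine_profile("AACAAAAA", reference_protein="AAAAAACA")
        assert prof.moved_positions == [(7, 3)]


class TestRepeatUnits:
    def test_tandem_octapeptides(self):
        assert me.count_repeat_units("PFPQQPQQPFPQQPQQ", "PFPQQPQQ") == 2

    def test_unit_family_matches_longest_first(self):
        region = "PFPQQPQQPQQ" + "PFPQPQQ"
        assert me.count_repeat_units(region, dg.GAMMA_REPEAT_UNITS) == 2

    def test_overlapping_count_never_below_greedy(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            s = random_protein(rng, 150, alphabet="QPF")
            for motif in ("QQQP", "PFPQQPQQ", "QPQ"):
                assert me.count_repeat_units(s, motif) <= me.count_repeat_units(
                    s, motif, allow_overlap=True
                )

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            me.count_repeat_units("QQQ", "")


class TestQpfAndOmega:
    def test_exact_431(self):
        fracs, ratio = me.qpf_ratio("QQQQPPPF")
        assert ratio == (4, 3, 1)
        assert fracs == (0.5, 0.375, 0.125)

    def test_degenerate_region(self):
        assert me.qpf_ratio("QP")[1] == (1, 1, 0)
        with pytest.raises(ValueError):
            me.qpf_ratio("AAAA")
        with pytest.raises(ValueError):
            me.qpf_ratio("")

    def test_generated_omega_composition_near_431(self, family):
        for gid in family.actives:
            t = family.truth.genes[gid]
            if t.gliadin_type != "omega":
                continue
            ann = dg.segment_domains(t.protein, "omega", gid)
            fracs, _ = me.qpf_ratio(ann.mature_protein)
            for got, want in zip(fracs, me.ARQE_QPF_FRACTIONS):
                assert abs(got - want) <= 0.05

    @pytest.mark.parametrize(
        "mature,expected",
        [
            ("ARQ" + "QQQQPPPF" * 10, "ARQ/E"),
            ("ARE" + "QQQQPPPF" * 10, "ARQ/E"),
            ("KEL" + "AAAA" * 10, "KEL"),
            ("SRL" + "AAAA" * 10, "SRL"),
            ("TRQ" + "AAAA" * 10, "TRQ"),
            ("ARH" + "QQQQPPPF" * 10, "ARQ/E-like variant"),
            ("MNO" + "AAAAQ" * 10, "unknown"),
        ],
    )
    def test_omega_typing_rules(self, mature, expected):
        assert me.classify_omega(mature) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            me.classify_omega("AR")


class TestAlphaGroups:
    @staticmethod
    def _annotated(group):
        from gliadinkit.synthetic import SimConfig, generate_family

        weights = {"I": 0.0, "II": 0.0, "III": 0.0, "none": 0.0}
        weights[group] = 1.0
        cfg = SimConfig(seed=31, n_alpha=3, n_gamma=0, n_omega=0,
                        pseudogene_fraction=0.0, n_duplicate_pairs=0,
                        alpha_group_weights=weights, alpha_19mer_rate=1.0)
        _, truth = generate_family(cfg, np.random.default_rng(31))
        gid = truth.active_ids()[0]
        t = truth.genes[gid]
        ann = dg.segment_domains(t.protein, "alpha", gid)
        hits = me.scan_epitopes(t.protein, me.load_epitope_library(), ann)
        return ann, hits

    @pytest.mark.parametrize(
        "group,expected",
        [("I", "I"), ("II", "II"), ("III", "III"), ("none", "unclassified")],
    )
    def test_group_rules_on_constructed_genes(self, group, expected):
        ann, hits = self._annotated(group)
        assert me.classify_alpha_group(ann, hits) == expected

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError):
            me.classify_alpha_group(None, [])
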