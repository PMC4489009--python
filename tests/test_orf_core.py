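import numpy as np
import pytest

from gliadinkit import orf_core
from gliadinkit.synthetic import SimConfig, generate_family, random_c_to_t, reverse_translate

# independent genetic-code oracle: codons in TCAG x TCAG x TCAG order
_BASES = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def _random_stop_free_cds(rng, n_codons):
    codons = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    out = ["ATG"] + [codons[i] for i in rng.integers(0, len(codons), size=n_codons - 1)]
    return "".join(out)


class TestTranslate:
    def test_simple(self):
        assert orf_core.translate_cds("ATGGGT") == "MG"

    def test_matches_codon_by_codon_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cds = _random_stop_free_cds(rng, 300)
            expected = "".join(
                CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3)
            )
            got = orf_core.translate_cds(cds)
            assert got == expected
            assert len(got) == 300

    def test_rejects_frameshifted_and_illegal_input(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            orf_core.translate_cds("ATGGG")
        with pytest.raises(ValueError, match="illegal"):
            orf_core.translate_cds("ATGXYZ")
        with pytest.raises(ValueError):
            orf_core.translate_cds("")

    def test_terminal_stop_trimmed_with_warning(self):
        with pytest.warns(UserWarning, match="trimming"):
            assert orf_core.trim_terminal_stop("ATGGGTTAA") == "ATGGGT"

    def test_missing_start_warns_not_errors(self):
        with pytest.warns(UserWarning, match="ATG"):
            assert orf_core.translate_cds("GGGGGT") == "GG"


class TestInternalStops:
    def test_planted_mutation_found_at_its_codon(self):
        rng = np.random.default_rng(1)
        cds = _random_stop_free_cds(rng, 100)
        mutated = cds[:147] + "TAG" + cds[150:]  # codon 50
        events = orf_core.find_internal_stops(mutated)
        assert [(e.codon_index, e.observed_codon) for e in events] == [(50, "TAG")]

    def test_full_orf_yields_empty_list(self):
        rng = np.random.default_rng(2)
        assert orf_core.find_internal_stops(_random_stop_free_cds(rng, 80)) == []

    def test_counts_match_generator_ground_truth(self, family):
        for gid, t in family.truth.genes.items():
            if t.status == orf_core.PSEUDO_STOP:
                events = orf_core.find_internal_stops(t.cds)
                assert [e.codon_index for e in events] == [
                    idx for idx, _ in t.stop_events
                ]
                assert 1 <= len(events) <= 3


class TestStopOrigin:
    @pytest.mark.parametrize(
        "observed,reference,origin",
        [
            ("TAG", "CAG", "CAG->TAG"),
            ("TAA", "CAA", "CAA->TAA"),
            ("TGA", "CGA", "CGA->TGA"),
            ("TAA", "AAA", orf_core.ORIGIN_UNEXPLAINED),
            ("TAG", "CAA", orf_core.ORIGIN_UNEXPLAINED),
        ],
    )
    def test_single_c_to_t_rule(self, observed, reference, origin):
        ev = orf_core.StopCodonEvent(codon_index=5, observed_codon=observed)
        assert orf_core.classify_stop_origin(ev, reference).origin == origin

    def test_gapped_reference_is_frameshift_induced(self):
        ev = orf_core.StopCodonEvent(codon_index=5, observed_codon="TAA")
        assert (
            orf_core.classify_stop_origin(ev, "C-A").origin
            == orf_core.ORIGIN_FRAMESHIFT
        )


class TestFrameshift:
    def test_single_base_deletion_at_471(self):
        rng = np.random.default_rng(3)
        ref = _random_stop_free_cds(rng, 200)
        # make bp 471 (1-based) an unambiguous A
        ref = ref[:469] + "CAG" + ref[472:]  # bp 470..472 = C,A,G
        observed = ref[:470] + ref[471:]
        events = orf_core.detect_frameshift(observed, ref)
        assert [(e.cds_position, e.kind, e.length) for e in events] == [
            (471, "deletion", 1)
        ]

    def test_identical_sequences_no_events(self):
        rng = np.random.default_rng(4)
        ref = _random_stop_free_cds(rng, 150)
        assert orf_core.detect_frameshift(ref, ref) == []

    def test_planted_insertions_recovered(self):
        rng = np.random.default_rng(5)
        ref = _random_stop_free_cds(rng, 250)
        for _ in range(20):
            p = int(rng.integers(30, len(ref) - 30))
            base = next(b for b in "ACGT" if b != ref[p] and b != ref[p - 1])
            observed = ref[:p] + base + ref[p:]
            events = orf_core.detect_frameshift(observed, ref)
            assert [(e.cds_position, e.kind, e.length) for e in events] == [
                (p + 1, "insertion", 1)
            ]

    def test_in_frame_indels_not_reported(self):
        rng = np.random.default_rng(6)
        ref = _random_stop_free_cds(rng, 150)
        observed = ref[:90] + ref[96:]  # clean 6-bp deletion
        assert orf_core.detect_frameshift(observed, ref) == []


class TestClassifyOrf:
    def test_panel_members_are_full_orf(self, family):
        panel = {g: family.truth.genes[g].cds for g in family.actives}
        for gid in list(family.actives)[:6]:
            res = orf_core.classify_orf(panel[gid], panel, gene_id=gid)
            assert res.status == orf_core.FULL_ORF
            assert res.stop_events == [] and res.frameshift_events == []

    def test_planted_cag_mutant_of_panel_member(self, family):
        gid = sorted(family.actives)[0]
        cds = family.truth.genes[gid].cds
        i = cds.find("CAG", 60)
        i -= i % 3  # snap to codon start
        while cds[i : i + 3] != "CAG":
            i = cds.find("CAG", i + 3)
            i -= i % 3
        mutant = cds[:i] + "TAG" + cds[i + 3 :]
        panel = {g: family.truth.genes[g].cds for g in family.actives}
        res = orf_core.classify_orf(mutant, panel)
        assert res.status == orf_core.PSEUDO_STOP
        assert [e.origin for e in res.stop_events] == ["CAG->TAG"]
        assert res.stop_events[0].codon_index == i // 3 + 1

    def test_simulated_family_status_and_origin_recovery(self, family):
        panel = {g: family.truth.genes[g].cds for g in family.actives}
        for gid, t in family.truth.genes.items():
            res = orf_core.classify_orf(t.cds, panel, gene_id=gid)
            assert res.status == t.status
            if t.status == orf_core.PSEUDO_STOP:
                assert [[e.codon_index, e.origin] for e in res.stop_events] == t.stop_events
            if t.status == orf_core.PSEUDO_FRAMESHIFT:
                assert [
                    [e.cds_position, e.kind, e.length] for e in res.frameshift_events
                ] == t.frameshift_events

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            orf_core.classify_orf("", {})


def test_uniform_c_to_t_mutations_enrich_stops_at_q_codons():
    """Under uniform C→T pressure, new stops should sit at glutamine codons
    far more often than glutamine's share of codons would predict."""
    rng = np.random.default_rng(11)
    cfg = SimConfig(seed=11, n_alpha=1000, n_gamma=0, n_omega=0,
                    pseudogene_fraction=0.0, n_duplicate_pairs=0)
    _, truth = generate_family(cfg, rng)
    stops_at_q = stops_total = q_codons = codons_total = 0
    for t in truth.genes.values():
        cds = t.cds
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        q_codons += sum(c in ("CAA", "CAG") for c in codons)
        codons_total += len(codons)
        mutated, pos = random_c_to_t(cds, rng)
        new = orf_core.find_internal_stops(mutated)
        for ev in new:
            stops_total += 1
            stops_at_q += codons[ev.codon_index - 1] in ("CAA", "CAG")
    assert stops_total > 50
    enrichment = (stops_at_q / stops_total) / (q_codons / codons_total)
    assert enrichment > 1
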