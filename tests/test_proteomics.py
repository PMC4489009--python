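import numpy as np
import pytest
from pyteomics import parser as pyt_parser

from gliadinkit import proteomics as pt
from gliadinkit.seqio import SpotTableRow, load_reference_spot_table
from tests.conftest import random_protein

CHYMO_REGEX = r"(?<=[FYWLM])(?!P)"


def oracle_digest(protein, max_missed, min_len):
    """Brute-force window enumeration: a peptide is any window bounded by
    the protein ends or cleavage points, with <= max_missed internal points."""
    cuts = {
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "FYWLM" and protein[i + 1] != "P"
    }
    bounds = {0, len(protein)} | cuts
    out = set()
    for i in range(len(protein)):
        for j in range(i + 1, len(protein) + 1):
            if i in bounds and j in bounds:
                internal = sum(1 for c in cuts if i < c < j)
                if internal <= max_missed and j - i >= min_len:
                    out.add((i + 1, protein[i:j]))
    return out


class TestDigest:
    def test_no_cleavage_before_proline(self):
        peps = pt.chymotryptic_digest("AAFGGYPKKW", max_missed=0, min_len=1)
        assert [p.sequence for p in peps] == ["AAF", "GGYPKKW"]

    def test_observed_unique_peptide_needs_missed_cleavage(self):
        # QPQQLPQFEEIRN spans an F|E cut, so it only exists at >=1 missed
        full = [
            p
            for p in pt.chymotryptic_digest("QPQQLPQFEEIRN", max_missed=2, min_len=5)
            if p.sequence == "QPQQLPQFEEIRN"
        ]
        assert full and all(p.missed_cleavages >= 1 for p in full)
        zero = pt.chymotryptic_digest("QPQQLPQFEEIRN", max_missed=0, min_len=5)
        assert "QPQQLPQFEEIRN" not in {p.sequence for p in zero}

    def test_zero_missed_peptides_tile_the_protein(self):
        rng = np.random.default_rng(71)
        for _ in range(20):
            protein = random_protein(rng, int(rng.integers(20, 120)))
            peps = pt.chymotryptic_digest(protein, max_missed=0, min_len=1)
            assert "".join(p.sequence for p in sorted(peps, key=lambda p: p.start)) == protein

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(73)
        for _ in range(25):
            protein = random_protein(rng, int(rng.integers(15, 60)))
            got = {
                (p.start, p.sequence)
                for p in pt.chymotryptic_digest(protein, max_missed=2, min_len=5)
            }
            assert got == oracle_digest(protein, max_missed=2, min_len=5)

    def test_matches_pyteomics_cleave(self):
        rng = np.random.default_rng(79)
        for _ in range(15):
            protein = random_protein(rng, 80)
            ours = {
                p.sequence
                for p in pt.chymotryptic_digest(protein, max_missed=2, min_len=1)
            }
            theirs = pyt_parser.cleave(protein, CHYMO_REGEX, missed_cleavages=2)
            assert ours == set(theirs)

    def test_monoisotopic_masses_positive(self):
        peps = pt.chymotryptic_digest("MKWITFISLLFLFSSAYS", max_missed=1, min_len=3)
        assert all(p.monoisotopic_mass > 300 for p in peps)


class TestMatching:
    PROTEOME = {
        "g1": "MKTAAAPEPTIDEONEGGG",
        "g2": "MKTAAAPEPTIDETWOGGG",
        "g3": "MKTAAAPEPTIDETWOGGH",
    }

    def test_single_owner(self):
        m = pt.match_peptides(["PEPTIDEONE"], self.PROTEOME)
        assert m["PEPTIDEONE"] == {"g1"}

    def test_shared_across_near_identical_proteins(self):
        m = pt.match_peptides(["PEPTIDETWO"], self.PROTEOME)
        assert m["PEPTIDETWO"] == {"g2", "g3"}

    def test_matches_naive_substring_oracle(self):
        rng = np.random.default_rng(83)
        proteome = {f"p{i}": random_protein(rng, 120, "QPFLS") for i in range(6)}
        peptides = [random_protein(rng, 6, "QPFLS") for _ in range(40)]
        got = pt.match_peptides(peptides, proteome)
        for pep in peptides:
            assert got[pep] == {g for g, s in proteome.items() if pep in s}

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            pt.match_peptides(["AAA"], {})


class TestSpotAssignment:
    def test_shared_plus_one_unique_peptide(self):
        proteome = {
            "Gli-a2": "AASHAREDPEPAQPQQLPQFEEIRNZZ".replace("Z", "G"),
            "Gli-a3": "AASHAREDPEPAGGGGGGGGGGGGG",
        }
        shared = ["SHAREDPEP"] * 6
        a = pt.assign_spot(1, shared + ["QPQQLPQFEEIRN"], proteome)
        assert a.unique and a.matched_genes == ["Gli-a2"]
        assert a.unique_peptides == {"Gli-a2": ["QPQQLPQFEEIRN"]}

    def test_all_shared_gives_ambiguous_pair(self):
        proteome = {"g10": "AAACOMMONBBB", "g11": "CCCCOMMONDDD"}
        a = pt.assign_spot(6, ["COMMON"] * 6, proteome)
        assert not a.unique and a.matched_genes == ["g10", "g11"]

    def test_one_peptide_one_protein_is_unique(self):
        a = pt.assign_spot(2, ["ONLYME"], {"g": "XXONLYMEXX", "h": "YYY"})
        assert a.unique and a.matched_genes == ["g"]

    def test_unmatched_spot_is_unassigned(self):
        a = pt.assign_spot(3, ["WWWWW"], {"g": "AAAA"})
        assert a.matched_genes == [] and not a.unique

    def test_unique_call_stable_under_shared_peptide_removal(self):
        proteome = {
            "g1": "AASHAREDONEBBSHAREDTWOCCUNIQUEBIT",
            "g2": "AASHAREDONEBBSHAREDTWOCCDDDDDDDD",
        }
        peps = ["SHAREDONE", "SHAREDTWO", "UNIQUEBIT"]
        base = pt.assign_spot(1, peps, proteome)
        assert base.unique
        for drop in ("SHAREDONE", "SHAREDTWO"):
            again = pt.assign_spot(1, [p for p in peps if p != drop], proteome)
            assert again.unique and again.matched_genes == base.matched_genes

    def test_round_trip_on_generated_spots(self, family):
        hit = 0
        for row in family.spots:
            a = pt.assign_spot(row.spot_id, row.peptides, family.proteins)
            st = family.spot_truth[row.spot_id]
            hit += sorted(a.matched_genes) == sorted(st["genes"]) and a.unique == st["unique"]
        assert hit / len(family.spots) >= 0.95


class TestVolumes:
    def test_reference_table_aggregation(self):
        volumes = pt.aggregate_volumes(load_reference_spot_table())
        assert volumes["per_gene"]["Gli-γ-1"] == pytest.approx(49.27)
        assert volumes["per_class"]["γ"] == pytest.approx(53.39)
        assert volumes["per_group"]["Gli-α-10+Gli-α-11"] == pytest.approx(18.79)
        assert volumes["total"] == pytest.approx(100.01)
        assert not volumes["total_exceeds_tolerance"]

    def test_single_spot_full_volume(self):
        rows = [SpotTableRow(1, 100.0, 30.0, 7.0, "Gli-α-1")]
        assert pt.aggregate_volumes(rows)["per_gene"]["Gli-α-1"] == 100.0

    def test_ambiguous_volume_never_split(self):
        rows = [
            SpotTableRow(1, 30.0, 30.0, 7.0, "Gli-α-1"),
            SpotTableRow(1, 30.0, 30.0, 7.0, "Gli-α-2"),
        ]
        v = pt.aggregate_volumes(rows)
        assert v["per_gene"] == {}
        assert v["per_group"] == {"Gli-α-1+Gli-α-2": 30.0}

    def test_inconsistent_volume_rows_rejected(self):
        rows = [
            SpotTableRow(1, 30.0, 30.0, 7.0, "a"),
            SpotTableRow(1, 31.0, 30.0, 7.0, "b"),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            pt.aggregate_volumes(rows)


class TestSpotConsistency:
    def test_published_alpha8_spot_is_consistent(self):
        ok, deltas = pt.spot_consistency(32.6, 7.3, {"Gli-α-8": (32.62, 7.31)})
        assert ok
        assert deltas["Gli-α-8"][0] == pytest.approx(-0.02)

    def test_distant_candidate_is_inconsistent(self):
        ok, _ = pt.spot_consistency(60.0, 5.0, {"g": (32.0, 7.0)})
        assert not ok

    def test_generated_spots_consistent_at_default_tolerances(self, family):
        from gliadinkit import physchem as pc

        for row in family.spots:
            genes = family.spot_truth[row.spot_id]["genes"]
            cands = {
                g: (pc.physchem(family.proteins[g]).mw_kd,
                    pc.physchem(family.proteins[g]).pi)
                for g in genes
            }
            ok, _ = pt.spot_consistency(row.mw_kd, row.pi, cands)
            assert ok
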