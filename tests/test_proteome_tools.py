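"""Digestion, species assignment, protein inference and iFPR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossfeed_sip.proteome_tools import (
    assign_species,
    build_index,
    compute_ifpr,
    infer_proteins,
    read_fasta,
    tryptic_digest,
    write_fasta,
)

from conftest import brute_force_digest


class TestReadFasta:
    def test_two_records_in_order(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">p1 desc\nAAAKCCC\n>p2\nGGGRTTT\n")
        assert read_fasta(path) == [("p1", "AAAKCCC"), ("p2", "GGGRTTT")]

    def test_lowercase_and_wrapping_and_stop(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">p1\naaak\nccc*\n")
        assert read_fasta(path) == [("p1", "AAAKCCC")]

    def test_header_only_record(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">p1\nAAAK\n>p2\n")
        with pytest.raises(ValueError):
            read_fasta(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "absent.fasta")

    def test_roundtrip(self, tmp_path):
        records = [("a", "AAAK" * 40), ("b", "CCCR" * 3)]
        path = tmp_path / "out.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == records


class TestTrypticDigest:
    def test_missed_cleavage_products(self):
        out = tryptic_digest("AAAAAAKCCCCCCC", max_missed=2, min_length=7)
        assert set(out) == {"AAAAAAK", "CCCCCCC", "AAAAAAKCCCCCCC"}

    def test_no_cleavage_before_proline(self):
        assert tryptic_digest("AAAKPAAAA", max_missed=0, min_length=7) == ["AAAKPAAAA"]

    def test_length_filter(self):
        assert tryptic_digest("AAAAAA", min_length=7) == []

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            tryptic_digest("AAAXKAAA")

    def test_order_of_first_occurrence(self):
        out = tryptic_digest("AAAAAAAKCCCCCCCK", max_missed=1, min_length=7)
        assert out == ["AAAAAAAK", "AAAAAAAKCCCCCCCK", "CCCCCCCK"]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        protein=st.text(alphabet="AKRPG", min_size=1, max_size=60),
        max_missed=st.integers(0, 2),
        min_length=st.integers(1, 8),
    )
    def test_matches_brute_force_enumeration(self, protein, max_missed, min_length):
        got = set(tryptic_digest(protein, max_missed, min_length))
        assert got == brute_force_digest(protein, max_missed, min_length)


@pytest.fixture
def indices():
    return build_index(
        [
            ("A", [("protA1", "AAAAAAKCCCCCCC"), ("protA2", "CCCCCCCKGGGGGGG")], "target"),
            ("B", [("protB1", "WWWWWWWKCCCCCCC")], "target"),
            ("dec", [("dec1", "DDDDDDDKCCCCCCC")], "decoy"),
        ],
        max_missed=1,
    )


class TestBuildIndex:
    def test_single_protein_index(self):
        [index] = build_index([("A", [("p1", "AAAAAAKCCCCCCC")], "target")])
        assert set(index.peptides) == {"AAAAAAK", "CCCCCCC", "AAAAAAKCCCCCCC"}
        assert all(prots == {"p1"} for prots in index.peptides.values())

    def test_empty_proteome_list(self):
        with pytest.raises(ValueError):
            build_index([])

    def test_duplicate_species_labels(self):
        with pytest.raises(ValueError):
            build_index([("A", [], "target"), ("A", [], "target")])

    def test_peptide_maps_to_both_parent_proteins(self):
        [index] = build_index(
            [("A", [("p1", "AAAAAAKCCCCCCC"), ("p2", "GGGGGGGKCCCCCCC")], "target")]
        )
        assert index.peptides["CCCCCCC"] == {"p1", "p2"}

    def test_ambiguous_residue_proteins_skipped(self):
        [index] = build_index([("A", [("p1", "AAAXAAAKCCCCCCC"), ("p2", "GGGGGGGK")], "target")])
        assert set(index.peptides) == {"GGGGGGGK"}


class TestAssignSpecies:
    def test_unique_target(self, indices):
        assignment = assign_species("AAAAAAK", indices)
        assert assignment.verdict == "species:A"
        assert assignment.proteins == {"protA1"}

    def test_shared_between_targets(self, indices):
        assert assign_species("CCCCCCC", indices).verdict == "decoy"  # decoy dominates
        no_decoy = [i for i in indices if i.provenance == "target"]
        assert assign_species("CCCCCCC", no_decoy).verdict == "shared"

    def test_decoy_dominates(self, indices):
        assert assign_species("DDDDDDDK", indices).verdict == "decoy"

    def test_unmapped(self, indices):
        assert assign_species("MMMMMMM", indices).verdict == "unmapped"

    def test_empty_peptide(self, indices):
        with pytest.raises(ValueError):
            assign_species("", indices)

    def test_partition_and_decoy_monotonicity(self, indices):
        """Every peptide gets exactly one verdict; adding a decoy
        proteome never decreases the decoy-verdict count."""
        peptides = ["AAAAAAK", "CCCCCCC", "DDDDDDDK", "MMMMMMM", "GGGGGGG", "WWWWWWWK"]
        before = [assign_species(p, indices).verdict for p in peptides]
        assert all(isinstance(v, str) for v in before)
        extra = build_index([("dec2", [("d2", "AAAAAAKWWWWWWW")], "decoy")])
        after = [assign_species(p, [*indices, *extra]).verdict for p in peptides]
        assert after.count("decoy") >= before.count("decoy")
        for v_before, v_after in zip(before, after):
            if v_before == "decoy":
                assert v_after == "decoy"


class TestInferProteins:
    def test_two_unique_peptides_reported(self, indices):
        assignments = [assign_species(p, indices) for p in ("CCCCCCCK", "GGGGGGG")]
        assert infer_proteins(assignments) == {"A": {"protA2"}}

    def test_single_unique_peptide_not_reported(self, indices):
        assignments = [assign_species("AAAAAAK", indices)]
        assert infer_proteins(assignments) == {}

    def test_shared_peptides_do_not_count(self):
        no_decoy = build_index(
            [
                ("A", [("pa", "CCCCCCCKDDDDDDDK")], "target"),
                ("B", [("pb", "CCCCCCCKDDDDDDDK")], "target"),
            ],
            max_missed=0,
        )
        assignments = [assign_species(p, no_decoy) for p in ("CCCCCCCK", "DDDDDDDK")]
        assert all(a.verdict == "shared" for a in assignments)
        assert infer_proteins(assignments) == {}


class TestComputeIfpr:
    def test_zero_and_full(self):
        assert compute_ifpr(0, 100) == 0.0
        assert compute_ifpr(100, 100) == 1.0

    def test_bounds(self):
        assert 0.0 <= compute_ifpr(7, 1000) <= 1.0

    @pytest.mark.parametrize("decoy, total", [(1, 0), (-1, 10), (11, 10)])
    def test_invalid_counts(self, decoy, total):
        with pytest.raises(ValueError):
            compute_ifpr(decoy, total)
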