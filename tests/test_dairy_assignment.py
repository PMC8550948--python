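"""In-silico digestion, peptide->taxon LCA assignment and dairy calls."""

import pytest
from hypothesis import given, settings, strategies as st

from paleodairy import synthetic_data as sd
from paleodairy.dairy_assignment import (
    MilkProteinRecord,
    assign_taxon,
    build_peptide_index,
    call_dairy_status,
    count_deamidation_sites,
    read_milk_fasta,
    tryptic_digest,
    write_milk_fasta,
)
from paleodairy.psm_validation import PeptideSpectralMatch

from conftest import naive_tryptic_digest


class TestDigest:
    def test_hand_cleavage(self):
        assert tryptic_digest("MKTAYIAKQR", 0, 1) == {"MK", "TAYIAK", "QR"}

    def test_no_cleavage_before_proline(self):
        assert tryptic_digest("AKPLR", 0, 1) == {"AKPLR"}

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residues"):
            tryptic_digest("AAKBB", 0, 1)

    def test_min_length_filters(self):
        assert tryptic_digest("MKTAYIAKQR", 0, 3) == {"TAYIAK"}

    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=300),
        mc=st.integers(0, 3),
        minlen=st.integers(1, 8),
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_naive_splitter(self, seq, mc, minlen):
        assert tryptic_digest(seq, mc, minlen) == naive_tryptic_digest(seq, mc, minlen)

    def test_matches_naive_splitter_long(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2000))
        assert tryptic_digest(seq, 2, 6) == naive_tryptic_digest(seq, 2, 6)


@pytest.fixture(scope="module")
def reference(tree):
    import numpy as np

    return sd.simulate_milk_reference(tree, np.random.default_rng(99))


@pytest.fixture(scope="module")
def call_setup(tree):
    import numpy as np

    records, exclusion, blocks = sd.simulate_milk_reference(
        tree, np.random.default_rng(5)
    )
    index = build_peptide_index(records, tree, exclusion=exclusion)
    return index, blocks


class TestIndex:
    def test_equus_blgi_peptide_is_singleton(self, reference, tree):
        records, exclusion, blocks = reference
        index = build_peptide_index(records, tree, exclusion=exclusion)
        pep = blocks[("Equus", "BLG-I")]
        assert index[pep] == {("Equus", "BLG-I")}
        assert assign_taxon(pep, index, tree) == "Equus"

    def test_shared_casein_block_spans_bovinae(self, reference, tree):
        records, exclusion, blocks = reference
        index = build_peptide_index(records, tree, exclusion=exclusion)
        pep = blocks[("Bovinae", "alpha-S1-casein")]
        assert {t for t, _ in index[pep]} == {"Bos", "Bubalus", "Bison"}
        assert assign_taxon(pep, index, tree) == "Bovinae"

    def test_excluded_contaminant_contributes_nothing(self, reference, tree):
        records, exclusion, blocks = reference
        index = build_peptide_index(records, tree, exclusion=exclusion)
        for sources in index.values():
            assert all(taxon in tree for taxon, _ in sources)

    def test_unexcluded_out_of_tree_taxon_fails_loudly(self, reference, tree):
        records, _exclusion, _blocks = reference
        with pytest.raises(ValueError, match="not in taxonomy"):
            build_peptide_index(records, tree, exclusion=())

    def test_fasta_round_trip(self, reference, tmp_path):
        records, _, _ = reference
        path = tmp_path / "milk.fasta"
        write_milk_fasta(records, path)
        assert read_milk_fasta(path) == records


class TestLca:
    @pytest.mark.parametrize(
        "taxa, expected",
        [
            ({"Bos"}, "Bos"),
            ({"Bos", "Bubalus", "Bison"}, "Bovinae"),
            ({"Ovis", "Capra", "Bos"}, "Bovidae"),
            ({"Ovis", "Bos", "Cervus"}, "Pecora"),
            ({"Ovis", "Equus"}, "Mammalia"),
        ],
    )
    def test_known_clades(self, tree, taxa, expected):
        assert tree.lca(taxa) == expected

    def test_matches_root_path_intersection(self, tree, rng):
        leaves = ["Bos", "Bubalus", "Bison", "Ovis", "Capra", "Cervus", "Equus"]
        for _ in range(200):
            taxa = list(rng.choice(leaves, size=rng.integers(1, 5), replace=False))
            paths = [set(tree.path_to_root(t)) for t in taxa]
            shared = set.intersection(*paths)
            deepest = max(shared, key=tree.depth)
            assert tree.lca(taxa) == deepest

    def test_enlarging_taxon_set_never_deepens(self, tree, rng):
        leaves = ["Bos", "Bubalus", "Bison", "Ovis", "Capra", "Cervus", "Equus"]
        for _ in range(100):
            k = int(rng.integers(1, 6))
            taxa = list(rng.choice(leaves, size=k, replace=False))
            extra = str(rng.choice(leaves))
            assert tree.depth(tree.lca(taxa + [extra])) <= tree.depth(tree.lca(taxa))

    def test_assignment_is_ancestor_of_every_source(self, small_cohort):
        tree = small_cohort.taxonomy
        index = build_peptide_index(
            small_cohort.milk_records, tree, exclusion=small_cohort.exclusion_list
        )
        for pep, sources in index.items():
            node = assign_taxon(pep, index, tree)
            for taxon, _family in sources:
                assert tree.is_ancestor_or_self(node, taxon)


class TestDeamidation:
    @pytest.mark.parametrize(
        "pep, n", [("AAAA", 0), ("AVNLF", 1), ("NQSLVYPFPGPIPN", 3)]
    )
    def test_site_counts(self, pep, n):
        assert count_deamidation_sites(pep) == n


class TestDairyCall:
    def _psm(self, pep, family, acc):
        return PeptideSpectralMatch(
            sample_id="I1", peptide=pep, protein_accession=acc,
            protein_family=family, e_value=1e-5,
        )

    def test_casein_only_is_equivocal(self, call_setup, tree):
        index, blocks = call_setup
        pep = blocks[("Bovinae", "alpha-S1-casein")]
        psms = [self._psm(pep, "alpha-S1-casein", "A")] * 2
        ev = call_dairy_status("I1", psms, index, tree)
        assert ev.call == "equivocal"
        assert ev.families_present == {"alpha-S1-casein"}

    def test_blg_with_caseins_is_positive(self, call_setup, tree):
        index, blocks = call_setup
        psms = [
            self._psm(blocks[("Bos", "BLG")], "BLG", "B"),
            self._psm(blocks[("Bos", "alpha-S1-casein")], "alpha-S1-casein", "C"),
            self._psm(blocks[("Bos", "alpha-S2-casein")], "alpha-S2-casein", "D"),
        ]
        ev = call_dairy_status("I1", psms, index, tree)
        assert ev.call == "positive"
        assert {"BLG", "alpha-S1-casein", "alpha-S2-casein"} <= ev.families_present

    def test_no_dairy_psms_is_negative(self, call_setup, tree):
        index, _ = call_setup
        non_dairy = self._psm("WWWWWWWWW", "other", "X")  # not in index
        ev = call_dairy_status("I1", [non_dairy], index, tree)
        assert ev.call == "negative" and not ev.assignments

    def test_decoys_never_count(self, call_setup, tree):
        index, blocks = call_setup
        pep = blocks[("Bos", "BLG")]
        decoy = PeptideSpectralMatch(
            sample_id="I1", peptide=pep, protein_accession="DECOY_B",
            protein_family="BLG", e_value=1e-5, is_decoy=True,
        )
        assert call_dairy_status("I1", [decoy], index, tree).call == "negative"
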