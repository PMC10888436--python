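"""Circular permutation, SIML assembly, reverse translation, T7 templates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circbact.designer import (
    CodonUsageTable,
    InteinPair,
    build_expression_cassette,
    build_linear_t7_template,
    build_siml_protein,
    circular_permute,
    reverse_translate,
    translate_dna,
)
from circbact.digest import TRYPSIN, digest_circular
from circbact.errors import ConfigurationError, DesignError
from circbact.sequences import ResidueSequence, Topology

AA = "ACDEFGHIKLMNPQRSTVWY"


def circ(s):
    return ResidueSequence(s, Topology.CIRCULAR)


@pytest.fixture(scope="module")
def table():
    return CodonUsageTable.ecoli()


@pytest.fixture(scope="module")
def inteins():
    # short synthetic placeholder fragments, as for all designer tests
    return InteinPair(
        int_c=ResidueSequence("GDSHETKC"),
        int_n=ResidueSequence("GTSNAELKR"),
        name="test_intein",
    )


class TestCircularPermute:
    def test_definitional_rotation(self):
        assert circular_permute(circ("ACDEF"), 3).residues == "DEFAC"

    def test_split_one_is_identity(self):
        out = circular_permute(circ("ACDEF"), 1)
        assert out.residues == "ACDEF" and not out.is_circular

    def test_out_of_range_split(self):
        with pytest.raises(ValueError):
            circular_permute(circ("ACDEF"), 6)

    def test_inverse_composition_over_all_splits(self):
        # permute(k) then permute(n-k+2) on the re-circularized result
        # restores the original residue order, for every split and length
        for n in range(2, 11):
            s = "".join(AA[i % 20] for i in range(n))
            for k in range(1, n + 1):
                once = circular_permute(circ(s), k)
                inv = 1 if k == 1 else n - k + 2
                twice = circular_permute(once.as_circular(), inv)
                assert twice.residues == s, (n, k)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40)
    def test_permutation_preserves_circular_digest(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        s = "".join(AA[i] for i in rng.integers(0, 20, n))
        k = int(rng.integers(1, n + 1))
        permuted = circular_permute(circ(s), k)
        orig = digest_circular(circ(s), TRYPSIN, 1)
        re_circ = digest_circular(permuted.as_circular(), TRYPSIN, 1)
        if len(orig) == 1 and orig[0].length == n:
            # trypsin-resistant cycle: the single intact record is reported
            # from position 1, so the two reports are rotations of each other
            assert re_circ[0].sequence.residues in s + s
        else:
            assert {(p.sequence.residues, p.missed_cleavages) for p in orig} == \
                   {(p.sequence.residues, p.missed_cleavages) for p in re_circ}


class TestSimlAssembly:
    def test_pumilarin_style_split_s37(self, inteins):
        # 70-residue core with S at 37 and G at 36: the permuted peptide
        # must start with that serine and end with the preceding glycine
        core = list("L" + "A" * 68 + "W")
        core[35], core[36] = "G", "S"
        design = build_siml_protein(circ("".join(core)), 37, inteins)
        pc = design.permuted_core.residues
        assert len(pc) == 70 and pc[0] == "S" and pc[-1] == "G"

    def test_altitudin_style_split_s8(self, inteins):
        core = list("L" + "A" * 63 + "W")
        core[6], core[7] = "I", "S"
        design = build_siml_protein(circ("".join(core)), 8, inteins)
        pc = design.permuted_core.residues
        assert len(pc) == 65 and pc[0] == "S" and pc[-1] == "I"

    def test_part_order_and_total_length(self, inteins):
        core = circ("LAAAGW")
        d = build_siml_protein(core, 2, inteins, tag="AANDENYALAA")
        assert [name for name, _ in d.parts] == ["IntC", "core", "IntN", "tag"]
        assert len(d.protein) == len(inteins.int_c) + 6 + len(inteins.int_n) + 11

    def test_disabling_tag_drops_last_part(self, inteins):
        d = build_siml_protein(circ("LAAAGW"), 2, inteins, tag=None)
        assert [name for name, _ in d.parts] == ["IntC", "core", "IntN"]

    def test_intein_order_configurable(self):
        pair = InteinPair(ResidueSequence("CCC"), ResidueSequence("NNN"), c_first=False)
        d = build_siml_protein(circ("LAAAGW"), 1, pair, tag=None)
        assert [name for name, _ in d.parts] == ["IntN", "core", "IntC"]

    def test_missing_intein_config_key(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("int_c: GDSHETKC\n")
        with pytest.raises(ConfigurationError, match="int_n"):
            InteinPair.from_yaml(p)


class TestReverseTranslate:
    def test_met_single_codon(self, table):
        assert reverse_translate("M", table) == "ATG"

    def test_frequencies_sum_to_one(self, table):
        for aa, entries in table.codons.items():
            assert sum(f for _, f in entries) == pytest.approx(1.0, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_both_strategies(self, table, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        prot = "".join(AA[i] for i in rng.integers(0, 20, n))
        assert translate_dna(reverse_translate(prot, table)) == prot
        dna = reverse_translate(prot, table, strategy="weighted", seed=seed)
        assert translate_dna(dna) == prot

    def test_weighted_is_seed_deterministic(self, table):
        prot = "MAGKLSTVRE"
        a = reverse_translate(prot, table, "weighted", seed=99)
        b = reverse_translate(prot, table, "weighted", seed=99)
        assert a == b

    def test_missing_residue_in_table(self):
        tiny = CodonUsageTable({"M": (("ATG", 1.0),)})
        with pytest.raises(ConfigurationError):
            reverse_translate("MA", tiny)


class TestExpressionCassette:
    def test_minimal_cassette_features(self):
        rec = build_expression_cassette("GGT")
        types = [f.type for f in rec.features]
        assert types == ["regulatory", "CDS", "regulatory"]
        cds = rec.features[1]
        cds_seq = str(rec.seq[int(cds.location.start):int(cds.location.end)])
        assert cds_seq.startswith("ATG") and cds_seq.endswith("TAA")

    def test_in_frame_stop_reports_codon(self):
        with pytest.raises(DesignError, match="codon 2"):
            build_expression_cassette("GGTTAAGGT")

    def test_full_siml_construct_single_cds(self, table, inteins):
        core = circ("L" + "A" * 30 + "S" + "A" * 30 + "W")
        d = build_siml_protein(core, 32, inteins)
        rec = build_expression_cassette(reverse_translate(d.protein, table))
        cds = [f for f in rec.features if f.type == "CDS"]
        assert len(cds) == 1
        # the cassette supplies the ATG start codon, so the CDS reads M + fusion
        assert cds[0].qualifiers["translation"][0] == "M" + d.protein.residues


class TestLinearT7Template:
    def test_forward_primer_is_amplicon_prefix(self, table):
        prot = ResidueSequence("MKDNAELFTGAVQKVGQSIG")
        t = build_linear_t7_template(prot, table)
        assert t.amplicon.startswith(t.forward_primer)

    def test_reverse_primer_revcomp_is_suffix(self, table):
        from Bio.Seq import Seq

        prot = ResidueSequence("MKDNAELFTGAVQKVGQSIG")
        t = build_linear_t7_template(prot, table)
        assert t.amplicon.endswith(str(Seq(t.reverse_primer).reverse_complement()))

    def test_clb_length_amplicon_arithmetic(self, table, panel):
        # an 83-residue mature peptide gives 83*3 + 6 nt of CDS (ATG + TAA)
        prot = ResidueSequence(panel.linear["syn_closticin_like"].residues + "A")
        assert len(prot) == 83
        t = build_linear_t7_template(prot, table)
        from circbact.designer import T7_PROMOTER, T7_TERMINATOR

        assert len(t.amplicon) == len(T7_PROMOTER) + 83 * 3 + 6 + len(T7_TERMINATOR)

    def test_too_short_protein_rejected(self, table):
        with pytest.raises(ValueError):
            build_linear_t7_template(ResidueSequence("MKDNAEL"), table)
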