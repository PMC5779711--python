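"""PCR engine, thermodynamics, primer design, sequence utilities."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from clonesim.fixtures import random_dna
from clonesim.molecule import DnaMolecule, reverse_complement_seq
from clonesim.pcr import (
    Primer, TmParams, analyze_oligos, codon_usage, design_primer_at,
    design_primers, expand_designer_text, melting_temperature, merge_sequences,
    reverse_translate, simulate_pcr, simulate_sequencing, tm_profile,
)

# SantaLucia (1998) unified parameters, entered independently of the
# implementation for the spreadsheet-style oracle below.
_DH = {"AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "TG": -8.5,
       "GT": -8.4, "AC": -8.4, "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
       "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0}
_DS = {"AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7, "TG": -22.7,
       "GT": -22.4, "AC": -22.4, "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
       "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9}


def _oracle_tm(seq, conc=0.5e-6, na=0.05):
    dh = sum(_DH[seq[i:i + 2]] for i in range(len(seq) - 1))
    ds = sum(_DS[seq[i:i + 2]] for i in range(len(seq) - 1))
    for terminal in (seq[0], seq[-1]):
        dh += 0.1 if terminal in "GC" else 2.3
        ds += -2.8 if terminal in "GC" else 4.1
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return dh * 1000 / (ds + 1.987 * math.log(conc / 4)) - 273.15


class TestTm:
    def test_wallace_formula(self):
        assert melting_temperature("AATTAATTGGCC", TmParams("wallace")) == 32.0

    @pytest.mark.parametrize("seq", ["AGCTTGCATGCCTGCAGGTC", "GGGCCCAAATTTGGGCCCAT",
                                     "ATATATGCGCATATATGCGC"])
    def test_nearest_neighbor_matches_hand_sum(self, seq):
        assert melting_temperature(seq, TmParams()) == pytest.approx(
            _oracle_tm(seq), abs=0.2)

    @given(st.text(alphabet="ACGT", min_size=6, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_appending_gc_never_lowers_wallace(self, seq):
        p = TmParams("wallace")
        assert melting_temperature(seq + "GC", p) >= melting_temperature(seq, p)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTN")


class TestTmProfile:
    def test_pointwise_equals_direct(self):
        rng = random.Random(0)
        mol = DnaMolecule.linear(random_dna(rng, 60))
        prof = tm_profile(mol, 12)
        assert len(prof) == 60 - 12 + 1
        for i, v in enumerate(prof):
            assert v == melting_temperature(mol.sequence[i:i + 12])

    def test_homopolymer_constant_profile(self):
        prof = tm_profile(DnaMolecule.linear("AT" * 20), 10, TmParams("wallace"))
        assert set(prof) == {20.0}

    def test_circular_window_count(self):
        mol = DnaMolecule.circular("ACGT" * 10)
        assert len(tm_profile(mol, 8)) == 40


class TestSimulatePcr:
    def _template(self, seed=7, n=500):
        return DnaMolecule.linear(random_dna(random.Random(seed), n), "tpl")

    def test_simple_amplicon_position_arithmetic(self):
        mol = self._template()
        seq = mol.sequence
        fwd = Primer("f", seq[10:30])
        rev = Primer("r", reverse_complement_seq(seq[190:210]))
        products, byproducts = simulate_pcr([mol], [fwd, rev])
        assert [len(p.sequence) for p in products] == [200]
        assert products[0].sequence == seq[10:210]

    def test_5prime_tail_retained_verbatim(self):
        mol = self._template()
        seq = mol.sequence
        tail = "GGGTTTCCCAAAGGG"
        fwd = Primer("f", tail + seq[10:30])
        rev = Primer("r", reverse_complement_seq(seq[190:210]))
        products, _ = simulate_pcr([mol], [fwd, rev])
        assert [len(p.sequence) for p in products] == [215]
        assert products[0].sequence == tail + seq[10:210]

    def test_overlap_extension_product(self):
        rng = random.Random(9)
        junction = random_dna(rng, 25)
        t1 = random_dna(rng, 200) + junction
        t2 = junction + random_dna(rng, 200)
        fwd = Primer("f", t1[:20])
        rev = Primer("r", reverse_complement_seq(t2[-20:]))
        products, _ = simulate_pcr([DnaMolecule.linear(t1, "t1"),
                                    DnaMolecule.linear(t2, "t2")], [fwd, rev])
        assert any(p.sequence == t1 + t2[25:] for p in products)

    def test_circular_template_spans_origin(self):
        mol = DnaMolecule.circular(self._template().sequence, "circ")
        seq = mol.sequence
        fwd = Primer("f", seq[450:470])
        rev = Primer("r", reverse_complement_seq(seq[30:50]))
        products, _ = simulate_pcr([mol], [fwd, rev])
        assert 100 in {len(p.sequence) for p in products}

    def test_phosphorylated_primer_makes_phosphorylated_end(self):
        mol = self._template()
        seq = mol.sequence
        fwd = Primer("f", seq[10:30], phosphorylated=True)
        rev = Primer("r", reverse_complement_seq(seq[190:210]))
        products, _ = simulate_pcr([mol], [fwd, rev])
        p = products[0]
        assert p.left_end.phosphorylated != p.right_end.phosphorylated

    def test_no_binding_no_products(self):
        products, byproducts = simulate_pcr(
            [self._template()], [Primer("f", "G" * 20), Primer("r", "C" * 20)])
        assert products == [] and byproducts == []

    def test_product_termini_are_primer_sequences(self):
        mol = self._template(13)
        seq = mol.sequence
        primers = [Primer("f", seq[5:25]), Primer("r", reverse_complement_seq(seq[300:320])),
                   Primer("m", seq[100:120])]
        products, _ = simulate_pcr([mol], primers)
        pset = {p.sequence for p in primers}
        for prod in products:
            starts = {prod.sequence[:20], reverse_complement_seq(prod.sequence)[:20]}
            assert starts <= pset

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_site_enumeration_oracle(self, seed):
        """Each exponential product corresponds to a fwd/rev site pair."""
        rng = random.Random(seed)
        mol = DnaMolecule.linear(random_dna(rng, 400), "t")
        seq = mol.sequence
        i = rng.randint(0, 150)
        j = rng.randint(250, 380)
        fwd = Primer("f", seq[i:i + 18])
        rev = Primer("r", reverse_complement_seq(seq[j - 18:j]))
        products, _ = simulate_pcr([mol], [fwd, rev])
        assert {len(p.sequence) for p in products} == {j - i}


class TestSequencing:
    def test_read_downstream_of_primer(self):
        mol = DnaMolecule.linear(random_dna(random.Random(5), 500), "t")
        primer = Primer("s", mol.sequence[85:100])
        read = simulate_sequencing(mol, primer, 300)
        assert read == mol.sequence[100:400]

    def test_template_exhaustion_truncates(self):
        mol = DnaMolecule.linear(random_dna(random.Random(5), 500), "t")
        primer = Primer("s", mol.sequence[435:450])
        assert len(simulate_sequencing(mol, primer, 300)) == 50

    def test_ambiguous_priming_is_an_error(self):
        site = random_dna(random.Random(6), 20)
        mol = DnaMolecule.linear(site + "ACGT" * 30 + site + "TTTT", "t")
        with pytest.raises(ValueError):
            simulate_sequencing(mol, Primer("s", site), 100)


class TestAnalyzeOligos:
    def test_polya_reports_nothing(self):
        assert analyze_oligos(Primer("a", "A" * 12)) == []

    def test_stem_loop_hairpin_detected(self):
        reports = analyze_oligos(Primer("h", "GGGGCCAAAAGGCCCC"))
        kinds = {r.kind for r in reports}
        assert "hairpin" in kinds
        hp = next(r for r in reports if r.kind == "hairpin")
        assert hp.delta_g < 0 and len(hp.involved_positions) >= 6

    def test_palindrome_full_self_dimer(self):
        pal = "ACGTACGTACGTACGT"
        assert reverse_complement_seq(pal) == pal
        reports = analyze_oligos(Primer("p", pal))
        sd = next(r for r in reports if r.kind == "self_dimer")
        assert len(sd.involved_positions) == 16
        # dG equals the full-duplex formation energy, summed independently
        dg = 1.03 + 1.03   # terminal A and terminal T initiation
        for i in range(15):
            dg += {"AC": -1.44, "CG": -2.17, "GT": -1.44, "TA": -0.58}[pal[i:i + 2]]
        assert sd.delta_g == pytest.approx(dg, abs=1e-9)

    def test_cross_dimer_reported_for_pair(self):
        a = Primer("a", "AAAAAAGGGCCC")
        b = Primer("b", "AAAAAAGGGCCC")
        reports = analyze_oligos(a, b)
        assert any(r.kind == "cross_dimer" and r.delta_g < 0 for r in reports)


class TestDesignPrimers:
    def test_one_click_minimality(self):
        mol = DnaMolecule.linear(random_dna(random.Random(21), 600), "m")
        p = design_primer_at(mol, 50, "+", 55)
        assert p.sequence[0] == mol.sequence[50]
        assert melting_temperature(p.sequence) >= 55
        assert melting_temperature(p.sequence[:-1]) < 55

    def test_one_click_minus_strand(self):
        mol = DnaMolecule.linear(random_dna(random.Random(22), 600), "m")
        p = design_primer_at(mol, 400, "-", 55)
        assert p.sequence[0] == reverse_complement_seq(mol.sequence[400])
        assert melting_temperature(p.sequence) >= 55

    def test_pair_search_closed_loop(self):
        mol = DnaMolecule.linear(random_dna(random.Random(23), 700), "m")
        fwd, rev = design_primers(mol, (150, 500), 55)[0]
        products, _ = simulate_pcr([mol], [fwd, rev])
        assert any(mol.sequence[150:500] in p.sequence for p in products)

    def test_unreachable_tm_errors(self):
        with pytest.raises(ValueError):
            design_primer_at(DnaMolecule.linear("AT" * 40), 0, "+", 75)


class TestDesignerText:
    def test_enzyme_name_expansion(self, registry, sites):
        assert expand_designer_text("AA[BamHI]TT", registry, sites) == "AAGGATCCTT"

    def test_reverse_complement_token(self, registry, sites):
        attb = sites.get("attB-phiC31").sequence
        out = expand_designer_text("<attB-phiC31:]", registry, sites)
        assert out == reverse_complement_seq(attb)

    def test_pattern_fills_n_positions(self, registry, sites):
        from clonesim.cut import RestrictionEnzyme, EnzymeRegistry
        reg = EnzymeRegistry()
        reg.add_enzyme(RestrictionEnzyme("XcmI", "CCANNNNNNNNNTGG", 8, 7))
        out = expand_designer_text("[XcmI:GATCGATCG>", reg, sites)
        assert out == "CCAGATCGATCGTGG"

    def test_plain_text_passthrough(self, registry, sites):
        assert expand_designer_text("ACGTACGT", registry, sites) == "ACGTACGT"

    def test_unknown_name_errors(self, registry, sites):
        with pytest.raises(KeyError):
            expand_designer_text("[NoSuchThing]", registry, sites)


class TestMerge:
    def test_visible_splice(self):
        assert merge_sequences(["AAATTTCCC", "TTTCCCGGG"], 6) == ["AAATTTCCCGGG"]

    def test_no_overlap_empty(self):
        assert merge_sequences(["AAAAAAAA", "CCCCCCCC"], 6) == []

    def test_alternative_registers_give_multiple_candidates(self):
        a = "GGGGGGGGGGCACACACACA"
        b = "CACACACACATTTTTTTTTT"
        merged = merge_sequences([a, b], 6)
        assert len(merged) >= 2


class TestReverseTranslation:
    def test_met_is_atg(self):
        table = codon_usage(["ATGATGTAA"])
        assert table["M"] == {"ATG": 1.0}
        assert reverse_translate("M", table) == "ATG"

    def test_one_codon_deterministic(self):
        table = codon_usage(["CTGCTGCTACTG"])
        assert reverse_translate("LLLL", table) == "CTG" * 4
        assert reverse_translate("LLLL", table) == reverse_translate("LLLL", table)

    def test_guided_random_tracks_usage(self):
        table = {"L": {"CTG": 0.7, "CTA": 0.3}}
        dna = reverse_translate("L" * 1000, table, "guided_random", seed=1)
        codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
        frac = codons.count("CTG") / 1000
        assert abs(frac - 0.7) < 0.05

    def test_usage_normalisation(self):
        table = codon_usage(["CTGCTATAA", "CTGCTTTGA"])
        assert sum(table["L"].values()) == pytest.approx(1.0, abs=1e-9)
        assert table["L"]["CTG"] == pytest.approx(0.5)

    def test_internal_stop_reported(self):
        with pytest.raises(ValueError):
            codon_usage(["ATGTAAATG"])

    def test_missing_residue_errors(self):
        with pytest.raises(KeyError):
            reverse_translate("W", {"M": {"ATG": 1.0}})
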