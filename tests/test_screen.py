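"""Gel, feature and PCR screening, sequence comparison, ORFs, hosts."""

import random

import pytest

from clonesim.fixtures import FixtureSpec, generate_fixture, random_dna
from clonesim.molecule import DnaMolecule, Feature, reverse_complement_seq
from clonesim.pcr import Primer
from clonesim.screen import (
    GEL_FLOOR_BP, HostCell, ScreenCondition, compare_sequences, detect_orfs,
    extract_plasmids, feature_screen, gel_select, incubate, pcr_screen, transform,
)


def _mol(n, seed=0):
    return DnaMolecule.linear(random_dna(random.Random(seed + n), n), f"m{n}")


class TestGelSelect:
    def test_floor_is_unconditional(self):
        mols = [_mol(49), _mol(50)]
        kept = gel_select(mols, 1, 1000)
        assert [len(m.sequence) for m in kept] == [50]

    def test_inclusive_bounds(self):
        assert len(gel_select([_mol(100)], 100, 100)) == 1
        assert gel_select([_mol(100)], 101, 200) == []

    def test_mixed_set(self):
        mols = [_mol(60), _mol(600), _mol(6000)]
        assert [len(m.sequence) for m in gel_select(mols, 500, 1000)] == [600]

    def test_unbounded_range_equals_floor_rule(self):
        mols = [_mol(n) for n in (10, 49, 50, 51, 200)]
        kept = gel_select(mols, 1, 10 ** 9)
        assert [len(m.sequence) for m in kept] == [n for n in (10, 49, 50, 51, 200)
                                                   if n >= GEL_FLOOR_BP]


class TestFeatureScreen:
    def _with(self, topo, feats):
        m = (DnaMolecule.circular("ACGT" * 100) if topo == "c"
             else DnaMolecule.linear("ACGT" * 100))
        m.features = [Feature(n, k, i * 10, i * 10 + 8, "+")
                      for i, (n, k) in enumerate(feats)]
        return m

    def test_circular_with_exact_counts(self):
        mix = [self._with("c", [("ampR", "resistance"), ("ori", "ori")]),
               self._with("c", [("ampR", "resistance")]),
               self._with("l", [("ampR", "resistance"), ("ori", "ori")])]
        cond = ScreenCondition(require_circular=True,
                               feature_counts=[("ampR", "eq", 1), ("ori", "eq", 1)])
        assert feature_screen(mix, cond) == [mix[0]]

    def test_require_linear_on_circular_set(self):
        mix = [self._with("c", [("x", "CDS")])]
        assert feature_screen(mix, ScreenCondition(require_circular=False)) == []

    def test_gt_zero(self):
        m = self._with("l", [("tag", "CDS"), ("tag", "CDS")])
        assert feature_screen([m], ScreenCondition(
            feature_counts=[("tag", "gt", 0)])) == [m]

    def test_unknown_feature_name_matches_nothing(self):
        m = self._with("l", [("tag", "CDS")])
        assert feature_screen([m], ScreenCondition(
            feature_counts=[("nonexistent", "gt", 0)])) == []

    def test_needs_a_criterion(self):
        with pytest.raises(ValueError):
            ScreenCondition()


class TestPcrScreen:
    def test_junction_primers_distinguish_clones(self):
        rng = random.Random(4)
        backbone = random_dna(rng, 600)
        insert = random_dna(rng, 500)
        correct = DnaMolecule.circular(backbone + insert, "correct")
        empty = DnaMolecule.circular(backbone, "empty")
        fwd = Primer("f", backbone[-200:-180])
        rev = Primer("r", reverse_complement_seq(insert[380:400]))
        kept = pcr_screen([correct, empty], [fwd, rev], (400, 800))
        assert kept == [correct]

    def test_strict_range_bounds(self):
        rng = random.Random(8)
        seq = random_dna(rng, 1000)
        mol = DnaMolecule.linear(seq, "t")
        fwd = Primer("f", seq[50:70])
        rev = Primer("r", reverse_complement_seq(seq[931:951]))   # 901-bp product
        assert pcr_screen([mol], [fwd, rev], (700, 900)) == []
        assert pcr_screen([mol], [fwd, rev], (700, 901)) == [mol]

    def test_nonbinding_primers_drop_all(self):
        kept = pcr_screen([_mol(300)], [Primer("f", "G" * 20), Primer("r", "C" * 20)],
                          (0, 10 ** 9))
        assert kept == []


@pytest.fixture(scope="module")
def reads():
    return generate_fixture(FixtureSpec("read_pair", seed=6))


class TestCompareSequences:
    def _feats(self, mol, kind):
        return [f for f in mol.features if f.kind == kind]

    def test_identical_read_single_match(self, reads):
        out = compare_sequences(reads.molecules["template"],
                                [reads.molecules["perfect_read"]])
        matches = self._feats(out, "alignment_match")
        assert [(f.start, f.end) for f in matches] == [tuple(reads.manifest["read_span"])]

    def test_substitution_splits_matches(self, reads):
        out = compare_sequences(reads.molecules["template"],
                                [reads.molecules["sub_read"]])
        pos = reads.manifest["substitution_at"]
        mism = self._feats(out, "alignment_mismatch")
        assert [(f.start, f.end) for f in mism] == [(pos, pos + 1)]
        spans = sorted((f.start, f.end) for f in self._feats(out, "alignment_match"))
        s, e = reads.manifest["read_span"]
        assert spans == [(s, pos), (pos + 1, e)]

    def test_insertion_feature_at_junction(self, reads):
        out = compare_sequences(reads.molecules["template"],
                                [reads.molecules["ins_read"]])
        ins = self._feats(out, "alignment_insertion")
        assert len(ins) == 1
        assert abs(ins[0].start - reads.manifest["insertion_at"]) <= 5  # indel sliding
        assert len(ins[0].qualifiers["inserted"]) == 3

    def test_multiple_queries_stack(self, reads):
        out = compare_sequences(reads.molecules["template"],
                                [reads.molecules["perfect_read"],
                                 reads.molecules["sub_read"]])
        assert len(self._feats(out, "alignment_match")) == 3

    def test_unalignable_query_flagged(self, reads):
        junk = DnaMolecule.linear("GC" * 100, "junk")
        out = compare_sequences(reads.molecules["template"], [junk])
        assert self._feats(out, "alignment_unaligned")


class TestDetectOrfs:
    def test_frame_scan_example(self):
        mol = DnaMolecule.linear("AAATGAAACCCGGGTTTTAAGG")
        orfs = detect_orfs(mol, {"ATG"}, 15, both_strands=True)
        assert [(f.start, f.end, f.strand) for f in orfs] == [(2, 20, "+")]

    def test_min_len_filters(self):
        mol = DnaMolecule.linear("AAATGAAACCCGGGTTTTAAGG")
        assert detect_orfs(mol, {"ATG"}, 21, both_strands=True) == []

    def test_alternative_start_codons(self):
        mol = DnaMolecule.linear("AAGTGAAACCCGGGTTTTAAGG")
        assert detect_orfs(mol, {"ATG"}, 15) == []
        assert len(detect_orfs(mol, {"ATG", "GTG"}, 15)) == 1

    def test_circular_wrap(self):
        lin = "ATGAAACCCGGGTTTTAA"
        seq = lin[8:] + "C" * 30 + lin[:8]     # ORF split across the origin
        orfs = detect_orfs(DnaMolecule.circular(seq), {"ATG"}, 18)
        assert any(f.end - f.start == 18 for f in orfs)

    def test_minus_strand(self):
        fwd = "ATGAAACCCGGGTTTTAA"
        mol = DnaMolecule.linear("CC" + reverse_complement_seq(fwd) + "CC")
        orfs = detect_orfs(mol, {"ATG"}, 18, both_strands=True)
        assert [(f.start, f.end, f.strand) for f in orfs] == [(2, 20, "-")]


def _amp_plasmid():
    rng = random.Random(10)
    seq = random_dna(rng, 400)
    feats = [Feature("colE1", "ori", 0, 100, "+", {"origin": "colE1"}),
             Feature("ampR", "resistance", 120, 300, "+", {"antibiotic": "ampicillin"})]
    return DnaMolecule.circular(seq, "pAmp", features=feats)


def _r6k_plasmid():
    rng = random.Random(11)
    feats = [Feature("R6K", "ori", 0, 100, "+", {"origin": "R6K"}),
             Feature("kanR", "resistance", 120, 300, "+", {"antibiotic": "kanamycin"})]
    return DnaMolecule.circular(random_dna(rng, 400), "pR6K", features=feats)


class TestHostSimulation:
    def test_transform_modes(self):
        host = HostCell("DH5a", primase_commands=["colE1"])
        dnas = [_amp_plasmid(), _r6k_plasmid()]
        assert len(transform(host, dnas, "chemical", "one_per_cell")) == 2
        assert len(transform(host, dnas, "chemical", "all_in_one")[0].hosted) == 2
        combo = transform(host, dnas, "chemical", "combinational")
        assert len(combo) == 3
        assert sorted(len(c.hosted) for c in combo) == [1, 1, 2]

    def test_combinational_scaling(self):
        host = HostCell("DH5a", primase_commands=["colE1"])
        dnas = [_amp_plasmid(), _r6k_plasmid(),
                DnaMolecule.circular("ACGT" * 50, "p3")]
        cells = transform(host, dnas, "chemical", "combinational")
        assert len(cells) == 2 ** 3 - 1
        hosted_sets = {frozenset(p.id for p in c.hosted) for c in cells}
        assert len(hosted_sets) == 7

    def test_incompetent_method_rejected(self):
        host = HostCell("DH5a", transfer_competence={"chemical"})
        with pytest.raises(ValueError):
            transform(host, [_amp_plasmid()], "conjugation", "all_in_one")

    def test_selection_needs_matching_ori_and_resistance(self):
        host = HostCell("DH5a", primase_commands=["colE1"])
        with_plasmid = transform(host, [_amp_plasmid()], "chemical", "all_in_one")
        without = [host.copy("+none")]
        survivors = incubate(with_plasmid + without, ["ampicillin"], overnight=True)
        assert len(survivors) == 1 and len(survivors[0].hosted) == 1

    def test_r6k_lost_without_pir(self):
        host = HostCell("DH5a", primase_commands=["colE1"])
        cells = transform(host, [_r6k_plasmid()], "chemical", "all_in_one")
        assert incubate(cells, ["kanamycin"], overnight=True) == []
        grown = incubate(cells)         # no antibiotics: survives, plasmid lost
        assert len(grown) == 1 and grown[0].hosted == []

    def test_intrinsic_and_genomic_resistance(self):
        genome = DnaMolecule("chr", "ACGT" * 100, "genomic_fragment",
                             features=[Feature("camR", "resistance", 0, 50, "+",
                                               {"antibiotic": "chloramphenicol"})])
        host = HostCell("mut", genome_fragments=[genome],
                        intrinsic_resistances=["streptomycin"])
        cells = [host.copy()]
        assert incubate(cells, ["chloramphenicol", "streptomycin"], overnight=True)

    def test_extraction_excludes_genome_and_is_pure(self):
        genome = DnaMolecule("chr", "ACGT" * 100, "genomic_fragment")
        host = HostCell("h", genome_fragments=[genome], primase_commands=["colE1"],
                        hosted=[_amp_plasmid(), _r6k_plasmid()])
        got = extract_plasmids(host)
        assert sorted(p.id for p in got) == ["pAmp", "pR6K"]
        assert sorted(p.id for p in extract_plasmids(host)) == ["pAmp", "pR6K"]
        assert len(host.hosted) == 2
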