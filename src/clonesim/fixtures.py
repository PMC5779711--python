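"""Deterministic synthetic-construct generator.

Every test input in the suite is built here, with a machine-readable
ground-truth manifest, so the whole test bed is self-contained and
reproducible: the same spec always yields byte-identical molecules.

Kinds
-----
toy_plasmid        backbone with a named ori, an ampR resistance CDS and
                   an MCS with declared unique restriction sites
golden_gate_set    circular backbone + n inserts carrying outward-facing
                   BsaI sites that release a designed 4-nt overhang cycle
lox_substrate      circular plasmid with two loxP copies (direct or
                   inverted) a declared distance apart
att_substrate_pair attB plasmid + attP plasmid for irreversible assembly
genomic_locus      a genomic fragment: unique flanks around a target gene
                   (lambda-Red substrate)
gibson_set         n linear fragments sharing designed terminal overlaps
read_pair          a template plus sequencing reads with planted
                   substitutions / indels
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .molecule import DnaMolecule, Feature, reverse_complement_seq

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "random_dna"]

# non-palindromic, mutually non-complementary 4-nt junction overhangs
_GG_OVERHANGS = ["AGTC", "TCCA", "GGAA", "CAAC", "ACCT", "CTGA", "GTCC", "TGGC"]

_BSA_F = "GGTCTCA"                       # BsaI site + 1-nt spacer
_BSA_R = reverse_complement_seq(_BSA_F)  # "TGAGACC"

_LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"
_ATTB = "CGGTGCGGGTGCCAGTTGCACCACGGGTCGTGC"
_ATTP = "GTAGTGCCCCAACTGTTGGGGTAACGCCAGGGT"


@dataclass
class FixtureSpec:
    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class Fixture:
    molecules: dict[str, DnaMolecule]
    manifest: dict


def random_dna(rng: random.Random, n: int, forbidden: tuple[str, ...] = ()) -> str:
    """Random sequence free of the forbidden patterns (either strand)."""
    probes = set(forbidden) | {reverse_complement_seq(p) for p in forbidden}
    for _ in range(200):
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        if not any(p in seq for p in probes):
            return seq
    raise RuntimeError("could not satisfy the forbidden-pattern constraint")


def _count_everywhere(seqs: list[str], probe: str) -> int:
    rc = reverse_complement_seq(probe)
    total = 0
    for s in seqs:
        total += s.count(probe)
        if rc != probe:
            total += s.count(rc)
    return total


def generate_fixture(spec: FixtureSpec) -> Fixture:
    rng = random.Random(spec.seed)
    p = spec.params
    kind = spec.kind

    if kind == "toy_plasmid":
        sites = p.get("unique_sites", {"EcoRI": "GAATTC", "BamHI": "GGATCC",
                                       "HindIII": "AAGCTT"})
        forb = tuple(sites.values())
        ori = random_dna(rng, p.get("ori_len", 200), forb)
        ampr = random_dna(rng, p.get("marker_len", 300), forb)
        stuffers = [random_dna(rng, p.get("stuffer_len", 250), forb) for _ in range(2)]
        mcs = "".join(sites.values())
        seq = ori + stuffers[0] + ampr + stuffers[1] + mcs
        feats = [
            Feature("colE1", "ori", 0, len(ori), "+", {"origin": "colE1"}),
            Feature("ampR", "resistance", len(ori) + len(stuffers[0]),
                    len(ori) + len(stuffers[0]) + len(ampr), "+",
                    {"antibiotic": "ampicillin"}),
        ]
        mol = DnaMolecule.circular(seq, p.get("id", "toy_plasmid"), features=feats)
        manifest = {"length": len(seq),
                    "site_counts": {name: _count_everywhere([seq + seq[:len(s) - 1]], s)
                                    for name, s in sites.items()},
                    "mcs_start": len(seq) - len(mcs),
                    "ori": "colE1", "resistance": "ampicillin"}
        return Fixture({"plasmid": mol}, manifest)

    if kind == "golden_gate_set":
        n = p.get("n_inserts", 3)
        if n + 1 > len(_GG_OVERHANGS):
            raise ValueError("too many inserts for the overhang palette")
        ovs = _GG_OVERHANGS[:n + 1]
        forb = ("GGTCTC",)

        def safe_payload(length: int, left: str, right: str) -> str:
            # the assembled context must contain no stray BsaI site
            for _ in range(50):
                pay = random_dna(rng, length, forb)
                ctx = left + pay + right
                if _count_everywhere([ctx], "GGTCTC") == 0:
                    return pay
            raise RuntimeError("could not place a BsaI-free payload")

        payloads = [safe_payload(p.get("payload_len", 120), ovs[i], ovs[i + 1])
                    for i in range(n)]
        inserts = {}
        for i in range(n):
            seq = _BSA_F + ovs[i] + payloads[i] + ovs[i + 1] + _BSA_R
            inserts[f"insert{i + 1}"] = DnaMolecule.linear(seq, f"insert{i + 1}")
        backbone_payload = safe_payload(p.get("backbone_len", 400), ovs[n], ovs[0])
        ori = safe_payload(150, ovs[n], backbone_payload[:6])
        # the released stuffer carries the same junction overhangs as the
        # backbone, so it must be small enough to vanish below the gel floor
        stuffer = random_dna(rng, p.get("stuffer_len", 30), forb)
        bb_seq = _BSA_F + ovs[n] + ori + backbone_payload + ovs[0] + _BSA_R + stuffer
        backbone = DnaMolecule.circular(
            bb_seq, "gg_backbone",
            features=[Feature("colE1", "ori", len(_BSA_F) + 4,
                              len(_BSA_F) + 4 + len(ori), "+", {"origin": "colE1"})])
        # the designed circle: payload path forced by the overhang cycle
        expected = ""
        for i in range(n):
            expected += ovs[i] + payloads[i]
        expected += ovs[n] + ori + backbone_payload
        manifest = {"overhangs": ovs, "expected_circle": expected,
                    "expected_len": len(expected),
                    "backbone_fragment_len": 4 + len(ori) + len(backbone_payload) + 4,
                    "stuffer_len": len(stuffer) + 2 * len(_BSA_F)}
        mols = {"backbone": backbone, **inserts}
        return Fixture(mols, manifest)

    if kind == "lox_substrate":
        gap = p.get("gap", 1000)
        rest = p.get("rest", 600)
        direct = p.get("direct", True)
        a = random_dna(rng, gap, (_LOXP,))
        b = random_dna(rng, rest, (_LOXP,))
        second = _LOXP if direct else reverse_complement_seq(_LOXP)
        seq = _LOXP + a + second + b
        mol = DnaMolecule.circular(seq, "lox_plasmid")
        manifest = {"length": len(seq), "direct": direct,
                    "circle_lengths": sorted([len(_LOXP) + gap, len(_LOXP) + rest]),
                    "site_len": len(_LOXP)}
        return Fixture({"plasmid": mol}, manifest)

    if kind == "att_substrate_pair":
        pay_b = random_dna(rng, p.get("payload_b", 700), (_ATTB, _ATTP))
        pay_p = random_dna(rng, p.get("payload_p", 500), (_ATTB, _ATTP))
        mol_b = DnaMolecule.circular(_ATTB + pay_b, "attB_plasmid")
        mol_p = DnaMolecule.circular(_ATTP + pay_p, "attP_plasmid")
        manifest = {"cointegrate_len": len(mol_b.sequence) + len(mol_p.sequence)}
        return Fixture({"attB": mol_b, "attP": mol_p}, manifest)

    if kind == "genomic_locus":
        flank = p.get("flank_len", 300)
        gene_len = p.get("gene_len", 400)
        up = random_dna(rng, flank)
        gene = random_dna(rng, gene_len)
        down = random_dna(rng, flank)
        seq = up + gene + down
        mol = DnaMolecule(
            "locus", seq, "genomic_fragment",
            features=[Feature("targetGene", "CDS", flank, flank + gene_len, "+")])
        manifest = {"flank_len": flank, "gene_start": flank,
                    "gene_end": flank + gene_len, "length": len(seq)}
        return Fixture({"locus": mol}, manifest)

    if kind == "gibson_set":
        n = p.get("n_fragments", 3)
        overlap = p.get("overlap", 0)   # 0 = no natural overlaps (designer input)
        core_len = p.get("core_len", 300)
        cores = [random_dna(rng, core_len) for _ in range(n)]
        if overlap:
            junctions = [random_dna(rng, overlap) for _ in range(n)]
            mols = {}
            for i in range(n):
                seq = junctions[i] + cores[i] + junctions[(i + 1) % n]
                mols[f"frag{i + 1}"] = DnaMolecule.linear(seq, f"frag{i + 1}")
            expected_len = sum(core_len + overlap for _ in range(n))
            manifest = {"n": n, "overlap": overlap, "expected_len": expected_len,
                        "junctions": junctions}
        else:
            mols = {f"frag{i + 1}": DnaMolecule.linear(cores[i], f"frag{i + 1}")
                    for i in range(n)}
            manifest = {"n": n, "overlap": 0}
        return Fixture(mols, manifest)

    if kind == "read_pair":
        tlen = p.get("template_len", 800)
        template = DnaMolecule.linear(random_dna(rng, tlen), "template")
        sub_at = p.get("substitution_at", 400)
        ins_at = p.get("insertion_at", 250)
        read_span = p.get("read_span", (100, 700))
        s, e = read_span
        raw = template.sequence[s:e]
        off = sub_at - s
        orig = raw[off]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[orig]
        sub_read = raw[:off] + alt + raw[off + 1:]
        ins = random_dna(rng, 3)
        ioff = ins_at - s
        ins_read = raw[:ioff] + ins + raw[ioff:]
        manifest = {"read_span": [s, e], "substitution_at": sub_at,
                    "substituted_to": alt, "insertion_at": ins_at, "inserted": ins}
        return Fixture({"template": template,
                        "perfect_read": DnaMolecule.linear(raw, "perfect_read"),
                        "sub_read": DnaMolecule.linear(sub_read, "sub_read"),
                        "ins_read": DnaMolecule.linear(ins_read, "ins_read")},
                       manifest)

    raise ValueError(f"unknown fixture kind {kind!r}")
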