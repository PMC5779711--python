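"""Executable example projects: the classic cloning strategies.

Each builder returns ``(project, terminal_node_id)``; executing the
project leaves exactly one screened product molecule in the terminal
node.  All inputs come from the deterministic fixture generator, so the
examples double as end-to-end integration fixtures:

- restriction cloning (sticky-end vector + insert)
- Golden Gate assembly (Type IIS digestion + exhaustive ligation)
- irreversible integrase assembly (phiC31 attB x attP)
- site-specific integration plus lambda-Red knockout on a genomic locus
- multi-fragment Gibson assembly (designed linkers, in-vivo annealing)
"""

from __future__ import annotations

import random

from .fixtures import FixtureSpec, generate_fixture, random_dna
from .join import GibsonSource, design_gibson
from .molecule import reverse_complement_seq
from .workflow import Project

__all__ = [
    "build_restriction_cloning_project",
    "build_golden_gate_project",
    "build_phic31_project",
    "build_recombineering_project",
    "build_gibson_project",
]


def build_restriction_cloning_project(seed: int = 1) -> tuple[Project, str]:
    """EcoRI/HindIII directional cloning of a gene into the toy vector."""
    fx = generate_fixture(FixtureSpec("toy_plasmid", seed=seed))
    vector = fx.molecules["plasmid"]
    rng = random.Random(seed + 1000)
    gene = random_dna(rng, 450, ("GAATTC", "AAGCTT", "GGATCC"))

    proj = Project("restriction_cloning")
    proj.feature_library.add("ampR", vector.sequence[
        [f for f in vector.features if f.name == "ampR"][0].start:
        [f for f in vector.features if f.name == "ampR"][0].end], "resistance",
        {"antibiotic": "ampicillin"})
    proj.feature_library.add("gene_of_interest", gene, "CDS")

    vec = proj.add_node("sequence_input", "vector",
                        {"sequence": vector.sequence, "topology": "circular",
                         "id": "vector"})
    ins = proj.add_node("sequence_input", "insert_precursor",
                        {"sequence": "TT" + "GAATTC" + gene + "AAGCTT" + "TT",
                         "topology": "linear", "id": "insert"})
    vcut = proj.add_node("digestion", "cut_vector",
                         {"enzymes": ["EcoRI", "HindIII"]}, [vec.node_id])
    icut = proj.add_node("digestion", "cut_insert",
                         {"enzymes": ["EcoRI", "HindIII"]}, [ins.node_id])
    lig = proj.add_node("ligation", "ligate", {"mode": "normal", "rounds": 2},
                        [vcut.node_id, icut.node_id])
    screen = proj.add_node("feature_screen", "pick_clone",
                           {"require_circular": True,
                            "feature_counts": [["ampR", "eq", 1],
                                               ["gene_of_interest", "eq", 1]]},
                           [lig.node_id])
    return proj, screen.node_id


def build_golden_gate_project(seed: int = 7, n_inserts: int = 3) -> tuple[Project, str]:
    fx = generate_fixture(FixtureSpec("golden_gate_set", seed=seed,
                                      params={"n_inserts": n_inserts}))
    proj = Project("golden_gate")
    backbone = fx.molecules["backbone"]
    ori_feat = [f for f in backbone.features if f.name == "colE1"][0]
    proj.feature_library.add("colE1",
                             backbone.sequence[ori_feat.start:ori_feat.end],
                             "ori", {"origin": "colE1"})
    sources = []
    for name, mol in fx.molecules.items():
        node = proj.add_node("sequence_input", name,
                             {"sequence": mol.sequence, "topology": mol.topology,
                              "id": mol.id})
        sources.append(node.node_id)
    cut = proj.add_node("digestion", "BsaI_digest", {"enzymes": ["BsaI"]}, sources)
    gel = proj.add_node("gel", "remove_small", {"min_len": 60, "max_len": 10 ** 6},
                        [cut.node_id])
    lig = proj.add_node("ligation", "assembly",
                        {"mode": "exhaustive", "copies": 1}, [gel.node_id])
    screen = proj.add_node("feature_screen", "pick_circle",
                           {"require_circular": True,
                            "feature_counts": [["colE1", "eq", 1]]}, [lig.node_id])
    proj.metadata["expected_circle"] = fx.manifest["expected_circle"]
    return proj, screen.node_id


def build_phic31_project(seed: int = 5) -> tuple[Project, str]:
    fx = generate_fixture(FixtureSpec("att_substrate_pair", seed=seed))
    proj = Project("phic31_assembly")
    b = proj.add_node("sequence_input", "attB_plasmid",
                      {"sequence": fx.molecules["attB"].sequence,
                       "topology": "circular", "id": "attB_plasmid"})
    p = proj.add_node("sequence_input", "attP_plasmid",
                      {"sequence": fx.molecules["attP"].sequence,
                       "topology": "circular", "id": "attP_plasmid"})
    rec = proj.add_node("recombination", "integrase",
                        {"sites": ["attB-phiC31", "attP-phiC31"]},
                        [b.node_id, p.node_id])
    screen = proj.add_node("feature_screen", "pick_cointegrate",
                           {"require_circular": True}, [rec.node_id])
    proj.metadata["cointegrate_len"] = fx.manifest["cointegrate_len"]
    return proj, screen.node_id


def build_recombineering_project(seed: int = 9) -> tuple[Project, str]:
    """HK022 integrase knock-in followed by a lambda-Red knockout.

    A donor plasmid integrates into a genomic attB-HK022 landing site;
    the target gene of the resulting locus is then replaced by a kanR
    cassette with 40-bp homology arms.
    """
    fx = generate_fixture(FixtureSpec("genomic_locus", seed=seed))
    locus = fx.molecules["locus"]
    man = fx.manifest
    rng = random.Random(seed + 2000)

    proj = Project("recombineering")
    attb = proj.sites.get("attB-HK022").sequence
    attp = proj.sites.get("attP-HK022").sequence
    genome_seq = locus.sequence[:100] + attb + locus.sequence[100:]
    donor_payload = random_dna(rng, 300)
    donor = attp + donor_payload

    kanr = random_dna(rng, 240)
    proj.feature_library.add("kanR", kanr, "resistance", {"antibiotic": "kanamycin"})
    proj.feature_library.add("targetGene",
                             locus.sequence[man["gene_start"]:man["gene_end"]], "CDS")
    proj.feature_library.add("attL-HK022", proj.sites.get("attL-HK022").sequence,
                             "misc_recomb")
    proj.feature_library.add("locus_end", genome_seq[-60:], "misc_feature")
    arm_len = 40
    gene_start = man["gene_start"] + len(attb)   # shifted by the landing site
    up = genome_seq[gene_start - arm_len:gene_start]
    gene_end = gene_start + (man["gene_end"] - man["gene_start"])
    down = genome_seq[gene_end:gene_end + arm_len]
    cassette = up + kanr + down

    g = proj.add_node("sequence_input", "genome",
                      {"sequence": genome_seq, "topology": "genomic_fragment",
                       "id": "genome"})
    d = proj.add_node("sequence_input", "donor",
                      {"sequence": donor, "topology": "circular", "id": "donor"})
    knockin = proj.add_node("recombination", "HK022_integration",
                            {"sites": ["attB-HK022", "attP-HK022"]},
                            [g.node_id, d.node_id])
    c = proj.add_node("sequence_input", "cassette",
                      {"sequence": cassette, "topology": "linear", "id": "cassette"})
    knockout = proj.add_node("recombination", "lambda_red_knockout",
                             {"family": "lambda_red"},
                             [knockin.node_id, c.node_id])
    screen = proj.add_node("feature_screen", "pick_edited_genome",
                           {"feature_counts": [["kanR", "eq", 1],
                                               ["targetGene", "eq", 0],
                                               ["attL-HK022", "eq", 1],
                                               ["locus_end", "eq", 1]]},
                           [knockout.node_id])
    return proj, screen.node_id


def build_gibson_project(seed: int = 8, n_fragments: int = 3) -> tuple[Project, str]:
    """Multi-fragment Gibson assembly: linkers designed onto PCR primers,
    then verified by exhaustive in-vivo annealing."""
    fx = generate_fixture(FixtureSpec("gibson_set", seed=seed,
                                      params={"n_fragments": n_fragments,
                                              "overlap": 0, "core_len": 300}))
    mols = list(fx.molecules.values())
    sources = [GibsonSource(m, is_pcr_product=True,
                            forward_primer=m.sequence[:20],
                            reverse_primer=reverse_complement_seq(m.sequence[-20:]))
               for m in mols]
    design = design_gibson(sources, tm_threshold=48, min_overlap=15)

    proj = Project("gibson_assembly")
    proj.feature_library.add("part1", mols[0].sequence[50:150], "misc_feature")
    node_ids = []
    for frag in design.fragments:
        node = proj.add_node("sequence_input", frag.id,
                             {"sequence": frag.sequence, "topology": "linear",
                              "id": frag.id})
        node_ids.append(node.node_id)
    rec = proj.add_node("recombination", "gibson",
                        {"family": "in_vivo_annealing", "mode": "exhaustive"},
                        node_ids)
    screen = proj.add_node("feature_screen", "pick_circle",
                           {"require_circular": True,
                            "feature_counts": [["part1", "eq", 1]]}, [rec.node_id])
    proj.metadata["expected_len"] = sum(len(m.sequence) for m in mols)
    return proj, screen.node_id
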