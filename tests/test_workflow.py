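"""Project DAG: construction, execution, recalculation, persistence."""

import random

import networkx as nx
import pytest

from clonesim.cut import digest
from clonesim.fixtures import FixtureSpec, generate_fixture, random_dna
from clonesim.molecule import canonical_hash, reverse_complement_seq
from clonesim.pcr import Primer
from clonesim.workflow import Project, WorkflowError


@pytest.fixture()
def plasmid():
    return generate_fixture(FixtureSpec("toy_plasmid", seed=1)).molecules["plasmid"]


def _input_node(proj, mol, name="input"):
    return proj.add_node("sequence_input", name,
                         {"sequence": mol.sequence, "topology": mol.topology,
                          "id": mol.id})


class TestGraph:
    def test_topological_registration(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGTACGT"})
        b = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                          sources=[a.node_id])
        assert list(nx.topological_sort(proj.graph())) == [a.node_id, b.node_id]

    def test_cycle_rejected(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGT"})
        b = proj.add_node("gel", params={"min_len": 1, "max_len": 10},
                          sources=[a.node_id])
        c = proj.add_node("gel", params={"min_len": 1, "max_len": 10},
                          sources=[b.node_id])
        with pytest.raises(WorkflowError):
            proj.connect(a.node_id, c.node_id)

    def test_dangling_source_rejected(self):
        proj = Project()
        with pytest.raises(WorkflowError):
            proj.add_node("gel", params={}, sources=["ghost"])

    def test_in_degree_two(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGT"})
        b = proj.add_node("sequence_input", params={"sequence": "TTTT"})
        c = proj.add_node("ligation", params={}, sources=[a.node_id, b.node_id])
        assert proj.graph().in_degree(c.node_id) == 2


class TestExecution:
    def test_dispatch_transparency(self, plasmid, registry):
        proj = Project()
        src = _input_node(proj, plasmid)
        node = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                             sources=[src.node_id])
        proj.execute_all()
        direct, _ = digest([plasmid], ["EcoRI"], registry)
        assert sorted(canonical_hash(m) for m in proj.nodes[node.node_id].results) == \
            sorted(canonical_hash(m) for m in direct)

    def test_stale_source_is_an_error(self, plasmid):
        proj = Project()
        src = _input_node(proj, plasmid)
        node = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                             sources=[src.node_id])
        with pytest.raises(WorkflowError, match=src.node_id):
            proj.execute_node(node.node_id)

    def test_determinism_across_fresh_runs(self, plasmid):
        def run():
            proj = Project()
            src = _input_node(proj, plasmid)
            cut = proj.add_node("digestion", params={"enzymes": ["EcoRI", "BamHI"]},
                                sources=[src.node_id])
            lig = proj.add_node("ligation", params={"rounds": 2}, sources=[cut.node_id])
            proj.execute_all()
            return {nid: n.summary["hashes"] for nid, n in proj.nodes.items()}

        assert run() == run()

    def test_cache_skips_unchanged_node(self, plasmid):
        proj = Project()
        src = _input_node(proj, plasmid)
        node = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                             sources=[src.node_id])
        proj.execute_all()
        before = proj.nodes[node.node_id].results
        proj.nodes[node.node_id].stale = False
        assert proj.execute_node(node.node_id) is before


class TestRecalculation:
    def test_chain_propagation(self, plasmid):
        rng = random.Random(0)
        seq = random_dna(rng, 400)
        proj = Project()
        proj.add_primer(Primer("fwd", seq[10:30]))
        proj.add_primer(Primer("rev", reverse_complement_seq(seq[190:210])))
        tpl = proj.add_node("sequence_input", params={"sequence": seq, "id": "t"})
        pcr = proj.add_node("pcr", params={"forward": "fwd", "reverse": "rev"},
                            sources=[tpl.node_id])
        gel = proj.add_node("gel", params={"min_len": 50, "max_len": 1000},
                            sources=[pcr.node_id])
        proj.execute_all()
        assert [len(m.sequence) for m in proj.nodes[gel.node_id].results] == [200]
        # edit the upstream primer: product must follow after recalculation
        proj.add_primer(Primer("rev", reverse_complement_seq(seq[280:300])))
        order = proj.recalculate_children(pcr.node_id)
        assert order == [pcr.node_id, gel.node_id]
        assert [len(m.sequence) for m in proj.nodes[gel.node_id].results] == [290]

    def test_diamond_order(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGT" * 30})
        b = proj.add_node("gel", params={"min_len": 1, "max_len": 200},
                          sources=[a.node_id])
        c = proj.add_node("gel", params={"min_len": 1, "max_len": 200},
                          sources=[a.node_id])
        d = proj.add_node("ligation", params={}, sources=[b.node_id, c.node_id])
        proj.execute_all()
        order = proj.recalculate_children(a.node_id)
        assert order.index(d.node_id) > order.index(b.node_id)
        assert order.index(d.node_id) > order.index(c.node_id)

    def test_leaf_recalculates_alone(self, plasmid):
        proj = Project()
        src = _input_node(proj, plasmid)
        node = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                             sources=[src.node_id])
        proj.execute_all()
        assert proj.recalculate_children(node.node_id) == [node.node_id]

    def test_failure_marks_descendants_stale(self, plasmid):
        proj = Project()
        src = _input_node(proj, plasmid)
        bad = proj.add_node("digestion", params={"enzymes": ["NoSuchEnzyme"]},
                            sources=[src.node_id])
        down = proj.add_node("gel", params={"min_len": 1, "max_len": 10 ** 6},
                             sources=[bad.node_id])
        ok = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                           sources=[src.node_id])
        done = proj.recalculate_children(src.node_id)
        assert src.node_id in done and ok.node_id in done
        assert bad.node_id not in done and down.node_id not in done
        assert proj.nodes[down.node_id].stale

    @pytest.mark.parametrize("seed", range(8))
    def test_random_dag_order_matches_reference_topological_sort(self, seed):
        rng = random.Random(seed)
        proj = Project()
        ids = []
        for i in range(50):
            sources = rng.sample(ids, k=min(len(ids), rng.randint(0, 2)))
            node = proj.add_node("gel", params={"min_len": 1, "max_len": 10 ** 6},
                                 sources=sources)
            ids.append(node.node_id)
        g = proj.graph()
        root = ids[0]
        scope = {root} | nx.descendants(g, root)
        # give every node something to chew on
        for nid in ids:
            proj.nodes[nid].results = []
            proj.nodes[nid].stale = False
        for nid in ids:
            proj.nodes[nid].results = [generate_fixture(
                FixtureSpec("toy_plasmid", seed=1)).molecules["plasmid"]]
        order = proj.recalculate_children(root)
        assert set(order) == scope
        pos = {nid: i for i, nid in enumerate(order)}
        for nid in order:
            for src in proj.nodes[nid].sources:
                if src in scope:
                    assert pos[src] < pos[nid]


class TestGroupCopyPaste:
    def _chain(self):
        proj = Project()
        a = proj.add_node("sequence_input", "A", {"sequence": "ACGTACGT"})
        b = proj.add_node("gel", "B", {"min_len": 1, "max_len": 100}, [a.node_id])
        c = proj.add_node("feature_screen", "C",
                          {"feature_counts": [["kanR", "eq", 1]]}, [b.node_id])
        return proj, a, b, c

    def test_internal_edges_kept_external_dropped(self):
        proj, a, b, c = self._chain()
        clip = proj.group_copy([b.node_id, c.node_id])
        new = proj.group_paste(clip)
        assert len(new) == 2
        b2, c2 = (proj.nodes[n] for n in new)
        assert b2.sources == []             # edge to non-copied A dropped
        assert c2.sources == [b2.node_id]   # internal edge remapped

    def test_referenced_features_merged(self):
        proj, a, b, c = self._chain()
        proj.feature_library.add("kanR", "ATGAAAGGGAAATTTCCC", "resistance")
        target = Project("target")
        assert "kanR" not in target.feature_library
        target.group_paste(proj.group_copy([c.node_id]))
        assert "kanR" in target.feature_library

    def test_double_paste_four_fresh_ids(self):
        proj, a, b, c = self._chain()
        clip = proj.group_copy([b.node_id, c.node_id])
        ids1 = proj.group_paste(clip)
        ids2 = proj.group_paste(clip)
        assert len(set(ids1) | set(ids2)) == 4


class TestSummaryAndStatus:
    def test_primer_partition(self):
        proj = Project()
        for i in range(6):
            proj.add_primer(Primer(f"p{i}", "ACGTACGTACGTACGTAGGA", ordered=i < 4))
        tpl = proj.add_node("sequence_input", params={"sequence": "ACGT" * 50})
        proj.add_node("pcr", params={"forward": "p0", "reverse": "p1"},
                      sources=[tpl.node_id])
        proj.add_node("pcr", params={"forward": "p2", "reverse": "p3"},
                      sources=[tpl.node_id])
        proj.add_node("pcr", params={"forward": "p4", "reverse": "p5"},
                      sources=[tpl.node_id])
        s = proj.project_summary()
        assert len(s["primers_ordered"]) == 4 and len(s["primers_new"]) == 2
        assert "p4" in s["copy_new"] and "p0" not in s["copy_new"]

    def test_no_pcr_no_primers(self):
        proj = Project()
        proj.add_node("sequence_input", params={"sequence": "ACGT"})
        s = proj.project_summary()
        assert s["primers_new"] == [] and s["primers_ordered"] == []

    def test_enzymes_deduplicated(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGT" * 10})
        proj.add_node("digestion", params={"enzymes": ["EcoRI"]}, sources=[a.node_id])
        proj.add_node("digestion", params={"enzymes": ["EcoRI"]}, sources=[a.node_id])
        assert proj.project_summary()["enzymes"] == ["EcoRI"]

    def test_obsolete_nodes_excluded(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGT" * 10})
        d = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                          sources=[a.node_id])
        proj.set_status(d.node_id, "obsolete")
        assert proj.project_summary()["enzymes"] == []

    def test_status_tokens(self):
        proj = Project()
        a = proj.add_node("sequence_input", params={"sequence": "ACGT"})
        proj.set_status(a.node_id, "completed")     # legacy alias
        assert proj.nodes[a.node_id].status == "finished"
        with pytest.raises(WorkflowError):
            proj.set_status(a.node_id, "done")


class TestPersistence:
    def test_save_load_save_byte_identical(self, tmp_path, plasmid):
        proj = Project("roundtrip")
        proj.add_primer(Primer("fwd", "ACGTACGTACGTACGT", ordered=True))
        proj.feature_library.add("tag", "ACGTTTACGG", "CDS")
        src = _input_node(proj, plasmid)
        d = proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                          sources=[src.node_id])
        proj.set_status(d.node_id, "finished")
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        proj.save(p1)
        Project.load(p1).save(p2)
        assert p1.read_text() == p2.read_text()

    def test_status_survives_round_trip(self, tmp_path, plasmid):
        proj = Project()
        src = _input_node(proj, plasmid)
        proj.set_status(src.node_id, "finished")
        path = tmp_path / "p.json"
        proj.save(path)
        assert Project.load(path).nodes[src.node_id].status == "finished"

    def test_loaded_project_executes(self, tmp_path, plasmid):
        proj = Project()
        src = _input_node(proj, plasmid)
        proj.add_node("digestion", params={"enzymes": ["EcoRI"]},
                      sources=[src.node_id])
        path = tmp_path / "p.json"
        proj.save(path)
        loaded = Project.load(path)
        loaded.execute_all()
        assert all(not n.stale for n in loaded.nodes.values())
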