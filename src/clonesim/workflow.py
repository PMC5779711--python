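"""The project model: a recalculable DAG of operation nodes.

Every wet-lab step is a node holding its parameters, references to the
nodes that supply its substrates, a status, and the cached products of
its last execution.  Editing an upstream node and recalculating its
children re-derives every downstream product in topological order —
the whole point of simulating cloning as a workflow rather than as a
pile of individual files.

Results are content-addressed: a node whose operation kind, parameters
and source-result hashes are unchanged is not re-executed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import cut as _cut
from . import join as _join
from . import pcr as _pcr
from . import screen as _screen
from .cut import EnzymeRegistry, default_registry
from .join import HomologyParams, JoinMode, SiteRegistry, default_sites
from .molecule import (
    DnaMolecule, Feature, FeatureLibrary, annotate_features,
    canonical_hash, parse_end_code, format_end_code,
)
from .pcr import Primer, expand_designer_text, simulate_pcr
from .screen import HostCell, ScreenCondition

__all__ = ["WorkflowNode", "Project", "NODE_STATUSES", "WorkflowError"]

NODE_STATUSES = ("not_started", "in_progress", "finished", "obsolete")
_STATUS_ALIASES = {"completed": "finished"}


class WorkflowError(RuntimeError):
    pass


@dataclass
class WorkflowNode:
    node_id: str
    name: str
    op_kind: str
    params: dict = field(default_factory=dict)
    sources: list[str] = field(default_factory=list)
    status: str = "not_started"
    notes: str = ""
    attachments: dict[str, str] = field(default_factory=dict)
    results: list = field(default_factory=list)
    stale: bool = True
    cache_key: str = ""
    summary: dict = field(default_factory=dict)


class Project:
    """A cloning project: nodes plus the shared registries they use."""

    def __init__(self, name: str = "project"):
        self.name = name
        self.nodes: dict[str, WorkflowNode] = {}
        self.feature_library = FeatureLibrary()
        self.enzymes: EnzymeRegistry = default_registry()
        self.sites: SiteRegistry = default_sites()
        self.primers: dict[str, Primer] = {}
        self.hosts: dict[str, HostCell] = {}
        self.metadata: dict = {}

    # ------------------------------------------------------------------
    # graph construction
    # ------------------------------------------------------------------
    def _fresh_id(self) -> str:
        i = len(self.nodes) + 1
        while f"n{i}" in self.nodes:
            i += 1
        return f"n{i}"

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for src in node.sources:
                g.add_edge(src, node.node_id)
        return g

    def add_node(self, op_kind: str, name: str = "", params: dict | None = None,
                 sources: list[str] | None = None, node_id: str | None = None
                 ) -> WorkflowNode:
        node_id = node_id or self._fresh_id()
        if node_id in self.nodes:
            raise WorkflowError(f"duplicate node id {node_id}")
        node = WorkflowNode(node_id, name or op_kind, op_kind, dict(params or {}),
                            list(sources or []))
        for src in node.sources:
            if src not in self.nodes:
                raise WorkflowError(f"dangling source {src}")
        self.nodes[node_id] = node
        if not nx.is_directed_acyclic_graph(self.graph()):
            del self.nodes[node_id]
            raise WorkflowError("adding this node would create a cycle")
        return node

    def connect(self, node_id: str, source_id: str) -> None:
        if source_id not in self.nodes:
            raise WorkflowError(f"dangling source {source_id}")
        node = self.nodes[node_id]
        node.sources.append(source_id)
        if not nx.is_directed_acyclic_graph(self.graph()):
            node.sources.pop()
            raise WorkflowError("edge would create a cycle")
        node.stale = True

    def add_primer(self, primer: Primer) -> None:
        self.primers[primer.name.lower()] = primer

    def add_host(self, host: HostCell) -> None:
        self.hosts[host.name.lower()] = host

    def set_status(self, node_id: str, status: str) -> None:
        status = _STATUS_ALIASES.get(status, status)
        if status not in NODE_STATUSES:
            raise WorkflowError(f"unknown status {status!r}")
        self.nodes[node_id].status = status

    # ------------------------------------------------------------------
    # execution
    # ------------------------------------------------------------------
    def _resolve_primer(self, spec: str) -> Primer:
        if spec.lower() in self.primers:
            return self.primers[spec.lower()]
        return Primer(f"adhoc_{spec[:8]}", spec)

    def _source_results(self, node: WorkflowNode) -> list:
        out = []
        for src in node.sources:
            s = self.nodes[src]
            if s.stale:
                raise WorkflowError(f"source node {src} is stale; execute it first")
            out.extend(s.results)
        return out

    def _dispatch(self, node: WorkflowNode, inputs: list) -> list:
        p = node.params
        mols = [x for x in inputs if isinstance(x, DnaMolecule)]
        cells = [x for x in inputs if isinstance(x, HostCell)]
        kind = node.op_kind

        if kind == "sequence_input":
            if "path" in p:
                from . import formats
                fmt = p.get("format", "genbank")
                if fmt == "genbank":
                    return [formats.read_genbank(p["path"])]
                if fmt == "fasta":
                    return list(formats.read_fasta(p["path"]))
                return [formats.read_plain(p["path"])]
            topo = p.get("topology", "linear")
            ends = {}
            if topo != "circular":
                ends["left_end"] = parse_end_code(p.get("left_end", "blunt"))
                ends["right_end"] = parse_end_code(p.get("right_end", "blunt"))
                return [DnaMolecule(p.get("id", node.node_id), p["sequence"], topo,
                                    ends["left_end"], ends["right_end"])]
            return [DnaMolecule.circular(p["sequence"], p.get("id", node.node_id))]
        if kind == "host_input":
            return [self.hosts[p["host"].lower()].copy()]
        if kind == "sequence_designer":
            seq = expand_designer_text(p["text"], self.enzymes, self.sites,
                                       self.feature_library)
            topo = p.get("topology", "linear")
            mol = (DnaMolecule.circular(seq, p.get("id", node.node_id)) if topo == "circular"
                   else DnaMolecule.linear(seq, p.get("id", node.node_id)))
            return [mol]
        if kind == "digestion":
            frags, warns = _cut.digest(mols, p["enzymes"], self.enzymes)
            if warns:
                node.notes = "; ".join(warns)
            return frags
        if kind == "crispr":
            guides = [self.enzymes.guides[g.lower()] for g in p["guides"]]
            return _cut.crispr_digest(mols, guides)
        if kind == "modification":
            return _join.modify_ends(mols, p["treatment"])
        if kind == "ligation":
            mode = JoinMode(p.get("mode", "normal"), p.get("rounds", 1),
                            p.get("copies"))
            return _join.ligate(mols, mode)
        if kind == "recombination":
            mode = JoinMode(p.get("mode", "normal"), p.get("rounds", 3), p.get("copies"))
            if "sites" in p:
                sites = [self.sites.get(s) for s in p["sites"]]
                return _join.recombine(mols, sites, mode=mode)
            family = p["family"]
            overrides = {k: p[k] for k in
                         ("min_homology_len", "terminal_window", "min_arm_len") if k in p}
            return _join.recombine(mols, family,
                                   HomologyParams.for_family(family, **overrides), mode)
        if kind == "pcr":
            primers = [self._resolve_primer(x)
                       for x in (p.get("primers") or [p["forward"], p["reverse"]])]
            products, byproducts = simulate_pcr(mols, primers,
                                                p.get("min_anneal_3p", 15))
            node.summary["byproducts"] = len(byproducts)
            return products
        if kind == "gel":
            return _screen.gel_select(mols, p["min_len"], p["max_len"])
        if kind == "feature_screen":
            cond = ScreenCondition(p.get("require_circular"),
                                   [tuple(c) for c in p.get("feature_counts", [])])
            return _screen.feature_screen(mols, cond)
        if kind == "pcr_screen":
            primers = [self._resolve_primer(x) for x in (p.get("primers")
                                                         or [p["forward"], p["reverse"]])]
            return _screen.pcr_screen(mols, primers, (p["min_len"], p["max_len"]),
                                      p.get("min_anneal_3p", 15))
        if kind == "merge":
            merged = _pcr.merge_sequences([m.sequence for m in mols],
                                          p.get("min_overlap", 15))
            return [DnaMolecule.linear(s, f"merge{i + 1}") for i, s in enumerate(merged)]
        if kind == "compare":
            template = mols[0]
            return [_screen.compare_sequences(template, mols[1:])]
        if kind == "transformation":
            host = self.hosts[p["host"].lower()].copy() if "host" in p else cells[0]
            return _screen.transform(host, mols, p.get("method", "chemical"),
                                     p.get("mode", "all_in_one"))
        if kind == "incubation":
            return _screen.incubate(cells, p.get("antibiotics", []),
                                    p.get("overnight", False))
        if kind == "extraction":
            out = []
            for c in cells:
                out.extend(_screen.extract_plasmids(c))
            return out
        raise WorkflowError(f"unknown op kind {kind!r}")

    def _cache_key(self, node: WorkflowNode, inputs: list) -> str:
        h = hashlib.sha256()
        h.update(node.op_kind.encode())
        h.update(json.dumps(node.params, sort_keys=True, default=str).encode())
        for x in inputs:
            if isinstance(x, DnaMolecule):
                h.update(canonical_hash(x).encode())
            elif isinstance(x, HostCell):
                h.update(x.name.encode())
                for m in x.hosted + x.genome_fragments:
                    h.update(canonical_hash(m).encode())
        return h.hexdigest()

    def execute_node(self, node_id: str) -> list:
        node = self.nodes[node_id]
        inputs = self._source_results(node)
        key = self._cache_key(node, inputs)
        if key == node.cache_key and node.results and not node.stale:
            return node.results
        try:
            results = self._dispatch(node, inputs)
        except WorkflowError:
            raise
        except Exception as exc:
            raise WorkflowError(f"node {node_id} ({node.op_kind}) failed: {exc}") from exc
        # every DNA product is auto-annotated against the project library
        if len(self.feature_library):
            results = [annotate_features(r, self.feature_library)
                       if isinstance(r, DnaMolecule) else r for r in results]
        node.results = results
        node.stale = False
        node.cache_key = key
        mols = [r for r in results if isinstance(r, DnaMolecule)]
        node.summary.update({
            "count": len(results),
            "lengths": sorted(len(m.sequence) for m in mols),
            "hashes": sorted(canonical_hash(m) for m in mols),
        })
        return results

    def execute_all(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.graph()))
        for nid in order:
            self.execute_node(nid)
        return order

    def recalculate_children(self, node_id: str) -> list[str]:
        """Re-execute the node and all its descendants in topological
        order; a failing node and its descendants are marked stale and
        the remaining branches continue.  Returns the ids actually
        recalculated."""
        if node_id not in self.nodes:
            raise WorkflowError(f"unknown node {node_id}")
        g = self.graph()
        scope = {node_id} | nx.descendants(g, node_id)
        for nid in scope:
            self.nodes[nid].stale = True
        order = [n for n in nx.lexicographical_topological_sort(g) if n in scope]
        done: list[str] = []
        failed: set[str] = set()
        for nid in order:
            if any(src in failed and src in scope or
                   (src in scope and self.nodes[src].stale)
                   for src in self.nodes[nid].sources):
                failed.add(nid)
                continue
            try:
                self.execute_node(nid)
                done.append(nid)
            except WorkflowError:
                failed.add(nid)
        return done

    # ------------------------------------------------------------------
    # group copy / paste
    # ------------------------------------------------------------------
    def group_copy(self, node_ids: list[str]) -> dict:
        """Copy nodes with their internal relations plus the registry
        entries they reference."""
        chosen = set(node_ids)
        clip_nodes = []
        for nid in node_ids:
            node = self.nodes[nid]
            clip_nodes.append({
                "node_id": nid, "name": node.name, "op_kind": node.op_kind,
                "params": json.loads(json.dumps(node.params)),
                "sources": [s for s in node.sources if s in chosen],
                "status": node.status, "notes": node.notes,
            })
        features = {}
        for nid in node_ids:
            node = self.nodes[nid]
            for name, _, count in node.params.get("feature_counts", []):
                entry = self.feature_library.get(name)
                if entry:
                    features[name] = entry
        return {"nodes": clip_nodes, "features": features}

    def group_paste(self, clipboard: dict) -> list[str]:
        mapping = {}
        new_ids = []
        for spec in clipboard["nodes"]:
            nid = self._fresh_id()
            mapping[spec["node_id"]] = nid
            node = WorkflowNode(nid, spec["name"], spec["op_kind"],
                                dict(spec["params"]),
                                [mapping[s] for s in spec["sources"] if s in mapping],
                                status=spec.get("status", "not_started"),
                                notes=spec.get("notes", ""))
            self.nodes[nid] = node
            new_ids.append(nid)
        for name, (seq, kind, quals) in clipboard.get("features", {}).items():
            if name not in self.feature_library:
                self.feature_library.add(name, seq, kind, quals)
        return new_ids

    # ------------------------------------------------------------------
    # summary
    # ------------------------------------------------------------------
    def project_summary(self) -> dict:
        primers_used: dict[str, Primer] = {}
        enzymes_used: set[str] = set()
        treatments: set[str] = set()
        to_synthesize: list[str] = []
        for node in self.nodes.values():
            if node.status == "obsolete":
                continue
            p = node.params
            if node.op_kind in ("pcr", "pcr_screen"):
                for spec in (p.get("primers") or
                             [p.get("forward"), p.get("reverse")]):
                    if spec:
                        pr = self._resolve_primer(spec)
                        primers_used[pr.name.lower()] = pr
            elif node.op_kind == "digestion":
                for e in p.get("enzymes", []):
                    enzymes_used.add(self.enzymes.resolve_canonical(e)
                                     if isinstance(e, str) else e.canonical_name)
            elif node.op_kind == "modification":
                treatments.add(p["treatment"])
            elif node.op_kind == "sequence_designer" and p.get("synthesize"):
                if node.results:
                    to_synthesize.extend(m.sequence for m in node.results)
        ordered = sorted(pr.name for pr in primers_used.values() if pr.ordered)
        new = sorted(pr.name for pr in primers_used.values() if not pr.ordered)
        return {
            "primers_ordered": ordered,
            "primers_new": new,
            "copy_new": "\n".join(f"{primers_used[n.lower()].name}\t"
                                  f"{primers_used[n.lower()].sequence}" for n in new),
            "enzymes": sorted(enzymes_used),
            "modification_treatments": sorted(treatments),
            "to_synthesize": to_synthesize,
        }

    # ------------------------------------------------------------------
    # persistence (canonical JSON)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def mol2d(m: DnaMolecule) -> dict:
            d = {"id": m.id, "sequence": m.sequence, "topology": m.topology,
                 "provenance": m.provenance,
                 "features": [[f.name, f.kind, f.start, f.end, f.strand,
                               dict(sorted(f.qualifiers.items()))] for f in m.features]}
            if not m.is_circular:
                d["left_end"] = format_end_code(m.left_end)
                d["right_end"] = format_end_code(m.right_end)
            return d

        def cell2d(c: HostCell) -> dict:
            return {"name": c.name, "primase_commands": sorted(c.primase_commands),
                    "intrinsic_resistances": sorted(c.intrinsic_resistances),
                    "genome_fragments": [mol2d(g) for g in c.genome_fragments],
                    "hosted": [mol2d(p) for p in c.hosted],
                    "transfer_competence": sorted(c.transfer_competence)}

        return {
            "name": self.name,
            "metadata": dict(sorted(self.metadata.items())),
            "features": [[name, seq, kind, dict(sorted(quals.items()))]
                         for name, seq, kind, quals in self.feature_library.items()],
            "primers": [[p.name, p.sequence, p.fixed, p.phosphorylated, p.ordered]
                        for _, p in sorted(self.primers.items())],
            "hosts": [cell2d(h) for _, h in sorted(self.hosts.items())],
            "nodes": [{
                "node_id": n.node_id, "name": n.name, "op_kind": n.op_kind,
                "params": n.params, "sources": n.sources, "status": n.status,
                "notes": n.notes, "attachments": dict(sorted(n.attachments.items())),
            } for _, n in sorted(self.nodes.items())],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Project":
        data = json.loads(Path(path).read_text())
        proj = cls(data.get("name", "project"))
        proj.metadata = data.get("metadata", {})
        for name, seq, kind, quals in data.get("features", []):
            proj.feature_library.add(name, seq, kind, quals)
        for name, seq, fixed, phos, ordered in data.get("primers", []):
            proj.add_primer(Primer(name, seq, fixed, phos, ordered))

        def d2mol(d: dict) -> DnaMolecule:
            feats = [Feature(*f[:5], dict(f[5])) for f in d.get("features", [])]
            if d["topology"] == "circular":
                return DnaMolecule.circular(d["sequence"], d["id"], features=feats,
                                            provenance=d.get("provenance", ""))
            return DnaMolecule(d["id"], d["sequence"], d["topology"],
                               parse_end_code(d.get("left_end", "blunt")),
                               parse_end_code(d.get("right_end", "blunt")),
                               feats, d.get("provenance", ""))

        for h in data.get("hosts", []):
            proj.add_host(HostCell(h["name"], [d2mol(g) for g in h["genome_fragments"]],
                                   list(h["primase_commands"]),
                                   list(h["intrinsic_resistances"]),
                                   [d2mol(p) for p in h["hosted"]],
                                   set(h["transfer_competence"])))
        for n in data.get("nodes", []):
            node = WorkflowNode(n["node_id"], n["name"], n["op_kind"], n["params"],
                                n["sources"], n.get("status", "not_started"),
                                n.get("notes", ""), n.get("attachments", {}))
            proj.nodes[node.node_id] = node
        if not nx.is_directed_acyclic_graph(proj.graph()):
            raise WorkflowError("project file contains a cyclic workflow")
        return proj
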