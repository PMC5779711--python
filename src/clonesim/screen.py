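"""Product selection and the host-cell simulation.

Covers the selection steps of a cloning workflow — gel separation,
feature (marker) screening, colony-PCR screening, sequence comparison of
sequencing reads against a theoretical construct, ORF detection — and
the bacterial host side: transformation, incubation with replication
and antibiotic selection, and plasmid extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .molecule import (
    DnaMolecule, Feature, clone, reverse_complement_seq,
)
from .pcr import Primer, simulate_pcr

__all__ = [
    "GEL_FLOOR_BP", "ScreenCondition", "HostCell",
    "gel_select", "feature_screen", "pcr_screen",
    "compare_sequences", "detect_orfs",
    "transform", "incubate", "extract_plasmids",
]

#: fragments shorter than this are invisible on the simulated gel and
#: always discarded, whatever range the user asks for
GEL_FLOOR_BP = 50


def gel_select(mols: list[DnaMolecule], min_len: int, max_len: int
               ) -> list[DnaMolecule]:
    """Select molecules whose length falls in [min_len, max_len]
    (inclusive), after discarding everything below the gel floor."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    visible = [m for m in mols if len(m.sequence) >= GEL_FLOOR_BP]
    return [m for m in visible if min_len <= len(m.sequence) <= max_len]


@dataclass
class ScreenCondition:
    """Feature-screening criteria: optional circularity requirement plus
    per-feature-name count conditions (comparator in gt/lt/eq)."""
    require_circular: bool | None = None
    feature_counts: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.require_circular is None and not self.feature_counts:
            raise ValueError("at least one screening criterion required")
        for _, cmp_, _ in self.feature_counts:
            if cmp_ not in ("gt", "lt", "eq"):
                raise ValueError("comparator must be gt, lt or eq")


def feature_screen(mols: list[DnaMolecule], cond: ScreenCondition
                   ) -> list[DnaMolecule]:
    """Molecules satisfying all criteria; counts are per-name
    occurrences regardless of strand."""
    out = []
    for m in mols:
        if cond.require_circular is not None and m.is_circular != cond.require_circular:
            continue
        ok = True
        for name, cmp_, want in cond.feature_counts:
            have = sum(1 for f in m.features if f.name.lower() == name.lower())
            if cmp_ == "eq" and have != want:
                ok = False
            elif cmp_ == "gt" and not have > want:
                ok = False
            elif cmp_ == "lt" and not have < want:
                ok = False
            if not ok:
                break
        if ok:
            out.append(m)
    return out


def pcr_screen(mols: list[DnaMolecule], primers: list[Primer],
               len_range: tuple[int, int], min_anneal_3p: int = 15
               ) -> list[DnaMolecule]:
    """Keep the molecules on which the primer set yields at least one
    PCR product whose length falls inside ``len_range`` (inclusive)."""
    lo, hi = len_range
    kept = []
    for m in mols:
        products, _ = simulate_pcr([m], primers, min_anneal_3p=min_anneal_3p)
        if any(lo <= len(p.sequence) <= hi for p in products):
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# sequence comparison
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    # semi-global, affine gaps: match 2 / mismatch -3 / open -5 / extend -2,
    # template end gaps free so a read aligns anywhere on the construct
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
    else:   # older Biopython naming
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
    return aligner


def compare_sequences(template: DnaMolecule, queries: list[DnaMolecule | str],
                      score_floor_per_base: float = 0.6) -> DnaMolecule:
    """Align each query (sequencing read) to the template and record
    matches, mismatches, insertions and deletions as features on a copy
    of the template.  Multiple queries stack on one template; a query
    scoring below the floor is annotated as unaligned."""
    out = clone(template)
    n = len(template.sequence)
    target = template.sequence + template.sequence if template.is_circular \
        else template.sequence
    aligner = _make_aligner()

    def norm(pos: int) -> int:
        return pos % n if template.is_circular else pos

    for qi, q in enumerate(queries):
        qname = q.id if isinstance(q, DnaMolecule) else f"query{qi + 1}"
        qseq = q.sequence if isinstance(q, DnaMolecule) else str(q).upper()
        best = None
        for qs, strand in ((qseq, "+"), (reverse_complement_seq(qseq), "-")):
            aln = aligner.align(target, qs)[0]
            if best is None or aln.score > best[0].score:
                best = (aln, strand)
        aln, strand = best
        if aln.score < score_floor_per_base * len(qseq):
            out.features.append(Feature(qname, "alignment_unaligned", 0, len(out.sequence),
                                        "+", {"query": qname, "score": str(aln.score)}))
            continue
        tb = [(int(s), int(e)) for s, e in aln.aligned[0]]
        qb = [(int(s), int(e)) for s, e in aln.aligned[1]]
        quals = {"query": qname}
        prev_t = prev_q = None
        aln_query = str(aln.query)
        for (ts, te), (qs_, qe) in zip(tb, qb):
            if prev_t is not None:
                if ts > prev_t and qs_ == prev_q:
                    out.features.append(Feature(qname, "alignment_deletion",
                                                norm(prev_t), norm(prev_t) + (ts - prev_t),
                                                strand, dict(quals)))
                elif qs_ > prev_q and ts == prev_t:
                    out.features.append(Feature(
                        qname, "alignment_insertion", norm(ts), norm(ts) + 1, strand,
                        {**quals, "inserted": aln_query[prev_q:qs_]}))
            # split the gapless block into exact-match runs and mismatches
            run_start = ts
            for k in range(te - ts + 1):
                t_pos, q_pos = ts + k, qs_ + k
                mismatch = k < te - ts and target[t_pos] != aln_query[q_pos]
                if mismatch or k == te - ts:
                    if t_pos > run_start:
                        out.features.append(Feature(qname, "alignment_match",
                                                    norm(run_start),
                                                    norm(run_start) + (t_pos - run_start),
                                                    strand, dict(quals)))
                    if mismatch:
                        out.features.append(Feature(
                            qname, "alignment_mismatch", norm(t_pos), norm(t_pos) + 1,
                            strand, {**quals, "observed": aln_query[q_pos]}))
                        run_start = t_pos + 1
                    else:
                        run_start = t_pos
            prev_t, prev_q = te, qe
    return out


# ---------------------------------------------------------------------------
# ORF detection
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def detect_orfs(mol: DnaMolecule, start_codons: set[str] = frozenset({"ATG"}),
                min_len: int = 300, both_strands: bool = True) -> list[Feature]:
    """Start-codon-to-in-frame-stop intervals of at least ``min_len``
    (stop codon included); all frames, both strands on request, wrapping
    honoured on circles."""
    if min_len < 3 or min_len % 3:
        raise ValueError("min_len must be >= 3 and divisible by 3")
    for c in start_codons:
        if len(c) != 3:
            raise ValueError("start codons must be 3-mers")
    orfs: list[Feature] = []
    n = len(mol.sequence)

    def scan(seq: str, strand: str):
        limit = len(seq)
        starts = [i for i in range(limit - 2) if seq[i:i + 3] in start_codons and i < n]
        for s in starts:
            j = s + 3
            while j + 3 <= limit and j + 3 - s <= n:
                codon = seq[j:j + 3]
                j += 3
                if codon in _STOPS:
                    if j - s >= min_len:
                        if strand == "+":
                            orfs.append(Feature(f"ORF_{s}", "ORF", s, j, "+"))
                        else:
                            orfs.append(Feature(f"ORF_{n - j}", "ORF", n - j, n - s, "-"))
                    break

    scan(mol.sequence + (mol.sequence if mol.is_circular else ""), "+")
    if both_strands:
        rc = reverse_complement_seq(mol.sequence)
        scan(rc + (rc if mol.is_circular else ""), "-")
    # normalise wrapped coordinates into [0, n)
    fixed = []
    seen = set()
    for f in orfs:
        s, e = f.start % n, f.start % n + (f.end - f.start)
        g = Feature(f.name, f.kind, s, e, f.strand, dict(f.qualifiers))
        if g.ident() not in seen:
            seen.add(g.ident())
            fixed.append(g)
    return sorted(fixed, key=lambda f: (f.start, f.end, f.strand))


# ---------------------------------------------------------------------------
# host cells
# ---------------------------------------------------------------------------

@dataclass
class HostCell:
    """A simulated strain: genome fragments, the replication origins its
    machinery can fire (primase commands), intrinsic resistances, and
    the plasmids it currently hosts."""
    name: str
    genome_fragments: list[DnaMolecule] = field(default_factory=list)
    primase_commands: list[str] = field(default_factory=list)
    intrinsic_resistances: list[str] = field(default_factory=list)
    hosted: list[DnaMolecule] = field(default_factory=list)
    transfer_competence: set[str] = field(default_factory=lambda: {"chemical", "electro"})

    def copy(self, suffix: str = "") -> "HostCell":
        return HostCell(self.name + suffix, [clone(g) for g in self.genome_fragments],
                        list(self.primase_commands), list(self.intrinsic_resistances),
                        [clone(p) for p in self.hosted], set(self.transfer_competence))


def transform(host: HostCell, dnas: list[DnaMolecule], method: str = "chemical",
              mode: str = "all_in_one") -> list[HostCell]:
    """Transformation: 'all_in_one' puts every DNA in one cell,
    'one_per_cell' makes one cell per DNA, 'combinational' one cell per
    non-empty subset."""
    if method not in host.transfer_competence:
        raise ValueError(f"host {host.name} is not competent for {method}")
    if mode == "all_in_one":
        cell = host.copy("+all")
        cell.hosted.extend(clone(d) for d in dnas)
        return [cell]
    if mode == "one_per_cell":
        cells = []
        for i, d in enumerate(dnas):
            cell = host.copy(f"+{i + 1}")
            cell.hosted.append(clone(d))
            cells.append(cell)
        return cells
    if mode == "combinational":
        cells = []
        for mask in range(1, 2 ** len(dnas)):
            cell = host.copy(f"+c{mask}")
            for i, d in enumerate(dnas):
                if mask >> i & 1:
                    cell.hosted.append(clone(d))
            cells.append(cell)
        return cells
    raise ValueError(f"unknown transformation mode {mode!r}")


def _ori_names(mol: DnaMolecule) -> set[str]:
    return {f.qualifiers.get("origin", f.name) for f in mol.features if f.kind == "ori"}


def _resistances(mol: DnaMolecule) -> set[str]:
    return {f.qualifiers.get("antibiotic", f.name) for f in mol.features
            if f.kind == "resistance"}


def incubate(cells: list[HostCell], antibiotics: list[str] | None = None,
             overnight: bool = False) -> list[HostCell]:
    """Replication + selection.  A hosted plasmid persists only if one of
    its ori features matches a host primase command; overnight incubation
    with antibiotics then keeps only cells with a matching resistance on
    a persisting plasmid, an integrated copy, or intrinsically."""
    antibiotics = antibiotics or []
    survivors = []
    for cell in cells:
        c = cell.copy()
        c.hosted = [p for p in c.hosted
                    if _ori_names(p) & set(c.primase_commands)]
        if overnight and antibiotics:
            have = set(c.intrinsic_resistances)
            for p in c.hosted:
                have |= _resistances(p)
            for g in c.genome_fragments:
                have |= _resistances(g)
            if not set(antibiotics) <= have:
                continue
        survivors.append(c)
    return survivors


def extract_plasmids(cell: HostCell) -> list[DnaMolecule]:
    """All DNA hosted in a cell, excluding the host genome; the cell is
    left untouched."""
    return [clone(p) for p in cell.hosted]
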