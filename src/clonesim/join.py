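"""Everything that joins DNA.

* End modification (CIAP, PNK, Klenow / T4 polymerase blunting).
* The ligation engine: two ends join when (1) at least one of them
  carries a 5' phosphate and (2) both are blunt, or both overhangs have
  the same polarity and reverse-complementary protruding sequences.
  Normal mode is a bounded breadth search with per-fragment copy limits;
  exhaustive mode returns only products consuming exactly the requested
  copy count of every fragment (multi-part assembly semantics).
* Recombination as virtual digestion + virtual ligation: recombination
  sites (or shared homology blocks) are treated as virtual restriction
  sites whose cuts produce marker-labelled pseudo-overhangs; the
  ligation engine is then rerun with marker compatibility in place of
  the phosphate rule, and every molecule still carrying a virtual end is
  discarded at the end so only physically real products remain.
* The Gibson assembly designer, which picks junction overlaps, extends
  non-fixed PCR primers with them, and verifies the design by running
  the in-vivo-annealing recombination in exhaustive mode.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
from collections import Counter
from dataclasses import dataclass, replace

from .cut import CutEvent, apply_cuts
from .molecule import (
    BLUNT, THREE_PRIME,
    DnaEnd, DnaMolecule, Feature, canonical_hash, clone, find_pattern,
    reverse_complement, reverse_complement_seq, _check_dna,
)

log = logging.getLogger(__name__)

__all__ = [
    "RecombinationSite", "SiteRegistry", "default_sites",
    "JoinMode", "HomologyParams",
    "modify_ends", "ligate", "recombine",
    "GibsonSource", "GibsonDesign", "GibsonDesignError", "design_gibson",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombinationSite:
    name: str
    sequence: str
    core_start: int
    core_end: int
    reversible: bool
    partner_names: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.core_start < self.core_end <= len(self.sequence)):
            raise ValueError("core interval must be non-empty and inside the site")

    @property
    def core(self) -> str:
        return self.sequence[self.core_start:self.core_end]


class SiteRegistry:
    def __init__(self):
        self.sites: dict[str, RecombinationSite] = {}

    def add(self, site: RecombinationSite) -> None:
        self.sites[site.name.lower()] = site

    def get(self, name: str) -> RecombinationSite:
        try:
            return self.sites[name.lower()]
        except KeyError:
            raise KeyError(f"unknown recombination site {name!r}") from None

    def load_table(self, text: str) -> None:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            name, seq, cs, ce, rev = cols[:5]
            partners = tuple(p.strip() for p in cols[5].split(",")) if len(cols) > 5 and cols[5] else ()
            self.add(RecombinationSite(name, _check_dna(seq), int(cs), int(ce),
                                       rev.lower() in ("yes", "true", "1"), partners))

    def __iter__(self):
        return iter(self.sites[k] for k in sorted(self.sites))


def default_sites() -> SiteRegistry:
    reg = SiteRegistry()
    text = (importlib.resources.files("clonesim.data") / "recomb_sites.tsv").read_text()
    reg.load_table(text)
    return reg


@dataclass
class JoinMode:
    mode: str = "normal"          # normal | exhaustive
    rounds: int = 1               # normal mode: joining rounds
    copies: dict[str, int] | int | None = None   # per-fragment copy limit/target

    def __post_init__(self):
        if self.mode not in ("normal", "exhaustive"):
            raise ValueError("mode must be 'normal' or 'exhaustive'")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class HomologyParams:
    """Homology search windows per recombination family.

    ``terminal_window`` bounds where on a linear substrate a shared
    block may lie (distance of its distal edge from the nearer
    terminus): 100 bp for lambda Red, 250 bp for the annealing-based
    assemblies, unbounded for plain homologous recombination.
    """
    family: str
    min_homology_len: int
    terminal_window: int | None
    min_arm_len: int = 0

    _DEFAULTS = {
        "homologous": (20, None, 0),
        "lambda_red": (20, 100, 20),
        "in_vitro_annealing": (15, 250, 0),
        "in_vivo_annealing": (15, 250, 0),
    }

    @classmethod
    def for_family(cls, family: str, **overrides) -> "HomologyParams":
        if family not in cls._DEFAULTS:
            raise ValueError(f"unknown recombination family {family!r}")
        mh, window, arm = cls._DEFAULTS[family]
        p = cls(family, mh, window, arm)
        for k, v in overrides.items():
            setattr(p, k, v)
        p.__post_init__()   # re-validate after overrides
        return p

    def __post_init__(self):
        if self.min_homology_len < 8:
            raise ValueError("min_homology_len must be >= 8")
        if self.terminal_window is not None and self.terminal_window <= 0:
            raise ValueError("terminal_window must be positive where bounded")


# ---------------------------------------------------------------------------
# end modification
# ---------------------------------------------------------------------------

def modify_ends(mols: list[DnaMolecule], treatment: str) -> list[DnaMolecule]:
    """CIAP removes 5' phosphates; PNK adds them; Klenow / T4 polymerase
    blunting fills in 5' overhangs and trims 3' overhangs."""
    if treatment not in ("CIAP", "PNK", "Klenow", "T4_blunt"):
        raise ValueError(f"unknown treatment {treatment!r}")
    out = []
    for mol in mols:
        if mol.is_circular:
            if treatment in ("Klenow", "T4_blunt"):
                raise ValueError("blunting requires linear substrates")
            out.append(clone(mol))
            continue
        m = clone(mol)
        if treatment in ("CIAP", "PNK"):
            phos = treatment == "PNK"
            m.left_end = replace(m.left_end, phosphorylated=phos)
            m.right_end = replace(m.right_end, phosphorylated=phos)
            out.append(m)
            continue
        # blunting
        if m.left_end.hairpin or m.right_end.hairpin:
            raise ValueError("hairpin ends cannot be blunted")
        seq = m.sequence
        feats = m.features
        lk = len(m.left_end.overhang_seq)
        rk = len(m.right_end.overhang_seq)
        if m.left_end.overhang == THREE_PRIME and lk:
            seq = seq[lk:]
            feats = [Feature(f.name, f.kind, max(f.start - lk, 0), f.end - lk, f.strand,
                             dict(f.qualifiers)) for f in feats if f.end - lk > 0]
        if m.right_end.overhang == THREE_PRIME and rk:
            seq = seq[:-rk]
            feats = [Feature(f.name, f.kind, f.start, min(f.end, len(seq)), f.strand,
                             dict(f.qualifiers)) for f in feats if f.start < len(seq)]
        m.sequence = seq
        m.features = feats
        m.left_end = DnaEnd(BLUNT, "", m.left_end.phosphorylated)
        m.right_end = DnaEnd(BLUNT, "", m.right_end.phosphorylated)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# ligation engine
# ---------------------------------------------------------------------------

def _ends_joinable(right: DnaEnd, left: DnaEnd, virtual: bool,
                   marker_compat=None) -> bool:
    """Can the right end of one fragment join the left end of another?"""
    if right.hairpin or left.hairpin:
        return False
    if virtual:
        if not (right.is_virtual and left.is_virtual):
            return False
        if marker_compat is not None and not marker_compat(right.virtual_marker,
                                                           left.virtual_marker):
            return False
    else:
        if right.is_virtual or left.is_virtual:
            return False
        if not (right.phosphorylated or left.phosphorylated):
            return False
    if right.overhang != left.overhang:
        return False
    if right.overhang == BLUNT:
        return True
    a, b = right.overhang_seq, left.overhang_seq
    if len(a) != len(b):
        return False
    if set(a) - set("ACGT") or set(b) - set("ACGT"):
        return False   # degenerate overhangs never produce a concrete joint
    return reverse_complement_seq(a) == b


def _merge_features(feats_a, feats_b, shift_b):
    merged = {f.ident(): f for f in feats_a}
    for f in feats_b:
        g = f.shifted(shift_b)
        merged.setdefault(g.ident(), g)
    return sorted(merged.values(), key=lambda f: (f.start, f.end, f.name))


def _join_linear(a: DnaMolecule, b: DnaMolecule) -> DnaMolecule:
    k = len(a.right_end.overhang_seq)
    seq = a.sequence + b.sequence[k:]
    topo = "genomic_fragment" if "genomic_fragment" in (a.topology, b.topology) else "linear"
    return DnaMolecule(f"({a.id}+{b.id})", seq, topo, a.left_end, b.right_end,
                       _merge_features(a.features, b.features, len(a.sequence) - k),
                       provenance=f"ligation of {a.id} and {b.id}")


def _circularize(a: DnaMolecule) -> DnaMolecule:
    k = len(a.right_end.overhang_seq)
    n = len(a.sequence) - k
    feats = {}
    for f in a.features:
        s, e = f.start, f.end
        if s >= n:
            s, e = s - n, e - n
        g = Feature(f.name, f.kind, s, e, f.strand, dict(f.qualifiers))
        feats.setdefault(g.ident(), g)
    return DnaMolecule(f"circ({a.id})", a.sequence[:n], "circular", None, None,
                       sorted(feats.values(), key=lambda f: (f.start, f.end, f.name)),
                       provenance=f"circularization of {a.id}")


@dataclass
class _Asm:
    mol: DnaMolecule
    usage: Counter
    n_joins: int = 0


def _copy_table(mols: list[DnaMolecule], copies) -> tuple[list[DnaMolecule], dict[str, int]]:
    uniq: dict[str, DnaMolecule] = {}
    counts: Counter = Counter()
    for m in mols:
        uniq.setdefault(m.id, m)
        counts[m.id] += 1
    if copies is None:
        table = dict(counts)
    elif isinstance(copies, int):
        table = {mid: copies for mid in uniq}
    else:
        table = {mid: int(copies.get(mid, 1)) for mid in uniq}
    return list(uniq.values()), table


def _closure(frags: list[DnaMolecule], limits: dict[str, int], rounds: int,
             virtual: bool, marker_compat=None, include_inputs: bool = True
             ) -> dict[str, _Asm]:
    """Bounded pairwise-joining search with canonical-hash dedup."""
    pool: dict[str, _Asm] = {}
    for f in frags:
        pool.setdefault(canonical_hash(f), _Asm(f, Counter({f.id: 1})))
    for _ in range(rounds):
        changed = False
        current = sorted(pool.items())
        for _, x in current:
            if x.mol.is_circular:
                continue
            for _, y in current:
                if y.mol.is_circular:
                    continue
                combined = x.usage + y.usage
                if any(combined[k] > limits.get(k, 1) for k in combined):
                    continue
                for xmol in (x.mol, reverse_complement(x.mol)):
                    for ymol in (y.mol, reverse_complement(y.mol)):
                        if _ends_joinable(xmol.right_end, ymol.left_end, virtual,
                                          marker_compat):
                            z = _join_linear(xmol, ymol)
                            h = canonical_hash(z)
                            if h not in pool:
                                pool[h] = _Asm(z, combined, x.n_joins + y.n_joins + 1)
                                changed = True
        # circularization pass (includes products formed this round)
        for _, x in sorted(pool.items()):
            if x.mol.is_circular:
                continue
            if _ends_joinable(x.mol.right_end, x.mol.left_end, virtual, marker_compat):
                z = _circularize(x.mol)
                h = canonical_hash(z)
                if h not in pool:
                    pool[h] = _Asm(z, Counter(x.usage), x.n_joins + 1)
                    changed = True
        if not changed:
            break
    if not include_inputs:
        input_hashes = {canonical_hash(f) for f in frags}
        pool = {h: a for h, a in pool.items() if h not in input_hashes or a.n_joins}
    return pool


def _exhaustive_chains(frags: list[DnaMolecule], targets: dict[str, int],
                       virtual: bool = False, marker_compat=None
                       ) -> list[DnaMolecule]:
    """All linear/circular products consuming exactly the target copy
    count of every fragment (order/orientation enumerated, hash-deduped)."""
    total = sum(targets.values())
    products: dict[str, DnaMolecule] = {}
    by_id = {f.id: f for f in frags}

    def extend(chain: DnaMolecule, used: Counter):
        if sum(used.values()) == total:
            if total > 1:
                products.setdefault(canonical_hash(chain), chain)
            if _ends_joinable(chain.right_end, chain.left_end, virtual, marker_compat):
                circ = _circularize(chain)
                products.setdefault(canonical_hash(circ), circ)
            return
        for fid in sorted(by_id):
            if used[fid] >= targets.get(fid, 0):
                continue
            f = by_id[fid]
            for fmol in (f, reverse_complement(f)):
                if _ends_joinable(chain.right_end, fmol.left_end, virtual, marker_compat):
                    used2 = used.copy()
                    used2[fid] += 1
                    extend(_join_linear(chain, fmol), used2)

    for fid in sorted(by_id):
        if targets.get(fid, 0) < 1:
            continue
        f = by_id[fid]
        for fmol in (f, reverse_complement(f)):
            extend(fmol, Counter({fid: 1}))
    return [products[h] for h in sorted(products)]


def _canonical_orientation(mol: DnaMolecule) -> DnaMolecule:
    """Present a linear molecule on its lexicographically minimal strand
    so product orientation does not depend on search order."""
    if mol.is_circular:
        return mol
    flipped = reverse_complement(mol)
    fwd = (mol.sequence, mol.left_end.key(), mol.right_end.key())
    rev = (flipped.sequence, flipped.left_end.key(), flipped.right_end.key())
    return flipped if rev < fwd else mol


def ligate(mols: list[DnaMolecule], mode: JoinMode | None = None) -> list[DnaMolecule]:
    """Simulate a ligation reaction over a pool of molecules.

    Normal mode returns the reaction mixture: unreacted substrates plus
    every distinct linear and circular product reachable within
    ``mode.rounds`` joining rounds under the per-fragment copy limits
    (self-circularization included).  Exhaustive mode returns only the
    products consuming exactly the specified copy count of every
    fragment.  An empty product list is a valid outcome.
    """
    if not mols:
        raise ValueError("at least one substrate required")
    mode = mode or JoinMode()
    frags, table = _copy_table(mols, mode.copies)
    if mode.mode == "exhaustive":
        return [_canonical_orientation(m)
                for m in _exhaustive_chains(frags, table, virtual=False)]
    pool = _closure(frags, table, mode.rounds, virtual=False)
    return [_canonical_orientation(pool[h].mol) for h in sorted(pool)]


# ---------------------------------------------------------------------------
# recombination: virtual digestion + virtual ligation
# ---------------------------------------------------------------------------

_recombine_ns = itertools.count(1)


def _normalize_circular_event(t: int, b: int, n: int) -> tuple[int, int]:
    start = min(t, b)
    shift = (start % n) - start
    return t + shift, b + shift


def _site_cut_events(mol: DnaMolecule, sites: list[RecombinationSite], ns: str
                     ) -> list[CutEvent]:
    n = len(mol.sequence)
    events: dict[tuple, CutEvent] = {}
    for site in sites:
        slen = len(site.sequence)
        for pos, strand in find_pattern(mol, site.sequence, both_strands=True):
            if strand == "+":
                t, b = pos + site.core_start, pos + site.core_end
                up, down = "A", "B"
            else:
                t, b = pos + slen - site.core_end, pos + slen - site.core_start
                up, down = "B", "A"
            if mol.is_circular:
                t, b = _normalize_circular_event(t, b, n)
            elif min(t, b) < 0 or max(t, b) > n:
                continue
            events.setdefault((t, b, site.name, up), CutEvent(
                t, b, f"site:{site.name}", pos, pos + slen,
                up_marker=f"{ns}:site:{site.name}:{up}",
                down_marker=f"{ns}:site:{site.name}:{down}"))
    return [events[k] for k in sorted(events)]


def _site_marker_compat(site_lookup: dict[str, RecombinationSite]):
    def compat(m1: str, m2: str) -> bool:
        try:
            ns1, _, name1, side1 = m1.rsplit(":", 3)
            ns2, _, name2, side2 = m2.rsplit(":", 3)
        except (ValueError, AttributeError):
            return False
        if ns1 != ns2 or side1 == side2:
            return False
        s1 = site_lookup.get(name1.lower())
        s2 = site_lookup.get(name2.lower())
        if s1 is None or s2 is None:
            return False
        return s2.name in s1.partner_names or s1.name in s2.partner_names
    return compat


def _hom_marker_compat(m1: str, m2: str) -> bool:
    return m1 == m2


def _maximal_common_blocks(a: str, b: str, min_len: int) -> list[tuple[int, int, int, str]]:
    """Maximal exact shared substrings >= min_len between a and b (both
    orientations of b); returns (a_start, b_start_on_top, length, orient)."""
    results = set()
    k = min_len
    for orient in ("+", "-"):
        bb = b if orient == "+" else reverse_complement_seq(b)
        seeds: dict[str, list[int]] = {}
        for i in range(len(a) - k + 1):
            seeds.setdefault(a[i:i + k], []).append(i)
        # group seed hits by diagonal; consecutive k-mer hits on one
        # diagonal form one maximal common substring
        diagonals: dict[int, list[int]] = {}
        for j in range(len(bb) - k + 1):
            for i in seeds.get(bb[j:j + k], ()):
                diagonals.setdefault(i - j, []).append(j)
        for diag, js in diagonals.items():
            js = sorted(set(js))
            merged_start = None
            prev = None
            runs = []
            for j in js:
                if prev is not None and j == prev + 1:
                    prev = j
                    continue
                if prev is not None:
                    runs.append((merged_start, prev + k))
                merged_start, prev = j, j
            if prev is not None:
                runs.append((merged_start, prev + k))
            for j0, j1 in runs:
                i0 = j0 + diag
                length = j1 - j0
                if orient == "+":
                    results.add((i0, j0, length, "+"))
                else:
                    # map back to top-strand coordinates of b
                    results.add((i0, len(b) - j1, length, "-"))
    return sorted(results)


def _window_eligible(mol: DnaMolecule, start: int, end: int,
                     params: HomologyParams) -> bool:
    """Is a shared block at [start, end) usable on this substrate under
    the family's terminal window?  Windows constrain linear donor
    fragments only; circular and genomic targets are unconstrained."""
    if params.terminal_window is None:
        return True
    if mol.is_circular or mol.topology == "genomic_fragment":
        return True
    n = len(mol.sequence)
    w = params.terminal_window
    near_left = end <= w
    near_right = n - start <= w
    if params.family == "in_vitro_annealing":
        # SLIC-style annealing cannot chew back non-matching tails
        near_left = near_left and start == 0
        near_right = near_right and end == n
    return near_left or near_right


def _homology_cut_events(mols: list[DnaMolecule], params: HomologyParams, ns: str
                         ) -> dict[str, list[CutEvent]]:
    min_len = max(params.min_homology_len, params.min_arm_len or 0)
    per_mol: dict[str, dict[tuple, CutEvent]] = {m.id: {} for m in mols}

    def add(mol: DnaMolecule, start: int, end: int, block: str):
        if not _window_eligible(mol, start, end, params):
            return
        n = len(mol.sequence)
        t, b = start, end
        if mol.is_circular:
            t, b = _normalize_circular_event(t, b, n)
        marker = f"{ns}:hom:{min(block, reverse_complement_seq(block))}"
        per_mol[mol.id].setdefault((t, b), CutEvent(
            t, b, "homology", start, end, up_marker=marker, down_marker=marker))

    for i, a in enumerate(mols):
        for j in range(i, len(mols)):
            b = mols[j]
            for a_start, b_start, length, orient in _maximal_common_blocks(
                    a.sequence, b.sequence, min_len):
                if i == j and orient == "+" and a_start == b_start:
                    continue   # trivial self-identity
                block = a.sequence[a_start:a_start + length]
                add(a, a_start, a_start + length, block)
                add(b, b_start, b_start + length, block)
    return {mid: [table[k] for k in sorted(table)] for mid, table in per_mol.items()}


def recombine(mols: list[DnaMolecule],
              family_or_sites: str | list[RecombinationSite],
              params: HomologyParams | None = None,
              mode: JoinMode | None = None) -> list[DnaMolecule]:
    """Simulate recombination over a pool of molecules.

    ``family_or_sites`` is either a homologous-recombination family name
    (``homologous``, ``lambda_red``, ``in_vitro_annealing``,
    ``in_vivo_annealing``) or a list of site-specific recombination
    sites.  Only molecules free of virtual pseudo-overhangs are
    returned; unresolved intermediates are disposed of.
    """
    if not mols:
        raise ValueError("at least one substrate required")
    mode = mode or JoinMode(rounds=max(3, len(mols) + 1))
    ns = f"r{next(_recombine_ns)}"

    if isinstance(family_or_sites, str):
        params = params or HomologyParams.for_family(family_or_sites)
        if params.family != family_or_sites:
            raise ValueError("params.family does not match the requested family")
        events_by_mol = _homology_cut_events(mols, params, ns)
        marker_compat = _hom_marker_compat
    else:
        sites = list(family_or_sites)
        events_by_mol = {m.id: _site_cut_events(m, sites, ns) for m in mols}
        marker_compat = _site_marker_compat({s.name.lower(): s for s in sites})

    if not any(events_by_mol.values()):
        log.info("recombine: no recombination site or shared homology found")
        return []

    _, source_copies = _copy_table(mols, mode.copies if mode else None)
    frags: list[DnaMolecule] = []
    frag_source: dict[str, str] = {}
    passthrough: list[DnaMolecule] = []
    limits: dict[str, int] = {}
    for mol in mols:
        events = events_by_mol.get(mol.id, [])
        if not events:
            passthrough.append(clone(mol))
            continue
        pieces, _ = apply_cuts(mol, events)
        for p in pieces:
            frags.append(p)
            frag_source[p.id] = mol.id
            limits[p.id] = source_copies.get(mol.id, 1)

    rounds = mode.rounds if mode.mode == "normal" else 2 * len(frags) + 2
    pool = _closure(frags, limits, rounds, virtual=True, marker_compat=marker_compat)

    resolved: list[tuple[str, _Asm]] = []
    for h, asm in sorted(pool.items()):
        m = asm.mol
        if not m.is_circular and (m.left_end.is_virtual or m.right_end.is_virtual):
            continue
        if not m.is_circular and asm.n_joins == 0:
            continue   # an uncut-looking fragment cannot occur; guard anyway
        resolved.append((h, asm))

    if mode.mode == "exhaustive":
        cut_sources = set(frag_source.values())
        kept = []
        for h, asm in resolved:
            srcs = {frag_source[fid] for fid in asm.usage if fid in frag_source}
            if srcs >= cut_sources:
                kept.append((h, asm))
        resolved = kept

    products = [_canonical_orientation(asm.mol) for _, asm in resolved]
    products.extend(passthrough)
    return products


# ---------------------------------------------------------------------------
# Gibson assembly designer
# ---------------------------------------------------------------------------

class GibsonDesignError(ValueError):
    pass


@dataclass
class GibsonSource:
    """One fragment entering a Gibson assembly, in assembly order.

    PCR-derived sources expose their primers; a primer that is not
    ``fixed`` may receive a 5' linker extension.  Synthesized or
    digested fragments are never altered — their neighbours' primers
    carry the full linker.
    """
    molecule: DnaMolecule
    is_pcr_product: bool = False
    forward_primer: str | None = None
    reverse_primer: str | None = None
    forward_fixed: bool = False
    reverse_fixed: bool = False


@dataclass
class GibsonDesign:
    sources: list[GibsonSource]          # with extended primers
    linkers: list[str]                   # overlap chosen per junction
    fragments: list[DnaMolecule]         # fragments after primer extension
    product: DnaMolecule                 # verified assembly


def _suffix_prefix_overlap(a: str, b: str, cap: int) -> int:
    best = 0
    for k in range(1, min(len(a), len(b), cap) + 1):
        if a[-k:] == b[:k]:
            best = k
    return best


def design_gibson(sources: list[GibsonSource], tm_threshold: float = 48.0,
                  min_overlap: int = 15, max_overlap: int = 60) -> GibsonDesign:
    """Design junction linkers for a circular Gibson assembly.

    For every junction the overlap is grown base by base from the
    upstream neighbour's terminal sequence until both its melting
    temperature and its length clear the thresholds; the overlap is
    prepended to the non-fixed primer of the PCR fragment at that
    junction.  The design is verified by running in-vivo-annealing
    recombination in exhaustive mode, which must produce a single circle
    containing every source exactly once.
    """
    from .pcr import melting_temperature, TmParams

    if len(sources) < 2:
        raise GibsonDesignError("at least two sources required")
    tm = TmParams(method="nearest_neighbor")

    def overlap_ok(seq: str) -> bool:
        return len(seq) >= min_overlap and melting_temperature(seq, tm) >= tm_threshold

    sources = [replace(s) for s in sources]
    ext_left = [""] * len(sources)    # linker prepended to fragment i's left
    ext_right = [""] * len(sources)   # linker appended to fragment i's right
    linkers: list[str] = []

    for i, up in enumerate(sources):
        j = (i + 1) % len(sources)
        down = sources[j]
        a, b = up.molecule.sequence, down.molecule.sequence
        nat = _suffix_prefix_overlap(a, b, max_overlap)
        if nat and overlap_ok(a[-nat:]):
            linkers.append(a[-nat:])
            continue
        down_open = down.is_pcr_product and not down.forward_fixed
        up_open = up.is_pcr_product and not up.reverse_fixed
        if not down_open and not up_open:
            raise GibsonDesignError(
                f"junction {i}->{j}: all primers fixed and no usable natural overlap")
        if down_open:
            # take the overlap from the upstream fragment's right terminus
            k = min_overlap
            while k <= max_overlap and not overlap_ok(a[-k:]):
                k += 1
            if k > max_overlap or k > len(a):
                raise GibsonDesignError(f"junction {i}->{j}: thresholds unsatisfiable")
            linker = a[-k:]
            down.forward_primer = linker + (down.forward_primer or "")
            ext_left[j] = linker
        else:
            # extend the upstream reverse primer with the downstream prefix
            k = min_overlap
            while k <= max_overlap and not overlap_ok(b[:k]):
                k += 1
            if k > max_overlap or k > len(b):
                raise GibsonDesignError(f"junction {i}->{j}: thresholds unsatisfiable")
            linker = b[:k]
            up.reverse_primer = reverse_complement_seq(linker) + (up.reverse_primer or "")
            ext_right[i] = linker
        linkers.append(linker)

    fragments = []
    for i, s in enumerate(sources):
        seq = ext_left[i] + s.molecule.sequence + ext_right[i]
        fragments.append(DnaMolecule.linear(seq, f"gibson_part_{i}_{s.molecule.id}",
                                            features=[f.shifted(len(ext_left[i]))
                                                      for f in s.molecule.features]))
    products = recombine(fragments, "in_vivo_annealing",
                         HomologyParams.for_family("in_vivo_annealing",
                                                   min_homology_len=max(8, min_overlap)),
                         JoinMode(mode="exhaustive"))
    circles = [p for p in products if p.is_circular]
    seen = {canonical_hash(c): c for c in circles}
    if len(seen) != 1:
        raise GibsonDesignError(
            f"verification failed: expected a single circular product, got {len(seen)}")
    product = next(iter(seen.values()))
    return GibsonDesign(sources, linkers, fragments, product)
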