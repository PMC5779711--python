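"""Everything that cleaves DNA.

Restriction digestion, CRISPR digestion (a guide RNA is compiled into a
temporary restriction enzyme), enzyme-condition analysis and digestion
buffer search over vendor alias systems.

The central primitive is :func:`apply_cuts`: a list of double-strand cut
events ``(top position, bottom position)`` in top-strand coordinates is
applied simultaneously to one molecule, yielding fragments whose typed
ends follow from the cut geometry (``cut_top < cut_bottom`` makes a 5'
overhang, ``>`` a 3' overhang, ``=`` a blunt cut).  Virtual digestion in
the recombination engine reuses the same primitive with marker-labelled
events.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .molecule import (
    BLUNT, FIVE_PRIME, THREE_PRIME,
    DnaEnd, DnaMolecule, Feature, clone, find_pattern, reverse_complement_seq,
    _check_dna,
)

__all__ = [
    "RestrictionEnzyme", "EnzymeAlias", "BufferSystem", "GuideRna",
    "CutEvent", "EnzymeRegistry", "default_registry",
    "apply_cuts", "digest", "crispr_digest", "enzyme_analysis", "find_buffer",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    canonical_name: str
    recognition: str
    cut_top: int      # offset of top-strand cut from recognition start
    cut_bottom: int   # offset of bottom-strand cut from recognition start
    notes: str = ""

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return FIVE_PRIME
        if self.cut_top > self.cut_bottom:
            return THREE_PRIME
        return BLUNT

    @property
    def is_outside_cutter(self) -> bool:
        return max(self.cut_top, self.cut_bottom) > len(self.recognition) or min(
            self.cut_top, self.cut_bottom) < 0


@dataclass(frozen=True)
class EnzymeAlias:
    alias_name: str
    canonical_name: str
    vendor: str


@dataclass
class BufferSystem:
    vendor: str
    # buffer name -> {alias name -> activity percentage}
    buffers: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class GuideRna:
    name: str
    spacer: str
    pam: str = "NGG"
    cut_offset: int = 3   # cut this many bp PAM-proximal of the protospacer 3' end

    def __post_init__(self):
        if len(self.spacer) < 16:
            raise ValueError("guide spacer must be at least 16 nt")
        if not self.pam:
            raise ValueError("PAM required")

    def as_enzyme(self) -> RestrictionEnzyme:
        """Temporary blunt cutter: protospacer+PAM with the cut inside
        the spacer, ``cut_offset`` bp 5' of the PAM."""
        pos = len(self.spacer) - self.cut_offset
        return RestrictionEnzyme(f"gRNA:{self.name}", self.spacer + self.pam, pos, pos,
                                 notes="temporary CRISPR cutter")


@dataclass(frozen=True)
class CutEvent:
    t: int                      # top-strand cut position
    b: int                      # bottom-strand cut position
    label: str = ""
    rec_start: int = -1
    rec_end: int = -1
    up_marker: str | None = None    # virtual marker for the upstream fragment's new end
    down_marker: str | None = None

    @property
    def start(self) -> int:
        return min(self.t, self.b)

    @property
    def stop(self) -> int:
        return max(self.t, self.b)


# ---------------------------------------------------------------------------
# registry & bundled tables
# ---------------------------------------------------------------------------

class EnzymeRegistry:
    """Restriction enzymes, vendor aliases, buffer systems and guides."""

    def __init__(self):
        self.enzymes: dict[str, RestrictionEnzyme] = {}
        self.aliases: dict[tuple[str, str], EnzymeAlias] = {}   # (vendor, alias) -> rec
        self.buffer_systems: dict[str, BufferSystem] = {}
        self.guides: dict[str, GuideRna] = {}

    # -- population --------------------------------------------------------
    def add_enzyme(self, enz: RestrictionEnzyme) -> None:
        self.enzymes[enz.canonical_name.lower()] = enz

    def add_alias(self, alias: EnzymeAlias) -> None:
        self.aliases[(alias.vendor.lower(), alias.alias_name.lower())] = alias

    def add_guide(self, g: GuideRna) -> None:
        self.guides[g.name.lower()] = g

    # -- lookup ------------------------------------------------------------
    def get(self, name: str) -> RestrictionEnzyme:
        """Resolve an enzyme by canonical name or any vendor alias."""
        key = name.lower()
        if key in self.enzymes:
            return self.enzymes[key]
        for (_, alias), rec in self.aliases.items():
            if alias == key:
                canonical = rec.canonical_name.lower()
                if canonical in self.enzymes:
                    return self.enzymes[canonical]
        raise KeyError(f"unknown enzyme {name!r}")

    def resolve_canonical(self, name: str) -> str:
        return self.get(name).canonical_name

    def vendor_aliases_for(self, canonical: str, vendor: str) -> list[str]:
        canonical = canonical.lower()
        vendor = vendor.lower()
        return sorted(rec.alias_name for (v, _), rec in self.aliases.items()
                      if v == vendor and rec.canonical_name.lower() == canonical)

    def all_enzymes(self) -> list[RestrictionEnzyme]:
        return [self.enzymes[k] for k in sorted(self.enzymes)]

    # -- table I/O ---------------------------------------------------------
    @staticmethod
    def _rows(text: str):
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield [c.strip() for c in line.split("\t")]

    def load_enzyme_table(self, text: str) -> None:
        for name, recognition, cut_top, cut_bottom, *rest in self._rows(text):
            self.add_enzyme(RestrictionEnzyme(name, _check_dna(recognition),
                                              int(cut_top), int(cut_bottom),
                                              rest[0] if rest else ""))

    def load_alias_table(self, text: str) -> None:
        for alias, canonical, vendor in self._rows(text):
            self.add_alias(EnzymeAlias(alias, canonical, vendor))

    def load_buffer_table(self, text: str) -> None:
        for vendor, buffer_name, alias, activity in self._rows(text):
            system = self.buffer_systems.setdefault(vendor, BufferSystem(vendor))
            act = float(activity)
            if not 0 <= act <= 100:
                raise ValueError(f"activity {act} out of [0, 100]")
            system.buffers.setdefault(buffer_name, {})[alias.lower()] = act

    def load_guide_table(self, text: str) -> None:
        for name, spacer, pam, cut_offset in self._rows(text):
            self.add_guide(GuideRna(name, _check_dna(spacer), pam, int(cut_offset)))


def default_registry() -> EnzymeRegistry:
    """Registry loaded from the bundled enzyme/alias/buffer/gRNA tables."""
    reg = EnzymeRegistry()
    pkg = importlib.resources.files("clonesim.data")
    reg.load_enzyme_table((pkg / "enzymes.tsv").read_text())
    reg.load_alias_table((pkg / "enzyme_aliases.tsv").read_text())
    reg.load_buffer_table((pkg / "buffers.tsv").read_text())
    reg.load_guide_table((pkg / "grnas.tsv").read_text())
    return reg


# ---------------------------------------------------------------------------
# cutting machinery
# ---------------------------------------------------------------------------

def enzyme_cut_events(mol: DnaMolecule, enz: RestrictionEnzyme) -> list[CutEvent]:
    """All double-strand cuts an enzyme makes on a molecule.

    Palindromic recognition sites found on both strands collapse to one
    event.  Cuts that would fall outside a linear molecule are dropped.
    """
    rec = enz.recognition
    rlen = len(rec)
    n = len(mol.sequence)
    events: dict[tuple[int, int], CutEvent] = {}
    for pos, strand in find_pattern(mol, rec, both_strands=True):
        if strand == "+":
            t, b = pos + enz.cut_top, pos + enz.cut_bottom
        else:
            t, b = pos + rlen - enz.cut_bottom, pos + rlen - enz.cut_top
        if mol.is_circular:
            start = min(t, b)
            shift = (start % n) - start
            t, b = t + shift, b + shift
        else:
            if min(t, b) < 0 or max(t, b) > n:
                continue
            if min(t, b) == 0 and max(t, b) == 0 or min(t, b) == n and max(t, b) == n:
                continue
        events.setdefault((t, b), CutEvent(t, b, enz.canonical_name, pos, pos + rlen))
    return [events[k] for k in sorted(events)]


def _resolve_conflicts(events: list[CutEvent], n: int, circular: bool,
                       warnings: list[str]) -> list[CutEvent]:
    """Sort events; warn on overlapping recognition sites of distinct
    cutters; drop cuts falling inside an already-consumed overhang."""
    events = sorted(events, key=lambda e: (e.start, e.stop, e.label))
    # recognition overlap warnings (between different cutters)
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            if a.label != b.label and a.rec_start >= 0 and b.rec_start >= 0:
                if a.rec_start < b.rec_end and b.rec_start < a.rec_end:
                    warnings.append(
                        f"recognition sites of {a.label} and {b.label} overlap "
                        f"at [{max(a.rec_start, b.rec_start)}, {min(a.rec_end, b.rec_end)})")
    accepted: list[CutEvent] = []
    for ev in events:
        clash = False
        for prev in accepted:
            if ev.start < prev.stop and prev.start < ev.stop:
                clash = True
                warnings.append(
                    f"cut of {ev.label} at {ev.start} dropped: overlaps the cut of "
                    f"{prev.label} at {prev.start}")
                break
        if not clash:
            accepted.append(ev)
    if circular and len(accepted) >= 2:
        # the wrap gap between the last and (first + n) event must also be clean
        first, last = accepted[0], accepted[-1]
        if first.start + n < last.stop:
            warnings.append(
                f"cut of {last.label} at {last.start} dropped: overlaps across origin")
            accepted.pop()
    return accepted


def _end_from_cut(seq: str, ev: CutEvent, side: str) -> DnaEnd:
    """Typed end created at a cut.  ``side`` is which fragment the end
    belongs to: 'up' = upstream fragment's right end, 'down' = downstream
    fragment's left end.  New 5' ends carry a phosphate."""
    d = ev.b - ev.t
    marker = ev.up_marker if side == "up" else ev.down_marker
    if d == 0:
        return DnaEnd(BLUNT, "", True, virtual_marker=marker)
    core = seq[ev.start:ev.stop]
    if d > 0:   # 5' overhang
        ov = reverse_complement_seq(core) if side == "up" else core
        return DnaEnd(FIVE_PRIME, ov, True, virtual_marker=marker)
    ov = core if side == "up" else reverse_complement_seq(core)
    return DnaEnd(THREE_PRIME, ov, True, virtual_marker=marker)


def _features_in_window(features: list[Feature], n: int, circular: bool,
                        lo: int, hi: int) -> list[Feature]:
    """Features intersecting [lo, hi) in (possibly rotated) coordinates,
    clipped and marked truncated where a cut split them."""
    out = []
    shifts = (-n, 0, n) if circular else (0,)
    for f in features:
        for sh in shifts:
            s, e = f.start + sh, f.end + sh
            cs, ce = max(s, lo), min(e, hi)
            if ce - cs <= 0:
                continue
            quals = dict(f.qualifiers)
            if cs != s or ce != e:
                quals["truncated"] = "true"
            out.append(Feature(f.name, f.kind, cs - lo, ce - lo, f.strand, quals))
    dedup = {}
    for f in out:
        dedup.setdefault(f.ident(), f)
    return sorted(dedup.values(), key=lambda f: (f.start, f.end, f.name))


def apply_cuts(mol: DnaMolecule, events: list[CutEvent]
               ) -> tuple[list[DnaMolecule], list[str]]:
    """Apply all cuts simultaneously; returns (fragments, warnings)."""
    warnings: list[str] = []
    n = len(mol.sequence)
    events = _resolve_conflicts(events, n, mol.is_circular, warnings)
    if not events:
        return [clone(mol)], warnings

    frag_topology = "genomic_fragment" if mol.topology == "genomic_fragment" else "linear"
    frags: list[DnaMolecule] = []

    if mol.is_circular:
        rot = events[0].start
        seq2 = mol.sequence[rot:] + mol.sequence + mol.sequence[:rot]  # length 2n, rotated
        # shift events into the rotated frame keeping the (t, b) offset pair
        shifted = []
        for ev in events:
            s = (ev.start - rot) % n
            shifted.append(CutEvent(s + (ev.t - ev.start), s + (ev.b - ev.start),
                                    ev.label, ev.rec_start, ev.rec_end,
                                    ev.up_marker, ev.down_marker))
        shifted.sort(key=lambda e: e.start)
        feats = [f.shifted(0) for f in mol.features]
        rot_feats = []
        for f in feats:
            s = (f.start - rot) % n
            rot_feats.append(Feature(f.name, f.kind, s, s + (f.end - f.start),
                                     f.strand, dict(f.qualifiers)))
        bounds = shifted + [CutEvent(shifted[0].t + n, shifted[0].b + n,
                                     shifted[0].label, -1, -1,
                                     shifted[0].up_marker, shifted[0].down_marker)]
        for i, (L, R) in enumerate(zip(bounds, bounds[1:])):
            lo, hi = L.start, R.stop
            span = seq2[lo:hi]
            frag = DnaMolecule(
                f"{mol.id}:f{i + 1}", span, frag_topology,
                _end_from_cut(seq2, L, "down"), _end_from_cut(seq2, R, "up"),
                _features_in_window(rot_feats, n, True, lo, hi),
                provenance=f"digest of {mol.id}")
            frags.append(frag)
        return frags, warnings

    # linear / genomic fragment
    lo_ov, ro_ov = mol.overhang_lengths()
    left_bound = CutEvent(0, lo_ov) if mol.left_end.overhang == FIVE_PRIME else \
        CutEvent(lo_ov, 0) if mol.left_end.overhang == THREE_PRIME else CutEvent(0, 0)
    right_bound = CutEvent(n, n - ro_ov) if mol.right_end.overhang == FIVE_PRIME else \
        CutEvent(n - ro_ov, n) if mol.right_end.overhang == THREE_PRIME else CutEvent(n, n)
    bounds = [left_bound] + events + [right_bound]
    for i, (L, R) in enumerate(zip(bounds, bounds[1:])):
        lo, hi = L.start, R.stop
        span = mol.sequence[lo:hi]
        if not span:
            continue
        left = mol.left_end if i == 0 else _end_from_cut(mol.sequence, L, "down")
        right = mol.right_end if i == len(bounds) - 2 else _end_from_cut(mol.sequence, R, "up")
        frags.append(DnaMolecule(
            f"{mol.id}:f{i + 1}", span, frag_topology, left, right,
            _features_in_window(mol.features, n, False, lo, hi),
            provenance=f"digest of {mol.id}"))
    return frags, warnings


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def digest(mols: list[DnaMolecule],
           enzymes: list[RestrictionEnzyme | str],
           registry: EnzymeRegistry | None = None
           ) -> tuple[list[DnaMolecule], list[str]]:
    """Simultaneous complete digestion of a pool of molecules.

    A circular substrate with k sites yields k linear fragments (itself
    when uncut); a linear one yields k+1.  Fragment ends carry the
    overhang implied by the cut geometry, with fresh 5' phosphates.
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    resolved: list[RestrictionEnzyme] = []
    for e in enzymes:
        if isinstance(e, str):
            reg = registry or default_registry()
            resolved.append(reg.get(e))
        else:
            resolved.append(e)
    all_frags: list[DnaMolecule] = []
    all_warnings: list[str] = []
    for mol in mols:
        events: list[CutEvent] = []
        for enz in resolved:
            events.extend(enzyme_cut_events(mol, enz))
        frags, warns = apply_cuts(mol, events)
        all_frags.extend(frags)
        all_warnings.extend(warns)
    return all_frags, all_warnings


def crispr_digest(mols: list[DnaMolecule], guides: list[GuideRna]
                  ) -> list[DnaMolecule]:
    """CRISPR digestion: each guide becomes a temporary restriction
    enzyme (protospacer+PAM recognition) fed to the digestion machinery.
    No PAM means no cut."""
    if not guides:
        raise ValueError("at least one guide required")
    frags, _ = digest(mols, [g.as_enzyme() for g in guides])
    return frags


@dataclass(frozen=True)
class AnalysisCondition:
    """Site-count condition over one substrate set: the count of an
    enzyme's sites (within ``region`` if given) must satisfy
    ``comparator count``."""
    molecules: tuple[DnaMolecule, ...]
    comparator: str          # gt | lt | eq
    count: int
    region: tuple[int, int] | None = None

    def __post_init__(self):
        if self.comparator not in ("gt", "lt", "eq"):
            raise ValueError("comparator must be gt, lt or eq")
        if self.count < 0:
            raise ValueError("count must be non-negative")


def _site_count(mol: DnaMolecule, enz: RestrictionEnzyme,
                region: tuple[int, int] | None) -> int:
    sites = {(ev.t, ev.b) for ev in enzyme_cut_events(mol, enz)}
    if region is None:
        return len(sites)
    lo, hi = region
    n = len(mol.sequence)
    loci = set()   # palindromes count once per locus
    for pos, strand in find_pattern(mol, enz.recognition, both_strands=True):
        s, e = pos, pos + len(enz.recognition)
        if lo <= s and e <= hi or (mol.is_circular and lo <= s + n and e + n <= hi):
            loci.add(pos)
    return len(loci)


def enzyme_analysis(conditions: list[AnalysisCondition],
                    registry: EnzymeRegistry | None = None
                    ) -> list[RestrictionEnzyme]:
    """Enzymes whose site counts satisfy every condition."""
    reg = registry or default_registry()
    if not reg.enzymes:
        raise ValueError("empty enzyme registry")
    if not conditions:
        raise ValueError("at least one condition required")
    out = []
    for enz in reg.all_enzymes():
        ok = True
        for cond in conditions:
            total = sum(_site_count(m, enz, cond.region) for m in cond.molecules)
            if cond.comparator == "eq" and total != cond.count:
                ok = False
            elif cond.comparator == "gt" and not total > cond.count:
                ok = False
            elif cond.comparator == "lt" and not total < cond.count:
                ok = False
            if not ok:
                break
        if ok:
            out.append(enz)
    return out


def find_buffer(enzyme_names: list[str], system: BufferSystem,
                registry: EnzymeRegistry | None = None,
                threshold: float = 75.0
                ) -> list[tuple[str, float, dict[str, float], bool]]:
    """Rank a vendor's buffers for a combination of enzymes.

    Each queried enzyme resolves to its canonical name; its activity in
    a buffer is taken from that vendor's alias entries mapped to the
    same canonical enzyme (best product when several, e.g. HF variants).
    Buffers are ranked by descending minimum activity, ties broken
    alphabetically; entries whose minimum falls below ``threshold`` are
    flagged.  Returns ``(buffer, min_activity, per-enzyme, ok)``.
    """
    reg = registry or default_registry()
    canonicals = [reg.resolve_canonical(name) for name in enzyme_names]
    per_enzyme_aliases = {}
    for canonical in canonicals:
        aliases = reg.vendor_aliases_for(canonical, system.vendor)
        if not aliases:
            raise KeyError(f"{canonical} has no alias in the {system.vendor} system")
        per_enzyme_aliases[canonical] = [a.lower() for a in aliases]
    ranked = []
    for buffer_name in sorted(system.buffers):
        table = system.buffers[buffer_name]
        per = {}
        for canonical in canonicals:
            acts = [table[a] for a in per_enzyme_aliases[canonical] if a in table]
            per[canonical] = max(acts) if acts else 0.0
        min_act = min(per.values()) if per else 0.0
        ranked.append((buffer_name, min_act, per, min_act >= threshold))
    ranked.sort(key=lambda r: (-r[1], r[0]))
    return ranked
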