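"""Double-stranded DNA molecules with typed ends.

The universal substrate/product object of the simulator.  A molecule is
stored as its top strand, 5'->3', in a *span* coordinate frame: the
sequence covers the union of both strands' extents, so a terminal
overhang region is part of ``sequence`` even though only one strand is
physically present there.  For regions where only the bottom strand
exists (3' overhangs on the left, 5' overhangs on the right) the stored
bases are the complement of the bottom strand, i.e. what the missing top
strand would read.  This makes cut-and-join arithmetic uniform: two ends
are ligatable exactly when the suffix of one span equals the prefix of
the other over the overhang length.

Molecules can be circular, linear or a genomic fragment (a linear piece
of a chromosome whose ends are not ligatable substrates in vitro but
which can serve as a recombination target in vivo).
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "IUPAC_SETS",
    "DnaEnd",
    "Feature",
    "FeatureLibrary",
    "DnaMolecule",
    "reverse_complement_seq",
    "reverse_complement",
    "find_pattern",
    "canonical_hash",
    "annotate_features",
    "format_end_code",
    "parse_end_code",
    "BLUNT",
    "FIVE_PRIME",
    "THREE_PRIME",
]

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BLUNT = "blunt"
FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


def reverse_complement_seq(seq: str) -> str:
    """Reverse complement of a plain IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in {what}")
    return seq


@dataclass(frozen=True)
class DnaEnd:
    """One terminus of a linear molecule.

    ``overhang_seq`` is given 5'->3' on the protruding strand; empty iff
    blunt.  ``virtual_marker`` is set only on recombination intermediates
    produced by virtual digestion; such ends never appear on a final
    product.
    """

    overhang: str = BLUNT
    overhang_seq: str = ""
    phosphorylated: bool = False
    hairpin: bool = False
    virtual_marker: str | None = None

    def __post_init__(self):
        if self.overhang not in (BLUNT, FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"bad overhang kind {self.overhang!r}")
        if self.overhang == BLUNT and self.overhang_seq:
            raise ValueError("blunt end cannot carry an overhang sequence")
        if self.overhang != BLUNT and not self.overhang_seq:
            raise ValueError("overhang end needs a non-empty overhang sequence")
        object.__setattr__(self, "overhang_seq", _check_dna(self.overhang_seq, "overhang")
                           if self.overhang_seq else "")

    @property
    def is_virtual(self) -> bool:
        return self.virtual_marker is not None

    def key(self) -> tuple:
        """Canonical tuple used by hashing; folds in every field."""
        return (self.overhang, self.overhang_seq, self.phosphorylated,
                self.hairpin, self.virtual_marker)


#: a ready-made plain blunt, unphosphorylated end
BLUNT_END = DnaEnd()


@dataclass
class Feature:
    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"   # "+" or "-"
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError("feature end must exceed start (unwrapped coordinates)")

    def ident(self) -> tuple:
        return (self.name, self.start, self.end, self.strand)

    def shifted(self, delta: int) -> "Feature":
        return Feature(self.name, self.kind, self.start + delta, self.end + delta,
                       self.strand, dict(self.qualifiers))


class FeatureLibrary:
    """Named sequence patterns for automatic annotation.

    Names are unique, looked up case-insensitively.
    """

    def __init__(self):
        self._entries: dict[str, tuple[str, str, dict]] = {}
        self._names: dict[str, str] = {}

    def add(self, name: str, sequence: str, kind: str = "misc_feature",
            qualifiers: dict | None = None) -> None:
        key = name.lower()
        if key in self._entries and self._entries[key][0] != _check_dna(sequence):
            raise ValueError(f"feature name {name!r} already defined with a different sequence")
        self._entries[key] = (_check_dna(sequence), kind, dict(qualifiers or {}))
        self._names[key] = name

    def get(self, name: str) -> tuple[str, str, dict] | None:
        return self._entries.get(name.lower())

    def items(self):
        for key, (seq, kind, quals) in sorted(self._entries.items()):
            yield self._names[key], seq, kind, quals

    def __len__(self):
        return len(self._entries)

    def __contains__(self, name: str):
        return name.lower() in self._entries

    def merge(self, other: "FeatureLibrary") -> None:
        for name, seq, kind, quals in other.items():
            if name not in self:
                self.add(name, seq, kind, quals)


_mol_counter = itertools.count(1)


@dataclass
class DnaMolecule:
    id: str
    sequence: str
    topology: str  # circular | linear | genomic_fragment
    left_end: DnaEnd | None = None
    right_end: DnaEnd | None = None
    features: list[Feature] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        self.sequence = _check_dna(self.sequence)
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.topology not in ("circular", "linear", "genomic_fragment"):
            raise ValueError(f"bad topology {self.topology!r}")
        if self.topology == "circular":
            if self.left_end is not None or self.right_end is not None:
                raise ValueError("circular molecules have no ends")
        else:
            if self.left_end is None:
                self.left_end = BLUNT_END
            if self.right_end is None:
                self.right_end = BLUNT_END

    # -- constructors ------------------------------------------------------
    @classmethod
    def linear(cls, sequence: str, id: str | None = None, *,
               left_end: DnaEnd = BLUNT_END, right_end: DnaEnd = BLUNT_END,
               features: list[Feature] | None = None, provenance: str = "") -> "DnaMolecule":
        return cls(id or f"mol{next(_mol_counter)}", sequence, "linear",
                   left_end, right_end, list(features or []), provenance)

    @classmethod
    def circular(cls, sequence: str, id: str | None = None, *,
                 features: list[Feature] | None = None, provenance: str = "") -> "DnaMolecule":
        return cls(id or f"mol{next(_mol_counter)}", sequence, "circular",
                   None, None, list(features or []), provenance)

    # -- basic geometry ----------------------------------------------------
    def __len__(self):
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def overhang_lengths(self) -> tuple[int, int]:
        if self.is_circular:
            return (0, 0)
        return (len(self.left_end.overhang_seq), len(self.right_end.overhang_seq))

    def nucleotide_count(self) -> int:
        """Total nucleotides over both strands (mass bookkeeping)."""
        if self.is_circular:
            return 2 * len(self.sequence)
        lo, ro = self.overhang_lengths()
        return 2 * len(self.sequence) - lo - ro

    def circular_slice(self, start: int, end: int) -> str:
        """Substring in circular coordinates; ``end`` may exceed length."""
        n = len(self.sequence)
        if not self.is_circular:
            return self.sequence[start:end]
        length = end - start
        if length > n:
            raise ValueError("slice longer than molecule")
        doubled = self.sequence + self.sequence
        start %= n
        return doubled[start:start + length]

    def with_id(self, new_id: str) -> "DnaMolecule":
        m = clone(self)
        m.id = new_id
        return m


def clone(mol: DnaMolecule) -> DnaMolecule:
    return DnaMolecule(mol.id, mol.sequence, mol.topology, mol.left_end, mol.right_end,
                       [replace(f, qualifiers=dict(f.qualifiers)) for f in mol.features],
                       mol.provenance)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reverse_complement(mol: DnaMolecule) -> DnaMolecule:
    """Flip a molecule to its other strand.

    Ends swap sides but keep their chemistry (a 5' overhang stays a 5'
    overhang and its protruding-strand sequence is unchanged).  Feature
    coordinates are mirrored and strands inverted.  Involution up to id.
    """
    n = len(mol.sequence)
    feats = []
    for f in mol.features:
        s, e = f.start, f.end
        ns, ne = n - e, n - s
        if mol.is_circular:
            # re-normalise wrapped intervals into [0, n) start
            ns %= n
            ne = ns + (e - s)
        feats.append(Feature(f.name, f.kind, ns, ne,
                             "-" if f.strand == "+" else "+", dict(f.qualifiers)))
    return DnaMolecule(mol.id, reverse_complement_seq(mol.sequence), mol.topology,
                       mol.right_end, mol.left_end, feats, mol.provenance)


def _iupac_window_match(window: str, pattern: str) -> bool:
    # a sequence symbol matches a pattern symbol when its base set is a
    # subset of the pattern's set (so N in the sequence only matches N)
    return all(IUPAC_SETS[w] <= IUPAC_SETS[p] for w, p in zip(window, pattern))


def find_pattern(mol: DnaMolecule, pattern: str, both_strands: bool = True
                 ) -> list[tuple[int, str]]:
    """All occurrences of an IUPAC pattern; ``(top-strand start, strand)``.

    Circular molecules are scanned across the origin.  Overlapping
    matches are all reported; a palindromic pattern yields one hit per
    strand at the same locus.
    """
    pattern = _check_dna(pattern, "pattern")
    if not pattern:
        raise ValueError("empty pattern")
    plen = len(pattern)
    seq = mol.sequence
    n = len(seq)
    scan = seq + seq[:plen - 1] if mol.is_circular else seq
    hits = []
    patterns = [(pattern, "+")]
    if both_strands:
        patterns.append((reverse_complement_seq(pattern), "-"))
    for pat, strand in patterns:
        for i in range(len(scan) - plen + 1):
            if i >= n:
                break
            if _iupac_window_match(scan[i:i + plen], pat):
                hits.append((i, strand))
    hits.sort()
    return hits


def _min_rotation(seq: str) -> str:
    return min(seq[i:] + seq[:i] for i in range(len(seq)))


def canonical_hash(mol: DnaMolecule) -> str:
    """Identity digest: rotation-invariant for circles, strand-flip
    invariant for all molecules, and sensitive to topology and end state.
    """
    if mol.is_circular:
        rep = min(_min_rotation(mol.sequence), _min_rotation(reverse_complement_seq(mol.sequence)))
        payload = ("circular", rep)
    else:
        fwd = (mol.sequence, mol.left_end.key(), mol.right_end.key())
        flp = reverse_complement(mol)
        rev = (flp.sequence, flp.left_end.key(), flp.right_end.key())
        payload = (mol.topology,) + min(fwd, rev)
    return hashlib.sha256(repr(payload).encode()).hexdigest()


def annotate_features(mol: DnaMolecule, lib: FeatureLibrary) -> DnaMolecule:
    """Add a feature for every library entry occurring in the molecule.

    Both strands are searched; on circular molecules matches may wrap.
    Existing features are kept; exact duplicates are suppressed.
    """
    out = clone(mol)
    seen = {f.ident() for f in out.features}
    for name, pat, kind, quals in lib.items():
        for pos, strand in find_pattern(mol, pat, both_strands=True):
            feat = Feature(name, kind, pos, pos + len(pat), strand, dict(quals))
            if feat.ident() not in seen:
                seen.add(feat.ident())
                out.features.append(feat)
    out.features.sort(key=lambda f: (f.start, f.end, f.name))
    return out


# ---------------------------------------------------------------------------
# end codes
# ---------------------------------------------------------------------------

_END_CODE_RE = re.compile(r"^(P-)?(blunt|5ov:([ACGTRYSWKMBDHVN]+)|3ov:([ACGTRYSWKMBDHVN]+))$|^hairpin$")


def format_end_code(end: DnaEnd) -> str:
    """Serialize an end to the token grammar
    ``[P-](blunt | 5ov:<SEQ> | 3ov:<SEQ>) | hairpin``."""
    if end.is_virtual:
        raise ValueError("virtual ends are intermediates and have no end code")
    if end.hairpin:
        return "hairpin"
    p = "P-" if end.phosphorylated else ""
    if end.overhang == BLUNT:
        return p + "blunt"
    tag = "5ov" if end.overhang == FIVE_PRIME else "3ov"
    return f"{p}{tag}:{end.overhang_seq}"


def parse_end_code(code: str) -> DnaEnd:
    m = _END_CODE_RE.match(code.strip())
    if not m:
        raise ValueError(f"malformed end code {code!r}")
    if code.strip() == "hairpin":
        return DnaEnd(hairpin=True)
    phos = m.group(1) is not None
    body = m.group(2)
    if body == "blunt":
        return DnaEnd(BLUNT, "", phos)
    if body.startswith("5ov:"):
        return DnaEnd(FIVE_PRIME, m.group(3), phos)
    return DnaEnd(THREE_PRIME, m.group(4), phos)
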