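"""PCR simulation and oligonucleotide analysis.

PCR is simulated mechanistically rather than by copying the region
between two binding sites: stage 1 enumerates every single-strand
extension product any primer can make on any template strand (iterated,
so products prime on products — this is what yields overlap-extension
products and by-products), and stage 2 anneals pairs of single strands
whose 3' regions are mutually complementary and fills them in to duplex
products.  Products flanked by primers on both strands are exponential
products; everything else is reported as a by-product.

Melting temperatures use either the Wallace rule 2(A+T)+4(G+C) or
unified nearest-neighbor thermodynamics (SantaLucia 1998 parameters via
Biopython, total strand concentration C_T/4, salt correction
0.368*(N-1)*ln[Na+] on the entropy).  Secondary-structure screening
(hairpins, self- and cross-dimers) uses the matching unified dG(37)
increments with an exhaustive small-structure search.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .molecule import (
    DnaMolecule, DnaEnd, BLUNT, canonical_hash, reverse_complement_seq, _check_dna,
)

__all__ = [
    "Primer", "DuplexReport", "TmParams",
    "melting_temperature", "tm_profile",
    "simulate_pcr", "simulate_sequencing",
    "analyze_oligos", "design_primers", "design_primer_at",
    "expand_designer_text", "merge_sequences",
    "reverse_translate", "codon_usage",
]


@dataclass
class Primer:
    name: str
    sequence: str
    fixed: bool = False
    phosphorylated: bool = False
    ordered: bool = False

    def __post_init__(self):
        self.sequence = _check_dna(self.sequence, "primer")
        if len(self.sequence) < 6:
            raise ValueError("primer must be at least 6 nt")


@dataclass
class DuplexReport:
    kind: str                    # hairpin | self_dimer | cross_dimer
    delta_g: float               # kcal/mol, <= 0
    involved_positions: list[int] = field(default_factory=list)


@dataclass
class TmParams:
    method: str = "nearest_neighbor"   # wallace | nearest_neighbor
    oligo_conc: float = 0.5e-6         # molar total strand concentration
    salt_conc: float = 0.05            # molar monovalent cation

    def __post_init__(self):
        if self.method not in ("wallace", "nearest_neighbor"):
            raise ValueError("method must be 'wallace' or 'nearest_neighbor'")
        if self.oligo_conc <= 0 or self.salt_conc <= 0:
            raise ValueError("concentrations must be positive")


def melting_temperature(seq: str, params: TmParams | None = None) -> float:
    """Tm in deg C.  Wallace: 2(A+T)+4(G+C).  Nearest-neighbor: unified
    duplex parameters with C_T/4 and SantaLucia-1998 salt correction."""
    params = params or TmParams()
    seq = _check_dna(seq)
    if set(seq) - set("ACGT"):
        raise ValueError("Tm needs a concrete ACGT sequence")
    if params.method == "wallace":
        at = seq.count("A") + seq.count("T")
        return float(2 * at + 4 * (len(seq) - at))
    if not 6 <= len(seq) <= 60:
        raise ValueError("nearest-neighbor Tm supported for 6-60 nt oligos")
    half_nM = params.oligo_conc * 1e9 / 2.0
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, dnac1=half_nM, dnac2=half_nM,
                           Na=params.salt_conc * 1000.0, K=0, Tris=0, Mg=0, dNTPs=0,
                           saltcorr=5))


def tm_profile(mol: DnaMolecule, window_len: int,
               params: TmParams | None = None) -> list[float]:
    """Tm of every window of ``window_len``; circular molecules wrap and
    yield exactly ``len(mol)`` windows."""
    if window_len < 6:
        raise ValueError("window must be at least 6 nt")
    n = len(mol.sequence)
    if window_len > n:
        raise ValueError("window longer than molecule")
    scan = mol.sequence + mol.sequence[:window_len - 1] if mol.is_circular else mol.sequence
    count = n if mol.is_circular else n - window_len + 1
    return [melting_temperature(scan[i:i + window_len], params) for i in range(count)]


# ---------------------------------------------------------------------------
# unified dG(37) increments for structure screening
# ---------------------------------------------------------------------------

_DG37 = {
    "AA": -1.00, "TT": -1.00, "AT": -0.88, "TA": -0.58,
    "CA": -1.45, "TG": -1.45, "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28, "GA": -1.30, "TC": -1.30,
    "CG": -2.17, "GC": -2.24, "GG": -1.84, "CC": -1.84,
}
_DG_INIT = {"G": 0.98, "C": 0.98, "A": 1.03, "T": 1.03}
_DG_HAIRPIN_LOOP = 3.5   # flat loop-closure penalty, kcal/mol


def _duplex_dg(seq: str) -> float:
    """dG(37) of a perfect duplex of ``seq`` with its complement."""
    dg = _DG_INIT[seq[0]] + _DG_INIT[seq[-1]]
    for i in range(len(seq) - 1):
        dg += _DG37[seq[i:i + 2]]
    return dg


def _stem_runs(a: str, b: str, min_len: int):
    """(i, j, L): a[i:i+L] pairs antiparallel with b[j:j+L], i.e.
    a[i:i+L] == revcomp(b[j:j+L]); maximal runs per alignment."""
    rb = reverse_complement_seq(b)
    for d in range(-(len(rb) - 1), len(a)):
        run = 0
        for p in range(max(0, d), min(len(a), len(rb) + d) + 1):
            q = p - d
            if p < len(a) and 0 <= q < len(rb) and a[p] == rb[q]:
                run += 1
            else:
                if run >= min_len:
                    i = p - run
                    yield i, len(b) - (i - d) - run, run
                run = 0


def _best_dimer(a: str, b: str, kind: str, min_stem: int = 3) -> DuplexReport | None:
    best = None
    for i, j, L in _stem_runs(a, b, min_stem):
        dg = _duplex_dg(a[i:i + L])
        if best is None or dg < best.delta_g:
            best = DuplexReport(kind, dg, list(range(i, i + L)))
    return best


def _best_hairpin(seq: str, min_stem: int = 3, min_loop: int = 3) -> DuplexReport | None:
    n = len(seq)
    best = None
    for L in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * L - min_loop + 1):
            for j in range(i + L + min_loop, n - L + 1):
                if seq[i:i + L] == reverse_complement_seq(seq[j:j + L]):
                    dg = _duplex_dg(seq[i:i + L]) + _DG_HAIRPIN_LOOP
                    if dg < 0 and (best is None or dg < best.delta_g):
                        best = DuplexReport("hairpin", dg,
                                            list(range(i, i + L)) + list(range(j, j + L)))
    return best


def analyze_oligos(p1: Primer | str, p2: Primer | str | None = None,
                   dg_cutoff: float = -1.0) -> list[DuplexReport]:
    """Minimum-dG hairpin, self-dimer and (optionally) cross-dimer for a
    primer or primer pair; structures weaker than ``dg_cutoff`` omitted."""
    s1 = p1.sequence if isinstance(p1, Primer) else _check_dna(p1)
    reports = []
    hp = _best_hairpin(s1)
    if hp:
        reports.append(hp)
    sd = _best_dimer(s1, s1, "self_dimer")
    if sd:
        reports.append(sd)
    if p2 is not None:
        s2 = p2.sequence if isinstance(p2, Primer) else _check_dna(p2)
        hp2 = _best_hairpin(s2)
        if hp2:
            reports.append(hp2)
        cd = _best_dimer(s1, s2, "cross_dimer")
        if cd:
            reports.append(cd)
    return [r for r in reports if r.delta_g <= dg_cutoff]


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------

def _sense_strands(mol: DnaMolecule) -> list[tuple[str, bool]]:
    """(sequence read along the future product, is_circular)."""
    return [(mol.sequence, mol.is_circular),
            (reverse_complement_seq(mol.sequence), mol.is_circular)]


def _extension_products(sense: str, circular: bool, primers: list[Primer],
                        min_anneal: int) -> set[str]:
    """Single strands a primer makes with this sense strand: the primer's
    3'-terminal ``min_anneal`` bases must occur exactly; the 5' tail is
    retained verbatim and extension runs to the template end (one full
    turn on circles)."""
    out = set()
    n = len(sense)
    scan = sense + sense[:min_anneal - 1] if circular else sense
    for p in primers:
        if len(p.sequence) < min_anneal:
            continue
        probe = p.sequence[-min_anneal:]
        if set(probe) - set("ACGT"):
            continue
        for i in range(len(scan) - min_anneal + 1):
            if i >= n:
                break
            if scan[i:i + min_anneal] == probe:
                if circular:
                    doubled = sense + sense
                    ext = doubled[i + min_anneal:i + n]
                else:
                    ext = sense[i + min_anneal:]
                out.add(p.sequence + ext)
    return out


def _anneal(s1: str, s2: str, min_anneal: int) -> list[str]:
    """Duplex top strands from 3'-overlap annealing + fill-in of two
    single strands."""
    rc2 = reverse_complement_seq(s2)
    tops = []
    for k in range(min_anneal, min(len(s1), len(s2)) + 1):
        if s1[-k:] == rc2[:k]:
            tops.append(s1 + rc2[k:])
    return tops


def simulate_pcr(templates: list[DnaMolecule], primers: list[Primer],
                 min_anneal_3p: int = 15, max_rounds: int = 10
                 ) -> tuple[list[DnaMolecule], list[DnaMolecule]]:
    """Mechanistic PCR: returns (products, byproducts).

    Products are duplexes flanked by a primer on each strand
    (exponential amplicons); all other annealed duplexes are
    by-products.  Ends are blunt and phosphorylated only when the
    corresponding primer is.
    """
    if not primers:
        raise ValueError("at least one primer required")
    strands: set[str] = set()
    # round 0: prime on the input templates
    pool_templates: set[tuple[str, bool]] = set()
    for mol in templates:
        pool_templates.update(_sense_strands(mol))
    for _ in range(max_rounds):
        new: set[str] = set()
        for sense, circ in pool_templates:
            new |= _extension_products(sense, circ, primers, min_anneal_3p)
        new -= strands
        if not new:
            break
        strands |= new
        # products serve as templates in later cycles
        pool_templates = {(reverse_complement_seq(s), False) for s in new}

    primer_seqs = [p.sequence for p in primers]
    phos = {p.sequence: p.phosphorylated for p in primers}

    def leading_primer(s: str) -> str | None:
        for ps in primer_seqs:
            if s.startswith(ps):
                return ps
        return None

    def primer_rank(s: str) -> int:
        p = leading_primer(s)
        return primer_seqs.index(p) if p else len(primer_seqs)

    products, byproducts = {}, {}
    slist = sorted(strands)
    for a in slist:
        for b in slist:
            for top in _anneal(a, b, min_anneal_3p):
                bottom = reverse_complement_seq(top)
                # present the strand led by the earliest-listed primer on top
                if (primer_rank(bottom), bottom) < (primer_rank(top), top):
                    top, bottom = bottom, top
                p_top, p_bot = leading_primer(top), leading_primer(bottom)
                left = DnaEnd(BLUNT, "", bool(p_top and phos[p_top]))
                right = DnaEnd(BLUNT, "", bool(p_bot and phos[p_bot]))
                mol = DnaMolecule.linear(top, f"pcr_{len(products) + len(byproducts)}",
                                         left_end=left, right_end=right,
                                         provenance="PCR product")
                h = canonical_hash(mol)
                if p_top and p_bot:
                    products.setdefault(h, mol)
                else:
                    byproducts.setdefault(h, mol)
    byproducts = {h: m for h, m in byproducts.items() if h not in products}
    return ([products[h] for h in sorted(products)],
            [byproducts[h] for h in sorted(byproducts)])


def simulate_sequencing(mol: DnaMolecule, primer: Primer, read_length: int,
                        min_anneal: int = 15) -> str:
    """Theoretical single-primer sequencing read: the template-directed
    extension downstream of the primer's 3' end.  The primer must anneal
    exactly once."""
    sites = []
    probe = primer.sequence[-min_anneal:]
    for sense, circ in _sense_strands(mol):
        n = len(sense)
        scan = sense + sense[:min_anneal - 1] if circ else sense
        for i in range(len(scan) - min_anneal + 1):
            if i >= n:
                break
            if scan[i:i + min_anneal] == probe:
                sites.append((sense, circ, i))
    if len(sites) != 1:
        raise ValueError(f"primer anneals at {len(sites)} sites; need exactly 1")
    sense, circ, i = sites[0]
    n = len(sense)
    if circ:
        doubled = sense + sense
        return doubled[i + min_anneal:i + min_anneal + min(read_length, n)]
    return sense[i + min_anneal:i + min_anneal + read_length]


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------

_MAX_PRIMER_LEN = 60


def design_primer_at(mol: DnaMolecule, position: int, strand: str,
                     tm_min: float, params: TmParams | None = None) -> Primer:
    """One-click design: a primer whose 5' end sits at ``position`` and
    which is extended 3'-ward base by base until its Tm reaches
    ``tm_min`` (minimal length)."""
    params = params or TmParams()
    n = len(mol.sequence)
    for length in range(6, _MAX_PRIMER_LEN + 1):
        if strand == "+":
            if not mol.is_circular and position + length > n:
                break
            seq = mol.circular_slice(position, position + length) if mol.is_circular \
                else mol.sequence[position:position + length]
        else:
            if not mol.is_circular and position + 1 - length < 0:
                break
            start = position + 1 - length
            raw = mol.circular_slice(start % n, start % n + length) if mol.is_circular \
                else mol.sequence[start:position + 1]
            seq = reverse_complement_seq(raw)
        if len(seq) < length:
            break
        if melting_temperature(seq, params) >= tm_min:
            return Primer(f"{mol.id}_{strand}{position}", seq)
    raise ValueError("cannot reach the requested Tm within the primer length cap")


def design_primers(mol: DnaMolecule, region: tuple[int, int], tm_min: float,
                   params: TmParams | None = None, n_offsets: int = 3
                   ) -> list[tuple[Primer, Primer]]:
    """Candidate primer pairs amplifying ``region``, each primer the
    shortest extension reaching ``tm_min``, ranked by weakest secondary
    structure (least-negative worst-case dG first)."""
    if not 30 <= tm_min <= 80:
        raise ValueError("tm_min out of the sane 30-80 range")
    lo, hi = region
    pairs = []
    for off_f in range(n_offsets):
        for off_r in range(n_offsets):
            fpos, rpos = lo - off_f, hi - 1 + off_r
            if not mol.is_circular and (fpos < 0 or rpos >= len(mol.sequence)):
                continue
            try:
                fwd = design_primer_at(mol, fpos % len(mol.sequence) if mol.is_circular else fpos,
                                       "+", tm_min, params)
                rev = design_primer_at(mol, rpos % len(mol.sequence) if mol.is_circular else rpos,
                                       "-", tm_min, params)
            except ValueError:
                continue
            reports = analyze_oligos(fwd, rev, dg_cutoff=0.0)
            worst = min((r.delta_g for r in reports), default=0.0)
            pairs.append((-worst, len(fwd.sequence) + len(rev.sequence),
                          fwd.sequence, rev.sequence, fwd, rev))
    if not pairs:
        raise ValueError("no primer pair reaches the requested Tm around the region")
    pairs.sort(key=lambda t: t[:4])
    return [(fwd, rev) for *_, fwd, rev in pairs]


# ---------------------------------------------------------------------------
# designer-text expansion
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\[([^\[\]:<>]+)\]|\[([^\[\]:<>]+):([ACGT]*)>|<([^\[\]:<>]+):([ACGT]*)\]")


def expand_designer_text(text: str, enzymes=None, sites=None, features=None) -> str:
    """Expand ``[name]``, ``[name:pattern>`` and ``<name:pattern]``
    tokens to sequences: forward, forward with N positions filled from
    the pattern, and the reverse complement thereof.  Names resolve
    against the enzyme registry, the recombination-site registry and the
    feature library, in that order."""

    def lookup(name: str) -> str:
        if enzymes is not None:
            try:
                return enzymes.get(name).recognition
            except KeyError:
                pass
        if sites is not None:
            try:
                return sites.get(name).sequence
            except KeyError:
                pass
        if features is not None and name in features:
            return features.get(name)[0]
        raise KeyError(f"unknown name {name!r} in designer text")

    def fill(seq: str, pattern: str) -> str:
        n_count = seq.count("N")
        if n_count != len(pattern):
            raise ValueError(
                f"pattern length {len(pattern)} does not match {n_count} N position(s)")
        it = iter(pattern)
        return "".join(next(it) if c == "N" else c for c in seq)

    def repl(m: re.Match) -> str:
        if m.group(1) is not None:
            return lookup(m.group(1))
        if m.group(2) is not None:
            return fill(lookup(m.group(2)), m.group(3))
        return reverse_complement_seq(fill(lookup(m.group(4)), m.group(5)))

    out = _TOKEN_RE.sub(repl, text)
    return _check_dna("".join(out.split()))


# ---------------------------------------------------------------------------
# sequence merging & reverse translation
# ---------------------------------------------------------------------------

def merge_sequences(seqs: list[str], min_overlap: int = 15) -> list[str]:
    """Every merge of two sequences via an exact suffix-prefix overlap of
    at least ``min_overlap`` (either orientation); all distinct outcomes."""
    if len(seqs) < 2:
        raise ValueError("at least two sequences required")
    seqs = [_check_dna(s) for s in seqs]
    out = set()
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i == j:
                continue
            for bb in (b, reverse_complement_seq(b)):
                for k in range(min_overlap, min(len(a), len(bb)) + 1):
                    if a[-k:] == bb[:k]:
                        out.add(a + bb[k:])
    # a flipped merge is the same molecule; keep the lexicographic representative
    canon = {min(s, reverse_complement_seq(s)) for s in out}
    return sorted(canon)


_STANDARD_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def codon_usage(cds_set: list[str]) -> dict[str, dict[str, float]]:
    """Per-amino-acid relative codon frequencies from a set of CDS.

    A stop codon is only legal as the final codon of a CDS; frequencies
    per amino acid sum to 1.
    """
    counts: dict[str, dict[str, int]] = {}
    for cds in cds_set:
        cds = _check_dna(cds, "CDS")
        if len(cds) % 3:
            raise ValueError("CDS length must be divisible by 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        for k, codon in enumerate(codons):
            aa = _STANDARD_CODONS.get(codon)
            if aa is None:
                raise ValueError(f"untranslatable codon {codon!r}")
            if aa == "*":
                if k != len(codons) - 1:
                    raise ValueError(f"internal stop codon at codon {k}")
                continue
            counts.setdefault(aa, {}).setdefault(codon, 0)
            counts[aa][codon] += 1
    usage = {}
    for aa, table in counts.items():
        total = sum(table.values())
        usage[aa] = {codon: c / total for codon, c in sorted(table.items())}
    return usage


def reverse_translate(protein: str, table: dict[str, dict[str, float]],
                      algorithm: str = "one_codon", seed: int = 0) -> str:
    """Back-translate a protein: ``one_codon`` always takes the most
    frequent codon per residue; ``guided_random`` samples codons in
    proportion to usage (reproducible for a fixed seed)."""
    protein = protein.upper()
    rng = random.Random(seed)
    out = []
    for aa in protein:
        if aa not in table or not table[aa]:
            raise KeyError(f"residue {aa!r} absent from the usage table")
        codons = sorted(table[aa].items())
        if algorithm == "one_codon":
            out.append(max(codons, key=lambda kv: (kv[1], kv[0]))[0])
        elif algorithm == "guided_random":
            seqs, weights = zip(*codons)
            out.append(rng.choices(seqs, weights=weights, k=1)[0])
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
    dna = "".join(out)
    assert "".join(_STANDARD_CODONS[dna[i:i + 3]] for i in range(0, len(dna), 3)) == protein
    return dna
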