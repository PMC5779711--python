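"""Readers and writers for standard sequence formats.

GenBank flatfiles carry sequence, circular/linear topology and features
(1-based inclusive locations, ``complement(...)`` for the minus strand,
origin-wrapping ``join(...)`` locations on circles); FASTA and plain
text yield linear, blunt, unphosphorylated molecules.  Internally all
coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .molecule import DnaMolecule, Feature

__all__ = ["read_genbank", "write_genbank", "read_fasta", "read_plain"]


def _to_feature(sf: SeqFeature, n: int) -> Feature:
    strand = "-" if sf.location.strand == -1 else "+"
    parts = sorted(sf.location.parts, key=lambda p: int(p.start))
    if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
        # origin-wrapping join: [a, n) + [0, b)
        start = int(parts[1].start)
        end = n + int(parts[0].end)
    else:
        start = int(sf.location.start)
        end = int(sf.location.end)
    quals = {k: (v[0] if isinstance(v, list) and v else str(v))
             for k, v in sf.qualifiers.items()}
    name = quals.pop("label", None) or quals.pop("gene", None) or \
        quals.pop("standard_name", None) or sf.type
    return Feature(name, sf.type, start, end, strand, quals)


def read_genbank(path: str | Path) -> DnaMolecule:
    rec = SeqIO.read(str(path), "genbank")
    topology = "circular" if rec.annotations.get("topology") == "circular" else "linear"
    n = len(rec.seq)
    feats = [_to_feature(sf, n) for sf in rec.features if sf.location is not None]
    if topology == "circular":
        return DnaMolecule.circular(str(rec.seq), rec.id, features=feats,
                                    provenance=rec.description or "")
    return DnaMolecule.linear(str(rec.seq), rec.id, features=feats,
                              provenance=rec.description or "")


def write_genbank(mol: DnaMolecule, path: str | Path) -> None:
    n = len(mol.sequence)
    rec = SeqRecord(Seq(mol.sequence), id=re.sub(r"[^\w.-]", "_", mol.id)[:16] or "mol",
                    name=re.sub(r"[^\w.-]", "_", mol.id)[:16] or "mol",
                    description=mol.provenance or "")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if mol.is_circular else "linear"
    for f in mol.features:
        strand = -1 if f.strand == "-" else 1
        quals = {"label": [f.name], **{k: [v] for k, v in f.qualifiers.items()}}
        if f.end > n:   # wraps the origin
            loc = CompoundLocation([SimpleLocation(f.start, n, strand),
                                    SimpleLocation(0, f.end - n, strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path) -> list[DnaMolecule]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return [DnaMolecule.linear(str(r.seq).upper(), r.id, provenance=r.description)
            for r in records]


def read_plain(path: str | Path) -> DnaMolecule:
    """Plain/.seq text: whitespace, digits and punctuation are stripped,
    the rest upper-cased."""
    raw = Path(path).read_text()
    seq = re.sub(r"[^A-Za-z]", "", raw).upper()
    if not seq:
        raise ValueError(f"no sequence in {path}")
    return DnaMolecule.linear(seq, Path(path).stem)
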