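# clonesim

In-silico molecular cloning and recombineering. `clonesim` simulates the
wet-lab operations of recombinant DNA work — restriction and CRISPR
digestion, end modification, ligation, site-specific and homologous
recombination, PCR, screening, transformation and incubation — as
mechanistic operations on a double-stranded DNA model, and composes them
into a recalculable workflow DAG. Instead of copying a region between
two landmarks, every operation enumerates the products its chemistry
allows, including intermediates and by-products, and screening steps
(gel, marker features, colony PCR) pick the intended construct from the
mixture, exactly as at the bench.

It is written for molecular biologists and synthetic-biology tool
builders who want to verify a cloning strategy — classic sticky-end
cloning, Golden Gate, Gibson/SLIC, Cre-lox, integrase (attB×attP)
assembly, lambda-Red knockouts — before ordering primers.

## The model

**Molecules.** A molecule is its top strand 5'→3' plus a topology
(circular, linear, or genomic fragment) and two typed ends: overhang
polarity (blunt / 5' / 3'), the protruding-strand sequence, a 5'
phosphorylation flag, and a hairpin flag. Identity is a canonical
digest invariant under circular rotation and strand flip.

**Cutting.** A restriction enzyme is a recognition pattern plus two cut
offsets `(cut_top, cut_bottom)`; `cut_top < cut_bottom` leaves a 5'
overhang, `>` a 3' overhang, `=` a blunt cut, and offsets outside the
site describe Type IIS enzymes. A guide RNA is compiled to a temporary
enzyme (protospacer+PAM, blunt cut 3 bp from the PAM), so CRISPR
digestion reuses the same machinery.

**Joining.** Two ends ligate iff (1) at least one carries a 5'
phosphate and (2) both are blunt, or both overhangs have the same
polarity and reverse-complementary sequences. Normal mode is a bounded
search with per-fragment copy limits; exhaustive mode returns only
products consuming every fragment exactly its specified number of times
(multi-part assembly semantics).

**Recombination = virtual digestion + virtual ligation.** Recombination
sites and shared homology blocks are treated as virtual restriction
sites: cutting them yields marker-labelled pseudo-overhangs, the
ligation engine is rerun with marker compatibility in place of base
pairing, and anything still carrying a virtual end is discarded, so only
chemically real molecules are reported. Reversible systems (loxP, FRT)
use self-compatible markers; irreversible pairs (attB×attP) use distinct
markers so products cannot revert. Homology search is windowed per
family: lambda-Red uses arms of ≥ 20 bp within 100 bp of the cassette
ends; SLIC/Gibson/yeast annealing uses blocks within 250 bp of a
fragment end; plain homologous recombination is unwindowed.

**PCR.** Stage 1 enumerates every single-strand extension product any
primer can make on any template strand (iterated, so products prime on
products — this produces overlap-extension fusions); stage 2 anneals
single strands with complementary 3' regions into duplexes. Products
flanked by primers on both strands are the exponential amplicons;
everything else is a by-product.

## Worked example: Golden Gate assembly

```python
from clonesim import (FixtureSpec, generate_fixture, digest, gel_select,
                      ligate, JoinMode, canonical_hash, DnaMolecule)

fx = generate_fixture(FixtureSpec("golden_gate_set", seed=7,
                                  params={"n_inserts": 3}))
fragments, warnings = digest(list(fx.molecules.values()), ["BsaI"])
print(f"{len(fragments)} fragments after BsaI digestion")
kept = gel_select(fragments, 60, 1_000_000)
print("gel-selected:", [(f.id, len(f.sequence), f.left_end.overhang_seq,
                         f.right_end.overhang_seq) for f in kept])
products = ligate(kept, JoinMode("exhaustive", copies=1))
circles = [m for m in products if m.is_circular]
print(f"{len(products)} exhaustive products, {len(circles)} circular")
designed = DnaMolecule.circular(fx.manifest["expected_circle"])
print("assembled circle:", len(circles[0].sequence), "bp; matches design:",
      canonical_hash(circles[0]) == canonical_hash(designed))
```

prints

```
11 fragments after BsaI digestion
gel-selected: [('gg_backbone:f1', 558, 'CAAC', 'GACT'), ('insert1:f2', 128, 'AGTC', 'TGGA'), ('insert2:f2', 128, 'TCCA', 'TTCC'), ('insert3:f2', 128, 'GGAA', 'GTTG')]
5 exhaustive products, 1 circular
assembled circle: 926 bp; matches design: True
```

BsaI releases each part with its designed 4-nt 5' overhangs (shown per
end); the sub-50-bp site stubs and the backbone stuffer vanish at the
gel step; exhaustive ligation over the overhang cycle yields open chains
plus exactly one circle, which is hash-identical to the designed
plasmid. `clonesim.examples` builds this and four other complete
strategies (restriction cloning, ΦC31 assembly, HK022 knock-in +
lambda-Red knockout, multi-fragment Gibson) as executable workflow
projects whose terminal screening node keeps exactly one product.

A thin CLI wraps the one-shot operations and project files:
`clonesim digest vector.gb -e EcoRI,BamHI`, `clonesim pcr`, `clonesim
ligate`, `clonesim recombine`, `clonesim run project.json`,
`clonesim summary project.json`.

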