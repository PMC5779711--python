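# Methods

## The span model of double-stranded DNA

A molecule stores its top strand 5'→3' in a *span* coordinate frame
covering the union of both strands' extents. Where only one strand is
physically present (a terminal overhang), the stored bases are the
top-strand reading of that region; the `DnaEnd` objects say which strand
is recessed. This makes every cut-and-join computation uniform string
arithmetic:

* a double-strand cut at `(t, b)` (top-/bottom-strand positions) splits
  the span at `min` and `max`, with the interval between them becoming
  the overhang of both daughter ends (`t < b` → 5' overhang, `t > b` →
  3', `t = b` → blunt);
* two ends are joinable exactly when the suffix of one span equals the
  prefix of the other over the overhang length, and joining is
  concatenation minus that overlap;
* circularization removes one overhang copy.

Mass bookkeeping uses total nucleotides over both strands
(`2·span − overhangs`), which is exactly conserved by cutting and
ligation; the "length" reported for gels is the span length.

Linear products are returned on their lexicographically minimal strand
so that output orientation is a function of the product, not of the
search order that discovered it.

## Ligation

Two ends join iff at least one has a 5' phosphate, and either both are
blunt or both overhangs share polarity and are reverse complements.
Hairpin ends and virtual (recombination-intermediate) ends never ligate;
overhangs containing degenerate bases are treated as non-matching, so no
concrete product is ever fabricated from ambiguity codes.

Normal mode performs joining rounds over a pool seeded with the input
fragments: every ordered pair in both orientations, plus a
self-circularization pass, with per-fragment copy limits and
canonical-hash deduplication; the pool after `rounds` rounds is the
reaction mixture (unreacted substrates included). The number of rounds
and the copy limits are the user-facing complexity knobs. Exhaustive
mode enumerates chains (all orders and orientations, depth-first) that
consume exactly the requested copy count of every fragment and returns
the distinct full-length linear chains and circles; with a unique
overhang cycle, as in Golden Gate, exactly one circle survives.

## Recombination as virtual digestion / virtual ligation

Stage 1 turns recombination into restriction geometry. A site-specific
site is cut across its core (`t = core_start`, `b = core_end`), giving
pseudo-5'-overhang ends labelled with `(site, side)` markers: the
upstream fragment carries the site's first arm ("A" side), the
downstream its second arm ("B"). A shared homology block between two
molecules (or two loci of one molecule) is cut across its full extent
and labelled with the block itself as marker. Stage 2 reruns the
ligation engine with marker compatibility in place of the phosphate and
base-pairing rules: homology markers must be equal; site markers must
pair A-with-B between partner sites. Reversible systems (loxP, FRT)
partner themselves, so excision products can re-integrate; irreversible
pairs (attB×attP for the serine integrases) partner only each other, so
the attL/attR-bearing products are terminal. Stage 3 discards every
molecule still carrying a virtual end; only chemically real DNA is
reported. Markers are namespaced per invocation so no state leaks
between calls.

Homology detection finds maximal exact common substrings via k-mer
seeding on shared diagonals; only exact matches recombine. Family
windows restrict which blocks are *used* on linear donor fragments
(circular and genomic targets are unconstrained):

| family               | min homology | terminal window | extra rule |
|----------------------|--------------|-----------------|------------|
| homologous           | 20 bp        | unbounded       | — |
| lambda_red           | 20 bp (arm)  | 100 bp          | arms searched only near cassette ends |
| in_vitro_annealing   | 15 bp        | 250 bp          | block must be flush with the fragment end (no tail is chewed back) |
| in_vivo_annealing    | 15 bp        | 250 bp          | non-matching tails removed by the splice |

A block is eligible when its distal edge lies within the window of the
nearer terminus. Because blocks are maximal exact matches, a scan
fixture must pin mismatching guard bases at the designed block's
boundaries, otherwise a chance matching neighbour base extends the block
one position past the window; the acceptance scans do this explicitly.

Exhaustive-mode recombination runs the joining closure to its fixed
point and keeps fully resolved products that include at least one
fragment from every cut input; this is what Gibson verification and
cre-lox re-integration use. Normal mode simply bounds the closure.

## PCR

Stage 1: for each sense strand S of each template (doubled for circles,
extension capped at one full turn) and each primer P, every exact
occurrence of P's 3'-terminal `min_anneal_3p` bases (default 15 nt)
yields the single strand `P + S[site_end:]` — the 5' tail verbatim, so
mismatched tails (cloning adapters, Gibson linkers) behave correctly.
New strands re-enter as templates until a fixed point (capped at 10
iterations). Stage 2 anneals strand pairs whose 3' regions are mutually
complementary over ≥ `min_anneal_3p` bases at every valid overlap and
fills in; duplexes led by a primer on both strands are products, the
rest by-products. Exact 3'-match annealing keeps the product set
decidable; mismatch thermodynamics is out of scope. On circular
templates, capping first-cycle extension at one turn admits a minor
long by-product alongside the true origin-spanning amplicon; it is
flanked by both primers and reported as a product, as the early-cycle
chemistry implies.

## Thermodynamics

Wallace rule `2(A+T)+4(G+C)` and unified nearest-neighbor Tm
(SantaLucia 1998 parameters through Biopython's `Tm_NN`, total strand
concentration C_T/4 with default C_T = 0.5 µM, entropy salt correction
`0.368·(N−1)·ln[Na+]` at 50 mM Na+). Secondary-structure screening
(hairpins, self-/cross-dimers) sums unified dG(37) increments over
exhaustively enumerated stems of ≥ 3 bp (loops ≥ 3 nt, flat 3.5
kcal/mol loop penalty) for oligos up to 60 nt, reporting the
minimum-dG structure of each kind below a −1 kcal/mol cutoff. Primer
design extends 3'-ward from the requested 5' position until Tm reaches
the threshold (minimal primer, 60-nt cap); pair search ranks candidate
pairs by their weakest secondary structure. The Gibson designer grows
each junction overlap base by base from the upstream neighbour's
terminus until both length and Tm thresholds hold (shortest qualifying
linker, deterministic), prepends it to the junction's non-fixed PCR
primer (never altering synthesized fragments), and verifies the design
by exhaustive in-vivo-annealing recombination, which must return exactly
one circle containing every source once.

## Screening and hosts

Gel selection applies an unconditional 50-bp visibility floor before the
user's inclusive range. Feature screening counts features by name,
strand-blind. Colony-PCR screening keeps molecules yielding at least
one product inside the inclusive length range. Sequence comparison
aligns reads semi-globally (match 2 / mismatch −3 / gap open −5 /
extend −2, free template end gaps, both orientations tried) and writes
exact-match runs, mismatches, insertions and deletions as features on
the template; reads scoring below 0.6·length are flagged unaligned.
Indel positions are reported where the aligner places them, which for a
repeated context can slide a few bases. ORF detection scans all frames
(both strands, wrapping on circles) for start-codon-to-in-frame-stop
intervals of at least the requested length, stop included.

A host persists a plasmid only if one of the plasmid's `ori` features
names an origin in the host's primase commands; overnight incubation
with antibiotics then requires a matching resistance feature on a
persisting plasmid, an integrated genomic copy, or an intrinsic
resistance. Origin and antibiotic matching is by exact name between
feature qualifiers and host strings. Combinational transformation
yields one cell per non-empty subset of the DNA pool.

## Workflow DAG

Nodes hold operation kind, parameters, source references, status
(`not_started`/`in_progress`/`finished` — with `completed` accepted as
a legacy alias — /`obsolete`), notes and cached results. Execution is
content-addressed over (op kind, params, source-result hashes), so
recalculation skips nodes whose world is unchanged. Recalculating a
node re-executes it and its descendants in lexicographic topological
order; a failing node leaves itself and its descendants stale while
sibling branches continue. Every DNA result is auto-annotated against
the project feature library. An executed node with zero products is a
valid source (the emptiness propagates as empty input, mirroring an
empty lane at the bench). Projects serialize to canonical JSON
(sorted keys), so save → load → save is byte-identical.

## Synthetic data

The fixture generator builds all test substrates deterministically from
a seed, each with a ground-truth manifest (declared site counts,
expected product lengths or sequences): a toy plasmid (ori + ampR + MCS
with declared unique sites), a Golden Gate set with a designed 4-nt
overhang cycle (the backbone stuffer is deliberately sub-gel-floor), a
two-loxP plasmid, an attB/attP plasmid pair, a genomic locus with
unique flanks, Gibson fragment sets with or without natural overlaps,
and template/read pairs with planted substitutions and indels.
Sequences are uniform random DNA with forbidden-pattern rejection; real
DNA's repeats, biased composition and methylation are not emulated, so
passing tests demonstrate the combinatorial and geometric correctness
of the algorithms, not robustness to repeat-rich genomes. The loxP and
FRT sequences are the canonical 34-bp sites; the bundled att sites are
synthetic stand-ins with the correct arm/core/partner structure, and
the bundled buffer-activity table is likewise illustrative.

Problem sizes throughout (plasmids of ~1 kb, genomic loci of 1 kb,
≤ 4-fragment assemblies, 50-node workflow graphs) were chosen as the
smallest sizes at which every behaviour of interest — wrapping origins,
multi-site digestion, window edges, multi-fragment cycles — is
exercised.

## Known limitations

Partial digestion, star activity and methylation sensitivity are not
modelled; homology must be exact; mismatch-tolerant primer annealing is
not modelled; recombination frequencies/kinetics are out of scope (all
feasible products are enumerated, none weighted); single-strand
intermediates of annealing-based assembly are not reportable objects;
chromatogram files are not parsed (reads enter as FASTA/plain text).
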