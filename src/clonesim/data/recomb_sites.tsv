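# Site-specific recombination sites:
# name<TAB>sequence<TAB>core_start<TAB>core_end<TAB>reversible(yes/no)<TAB>partners(comma-separated)
# loxP and FRT are the canonical 34-bp sites (13-bp arms, 8-bp core).
# The att sites are SYNTHETIC stand-ins: correct structure (two arms
# around a core identical between the B/P partners, irreversible
# pairing) but not the published arm sequences.  attL/attR entries are
# the corresponding hybrid products, kept for annotation; they have no
# partners because the simulated integrases act without an RDF.
loxP	ATAACTTCGTATAATGTATGCTATACGAAGTTAT	13	21	yes	loxP
FRT	GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC	13	21	yes	FRT
attB-phiC31	CGGTGCGGGTGCCAGTTGCACCACGGGTCGTGC	15	18	no	attP-phiC31
attP-phiC31	GTAGTGCCCCAACTGTTGGGGTAACGCCAGGGT	15	18	no	attB-phiC31
attL-phiC31	CGGTGCGGGTGCCAGTTGGGGTAACGCCAGGGT	15	18	no
attR-phiC31	GTAGTGCCCCAACTGTTGCACCACGGGTCGTGC	15	18	no
attB-HK022	ACCTGCAGGTCAGCATTCATACAGGCTTGAGCCAAC	15	21	no	attP-HK022
attP-HK022	GGCTACCTCTTCAGGTTCATACTCGTTACCTTGCGG	15	21	no	attB-HK022
attL-HK022	ACCTGCAGGTCAGCATTCATACTCGTTACCTTGCGG	15	21	no
attR-HK022	GGCTACCTCTTCAGGTTCATACAGGCTTGAGCCAAC	15	21	no
attB-lambda	CTGCTTTTTTATACTAACTTGAGCG	9	16	no	attP-lambda
attP-lambda	CAGCTTTTTTATACTAAGTTGGCAT	9	16	no	attB-lambda
attL-lambda	CTGCTTTTTTATACTAAGTTGGCAT	9	16	no
attR-lambda	CAGCTTTTTTATACTAACTTGAGCG	9	16	no
attB-phiBT1	TCGACGGTACTGACCTGGCAGGGCAACACC	12	17	no	attP-phiBT1
attP-phiBT1	GGAAGCTTCATTGACCTGAATCAGGTGCGC	13	18	no	attB-phiBT1
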