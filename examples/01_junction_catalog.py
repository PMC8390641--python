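"""Derive the TP53 junction catalog from the bundled gene model.

Prints every genomic exon-exon junction of the locus with its class: 'main'
junctions belong to the predominant isoform NM_000546.6; 'cterm_distinct' are
the two junctions flanking the extra C-terminal exon shared by the
beta-family isoforms (their counts are averaged downstream); 'utr5_distinct'
is the 3-bp-shifted 5'UTR acceptor of NM_001126112.2.
"""

import tp53junc as tj

catalog = tj.builtin_tp53_catalog()
print(catalog.to_frame().to_string(index=False))
print()
print("C-terminal distinct pair :", catalog.cterm_pair)
print("competing main junction  :", catalog.cterm_main)
print("5'UTR distinct / main    :", catalog.utr5_distinct, "/", catalog.utr5_main)
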