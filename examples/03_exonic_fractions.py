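"""Compute per-sample exonic fractions from junction counts.

The C-terminal fraction is mean(D1, D2) / (M + mean(D1, D2)) where D1 and D2
are the two distinct junctions flanking the extra exon and M is the competing
main-isoform junction; the 5'UTR fraction is D / (M + D).  A sample with a
zero denominator gets a missing fraction, not 0.
"""

import tempfile
from pathlib import Path

import tp53junc as tj

locus = tj.make_toy_locus()
catalog = locus.catalog()

counts_list = []
for sample_id, seed in [("sample_a", 1), ("sample_b", 2), ("sample_c", 3)]:
    mixture = tj.MixtureConfig(n_reads=8000, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        sam = Path(tmp) / "r.sam"
        tj.simulate_alignments(locus, mixture, sam)
        counts_list.append(tj.count_junction_reads(sam, catalog, sample_id=sample_id))

table = tj.fractions_table(counts_list, catalog)
print(table.to_string(index=False))
print(
    "\nWith a 4% C-terminal / 2% 5'UTR transcript mixture the fractions scatter"
    "\naround ~0.037 and ~0.02: at this depth each distinct junction collects"
    "\nonly 10-20 reads, so individual samples jitter considerably (and longer"
    "\nalternative transcripts dilute their per-junction coverage slightly)."
)
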