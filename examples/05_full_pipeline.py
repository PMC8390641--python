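"""One-command end-to-end run on synthetic inputs.

Generates a toy locus, cohort annotations and junction counts, then executes
the full pipeline (catalog -> counts -> fractions -> classify -> compare) and
lists the stage tables it wrote.  Equivalent CLI:

    tp53junc run --demo --outdir demo_out --seed 7
"""

import tempfile
from pathlib import Path

import tp53junc as tj
from tp53junc.cohort import write_annotations_tsv
from tp53junc.counting import write_counts_tsv

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    inputs = tmp / "inputs"
    locus = tj.make_toy_locus()
    paths = tj.write_locus(locus, inputs)
    sim = tj.simulate_cohort(tj.CohortSimConfig(seed=7, n_pairs=20), locus.catalog())
    write_annotations_tsv(sim.samples, inputs / "annotations.tsv")
    write_counts_tsv(sim.counts, inputs / "counts.tsv")

    config = tj.PipelineConfig(
        model=str(paths["model_json"]),
        annotations=str(inputs / "annotations.tsv"),
        counts=str(inputs / "counts.tsv"),
        outdir=str(tmp / "out"),
    )
    result = tj.run_pipeline(config)

    for name, path in sorted(result.tables.items()):
        print(f"{name:12s} {path.name:18s} {path.read_text().count(chr(10)) - 1} rows")
    print("\ncomparisons:")
    print((tmp / "out" / "comparisons.tsv").read_text())
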