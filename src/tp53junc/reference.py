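"""Bundled reference tables."""

from importlib import resources

import pandas as pd


def gtex_cterm_tissue_summary() -> pd.DataFrame:
    """Per-tissue summary of the C-terminal alternative-isoform exonic
    fraction in normal tissues (GTEx junction-read analysis): median, mean
    and sample count for 53 tissue types.

    Columns: ``tissue``, ``median_cterm_fraction``, ``mean_cterm_fraction``,
    ``n_samples``.  Fractions are proportions in [0, 1].
    """
    path = resources.files(__package__) / "data" / "gtex_cterm_tissue_summary.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
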