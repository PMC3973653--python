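"""Bundled reference tables.

``pool_individual_flags.tsv`` is the curated pool-vs-individual
concordance flag table for the 39 conserved sugarcane miRNAs that
responded in at least one comparison under 24-h water depletion:
comparison 1 ('+' iff the tolerant/sensitive expression ratio of the
pooled libraries agrees with the individual-cultivar libraries) and
comparison 2 ('+' iff the stress response direction agrees in at least
one genotype).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_pool_individual_flags() -> pd.DataFrame:
    """Flag table with columns mirna, sequence, comp1, comp2 (booleans)."""
    with resources.files("canesrna.data").joinpath(
        "pool_individual_flags.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in ("comp1", "comp2"):
        bad = ~df[col].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"malformed flag in column {col}")
        df[col] = df[col] == "+"
    return df
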