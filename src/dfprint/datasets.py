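"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_shared_dhs_counts() -> pd.DataFrame:
    """Published per-cell-type-pair DHS overlap and over-footprinted site
    counts for seven primary cell types (21 pairs, two directions each).

    Columns: cell_a, cell_b, dhs_a, dhs_b, shared, over_a, over_a_shared,
    over_b, over_b_shared.
    """
    with resources.files("dfprint.data").joinpath("shared_dhs_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
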