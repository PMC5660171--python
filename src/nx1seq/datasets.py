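"""Bundled reference tables.

``load_side_distribution`` returns the published per-gene positive-cell
counts for the two tumor sides (E-side n=305, M-side n=180 estimated cancer
cells): one half lists spheroid-signature genes whose printed fold is
E-over-M, the other serum-culture-signature genes printed M-over-E.  The
printed fold column is retained verbatim so arithmetic can be validated
against it; zero-denominator rows are internally inconsistent in the source
and are flagged by ``fold_defined``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from nx1seq.annotate import E_OVER_M, M_OVER_E

#: Estimated cancer cells entering the side comparison, per side.
SIDE_TOTAL_E = 305
SIDE_TOTAL_M = 180


def load_side_distribution() -> pd.DataFrame:
    """Printed side-distribution counts, percentages and folds."""
    ref = resources.files("nx1seq.data") / "side_distribution_printed.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="gene")
    denom_positive = df.apply(
        lambda r: (r["count_M"] if r["direction"] == E_OVER_M else r["count_E"]) > 0,
        axis=1,
    )
    df["fold_defined"] = denom_positive
    return df
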