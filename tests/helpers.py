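"""Shared test construction helpers."""

import pandas as pd

from mlagnn.omics import OmicsMatrix


def make_omics(values, tumor_samples, kind="expression", scale="raw"):
    """Build an OmicsMatrix from a DataFrame; columns not listed as tumor
    are labeled normal."""
    df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(values)
    df.index = df.index.astype(str)
    labels = pd.Series(
        ["tumor" if c in tumor_samples else "normal" for c in df.columns],
        index=df.columns, dtype=str,
    )
    return OmicsMatrix(values=df, labels=labels, omics_kind=kind, scale=scale)
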