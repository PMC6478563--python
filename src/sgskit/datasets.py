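"""Bundled reference tables.

``load_family_summary`` returns the published summary characteristics of the
43 high-risk extended families analyzed in the source study: familial
standardized incidence ratio (FSIR) and its p-value, observed and expected
case counts, number of genotyped cases, meioses between analyzed cases, and
the family-specific genome-wide significant/suggestive sharing thresholds.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_family_summary"]


def load_family_summary() -> pd.DataFrame:
    with resources.files("sgskit.data").joinpath("high_risk_families.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["family_id"] = df["family_id"].astype(str)
    return df
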