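"""Report-layer formatting helpers.

Published tables in this field truncate (not round) trailing digits — a
57.647% co-breeding fraction is printed as 57.64% and an SD of 0.01058 as
0.010 — so the report layer exposes truncation explicitly while every
computational function returns full precision.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["truncate", "format_mean_sd", "overlap_table"]


def truncate(x: float, ndigits: int) -> float:
    """Truncate ``x`` toward zero to ``ndigits`` decimal places."""
    factor = 10.0**ndigits
    return math.trunc(x * factor) / factor


def format_mean_sd(mean: float, sd: float, ndigits: int = 3) -> str:
    """``mean ± sd`` with both values truncated to ``ndigits`` places."""
    return f"{truncate(mean, ndigits):.{ndigits}f} ± {truncate(sd, ndigits):.{ndigits}f}"


def overlap_table(result, ndigits: int = 3) -> pd.DataFrame:
    """Per-variable table with truncated overlaps and significance asterisks."""
    df = result.to_dataframe().copy()
    df["observed"] = df["observed"].map(lambda v: truncate(v, ndigits))
    df["flag"] = df["significant"].map(lambda s: "*" if s else "")
    return df.drop(columns=["significant"])
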