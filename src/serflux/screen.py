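"""Mining genetic-interaction tables for aggravating partners of a query gene.

Input is a published interaction table (partner gene, epsilon score, p-value)
where negative epsilon means an aggravating (synthetic-sick/lethal)
interaction.  The module emits volcano-style summaries (-log10 p against
epsilon) and ranked hit lists; it never recomputes epsilon scores from raw
colony sizes.  Raw p-values drive the default significance call, matching
the volcano-plot convention, but a Benjamini-Hochberg adjusted column is
emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["InteractionRecord", "volcano_table", "top_interactions"]


@dataclass(frozen=True)
class InteractionRecord:
    gene: str
    epsilon: float
    p_value: float


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "gene": [r.gene for r in records],
                "epsilon": [r.epsilon for r in records],
                "p_value": [r.p_value for r in records],
            }
        )
    required = {"gene", "epsilon", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table is missing columns {sorted(missing)}")
    return df


def volcano_table(records, p_threshold: float = 0.05) -> pd.DataFrame:
    """Annotated volcano table sorted by significance.

    Adds ``neg_log10_p``, a Benjamini-Hochberg ``q_value`` and the boolean
    ``negative_significant`` (epsilon < 0 and p below the threshold).
    Records with p <= 0 or p > 1 or non-finite epsilon are rejected with a
    warning.  Sorted by ascending p, ties broken by descending |epsilon|.
    """
    df = _as_frame(records)
    if len(df) == 0:
        return df.assign(neg_log10_p=[], q_value=[], negative_significant=[])
    p = pd.to_numeric(df["p_value"], errors="coerce")
    eps = pd.to_numeric(df["epsilon"], errors="coerce")
    ok = np.isfinite(p) & (p > 0) & (p <= 1) & np.isfinite(eps)
    if (~ok).any():
        warnings.warn(
            f"rejecting {int((~ok).sum())} records with invalid p-value or epsilon",
            stacklevel=2,
        )
    df = df.loc[ok].copy()
    if len(df) == 0:
        return df.assign(neg_log10_p=[], q_value=[], negative_significant=[])
    df["neg_log10_p"] = -np.log10(df["p_value"].astype(float))
    df["q_value"] = multipletests(df["p_value"].astype(float), method="fdr_bh")[1]
    df["negative_significant"] = (df["epsilon"] < 0) & (df["p_value"] < p_threshold)
    df = df.sort_values(
        by=["p_value", "epsilon"],
        key=lambda s: s if s.name == "p_value" else -s.abs(),
        kind="stable",
    ).reset_index(drop=True)
    return df


def top_interactions(records, k: int = 10) -> pd.DataFrame:
    """Top-k partners by ascending p-value, ties by descending |epsilon|."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return volcano_table(records).head(k).reset_index(drop=True)
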