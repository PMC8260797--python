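"""Reference-genome choice for short-read mapping via a quality index.

For each candidate reference the index multiplies three terms: the
annotation completeness of the reference, the proportion of properly
mapped read pairs, and the probability that a mapping with the observed
mean MAPQ is correct.  MAPQ is Phred-scaled (error probability
10^(−MAPQ/10)), so

    index = completeness · P_proper · (1 − 10^(−MAPQ/10))  ∈ [0, 1].

A ``literal_formula`` switch instead evaluates 1 − 10^MAPQ in the last
term for auditing against sources that print the expression that way; the
literal form is negative for any positive MAPQ and is not used for
ranking by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = ["MappingSummary", "reference_quality_index", "choose_reference",
           "rank_references"]


@dataclass(frozen=True)
class MappingSummary:
    """Per-reference mapping summary for one short-read dataset."""

    reference_id: str
    completeness: float  # annotation completeness fraction in [0, 1]
    p_proper: float      # proportion properly paired in [0, 1]
    mean_mapq: float     # Phred-scaled, >= 0

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError(f"completeness {self.completeness} not in [0, 1]")
        if not 0.0 <= self.p_proper <= 1.0:
            raise ValueError(f"p_proper {self.p_proper} not in [0, 1]")
        if self.mean_mapq < 0:
            raise ValueError(f"mean_mapq {self.mean_mapq} must be >= 0")


def reference_quality_index(
    ms: MappingSummary, literal_formula: bool = False
) -> float:
    """Quality index of one reference; in [0, 1] for the default form."""
    if literal_formula:
        return ms.completeness * ms.p_proper * (1.0 - 10.0 ** ms.mean_mapq)
    return (
        ms.completeness
        * ms.p_proper
        * (1.0 - 10.0 ** (-ms.mean_mapq / 10.0))
    )


def rank_references(
    summaries: Iterable[MappingSummary], literal_formula: bool = False
) -> pd.DataFrame:
    """Index every reference, best first.

    Ties broken by higher completeness, then lexical reference id, making
    the ranking deterministic and input-order independent.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no mapping summaries given")
    ids = [s.reference_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference ids")
    rows = [
        {
            "reference": s.reference_id,
            "completeness": s.completeness,
            "p_proper": s.p_proper,
            "mean_mapq": s.mean_mapq,
            "quality_index": reference_quality_index(s, literal_formula),
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["quality_index", "completeness", "reference"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def choose_reference(
    summaries: Iterable[MappingSummary], literal_formula: bool = False
) -> str:
    """Reference id with the highest quality index."""
    return str(rank_references(summaries, literal_formula)["reference"].iloc[0])
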