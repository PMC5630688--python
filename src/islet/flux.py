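"""Donor-recipient direction inference for homologous island pairs.

For two homologous islands found in two hosts, the island pair's usage
patterns are compared with both host genome patterns.  When both islands
are compositionally closer to one host (by at least a decision margin),
that host is the likely donor and the other the recipient; otherwise the
direction is called ambiguous.  Transient intermediate hosts can never be
excluded — the call is a likelihood statement, not proof.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .oup import OUPattern, pattern_similarity

__all__ = ["Direction", "FluxCall", "infer_flux", "flux_table"]


class Direction(str, Enum):
    SUBJECT_TO_QUERY = "subject_to_query"   # subject's host is the donor
    QUERY_TO_SUBJECT = "query_to_subject"   # query's host is the donor
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class FluxCall:
    query_island: str
    subject_island: str
    direction: Direction
    sim_q_hostq: float
    sim_q_hosts: float
    sim_s_hostq: float
    sim_s_hosts: float
    margin_used: float


def infer_flux(
    query_id: str,
    query_pattern: OUPattern,
    query_host_pattern: OUPattern,
    subject_id: str,
    subject_pattern: OUPattern,
    subject_host_pattern: OUPattern,
    margin: float = 5.0,
) -> FluxCall:
    """Call the transfer direction for one homologous island pair.

    Both islands must prefer the same host by at least ``margin``
    percentage points for a directional call; anything else is ambiguous.
    Swapping query and subject flips a directional call and preserves
    ambiguity; raising the margin can only turn directional calls into
    ambiguous ones.
    """
    if query_host_pattern is None or subject_host_pattern is None:
        raise ValueError("both host genome patterns are required")
    sqq = pattern_similarity(query_pattern, query_host_pattern)
    sqs = pattern_similarity(query_pattern, subject_host_pattern)
    ssq = pattern_similarity(subject_pattern, query_host_pattern)
    sss = pattern_similarity(subject_pattern, subject_host_pattern)

    if sqs - sqq >= margin and sss - ssq >= margin:
        direction = Direction.SUBJECT_TO_QUERY
    elif sqq - sqs >= margin and ssq - sss >= margin:
        direction = Direction.QUERY_TO_SUBJECT
    else:
        direction = Direction.AMBIGUOUS
    return FluxCall(
        query_island=query_id,
        subject_island=subject_id,
        direction=direction,
        sim_q_hostq=sqq,
        sim_q_hosts=sqs,
        sim_s_hostq=ssq,
        sim_s_hosts=sss,
        margin_used=margin,
    )


def flux_table(pairs, margin: float = 5.0) -> pd.DataFrame:
    """Apply :func:`infer_flux` to an iterable of pair records.

    Each record is ``(query_id, query_pattern, query_host_pattern,
    subject_id, subject_pattern, subject_host_pattern)``.  Returns one row
    per pair; filter on the ``direction`` column for donor/recipient or
    ambiguous subsets.
    """
    calls = [infer_flux(*rec, margin=margin) for rec in pairs]
    return pd.DataFrame(
        [
            (
                c.query_island,
                c.subject_island,
                c.sim_q_hostq,
                c.sim_q_hosts,
                c.sim_s_hostq,
                c.sim_s_hosts,
                c.margin_used,
                c.direction.value,
            )
            for c in calls
        ],
        columns=[
            "query",
            "subject",
            "sim_q_hostq",
            "sim_q_hosts",
            "sim_s_hostq",
            "sim_s_hosts",
            "margin",
            "direction",
        ],
    )
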