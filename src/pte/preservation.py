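"""Per-sorter pile-preservation diagnostics.

A sorter's pile is *preserved* when every excerpt it contains landed in
the same final group: preservation measures how much of each individual
perspective survives the combined grouping.  A pile containing an
unassigned excerpt can never be preserved, because that excerpt belongs
to no group at all.  Sorters with unusually low preservation saw the
data differently from the consensus and are natural candidates for
qualitative follow-up.
"""

from __future__ import annotations

import pandas as pd

from .communities import Clustering
from .errors import ConsistencyError
from .sort_io import SortDataset


def preservation_table(
    ds: SortDataset,
    clustering: Clustering,
    count_singletons: bool = False,
) -> pd.DataFrame:
    """Per-participant pile counts: total, multi-excerpt, and preserved.

    By default preservation is counted over multi-excerpt piles only —
    a singleton pile is trivially coherent and would inflate the
    diagnostic.  With ``count_singletons`` a singleton pile also counts
    as preserved when its excerpt was assigned to a group.
    """
    covered = clustering.excerpts()
    missing = [e for e in ds.excerpt_ids if e not in covered]
    if missing:
        raise ConsistencyError(
            "clustering does not cover dataset excerpts: " + ", ".join(missing)
        )
    rows = []
    for p in ds.participant_ids:
        piles = ds.piles(p)
        n_piles = len(piles)
        n_multi = 0
        n_preserved = 0
        for members in piles.values():
            assigned = {clustering.groups.get(e) for e in members}
            coherent = None not in assigned and len(assigned) == 1
            if len(members) >= 2:
                n_multi += 1
                if coherent:
                    n_preserved += 1
            elif count_singletons and coherent:
                n_preserved += 1
        rows.append((p, n_piles, n_multi, n_preserved))
    return pd.DataFrame(
        rows, columns=["participant_id", "piles", "piles_multi", "piles_preserved"]
    )


def low_preservation_flags(
    table: pd.DataFrame,
    threshold: float,
    denominator: str = "multi",
) -> list[str]:
    """Participants whose preservation ratio falls below ``threshold``.

    The ratio is preserved piles over multi-excerpt piles (default) or
    over all piles (``denominator="all"``).  Returned ascending by ratio,
    so the most divergent sorter comes first.  Participants with a zero
    denominator are skipped.
    """
    if denominator not in ("multi", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    col = "piles_multi" if denominator == "multi" else "piles"
    flagged = []
    for _, row in table.iterrows():
        denom = row[col]
        if denom <= 0:
            continue
        ratio = row["piles_preserved"] / denom
        if ratio < threshold:
            flagged.append((ratio, str(row["participant_id"])))
    flagged.sort()
    return [p for _, p in flagged]
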