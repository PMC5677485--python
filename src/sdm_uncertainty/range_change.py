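"""Range Change Index and vulnerability ranks.

RCI = (forecast range − hindcast range) / hindcast range, with range size
the count of sites predicted occupied.  The baseline is always a
pseudo-GCM *hindcast*, never the observed-climate prediction, so that a
member's constant bias cancels out of its own range change.  Ranks order
species by RCI within each factorial configuration (rank 1 = most
negative = most projected loss).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FACTOR_COLUMNS = ["gcm", "hypothesis", "collinearity", "threshold"]


def rci(hindcast_map, forecast_map) -> float:
    """Proportional range change between two binary site maps."""
    h = np.asarray(hindcast_map).astype(int)
    f = np.asarray(forecast_map).astype(int)
    if h.shape != f.shape:
        raise ValueError("hindcast and forecast maps must cover identical site sets")
    hr = int(h.sum())
    if hr == 0:
        raise ZeroDivisionError("hindcast range is empty; RCI undefined")
    return float((int(f.sum()) - hr) / hr)


def rank_vulnerability(records: pd.DataFrame, on_missing: str = "raise") -> pd.DataFrame:
    """Species ranks per configuration (ascending RCI; ties → average rank).

    ``records`` needs columns species, gcm, hypothesis, collinearity,
    threshold, rci.  Returns a configuration × species table of ranks.
    Missing species-configuration cells raise, listing the gaps;
    ``on_missing='drop'`` instead drops the incomplete configurations.
    """
    wide = records.pivot_table(
        index=FACTOR_COLUMNS, columns="species", values="rci", aggfunc="first"
    )
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        if on_missing == "drop":
            wide = wide[~incomplete]
        else:
            gaps = [
                (cfg, sp)
                for cfg, row in wide[incomplete].iterrows()
                for sp, v in row.items()
                if pd.isna(v)
            ]
            raise ValueError(f"missing species-configuration cells: {gaps[:10]}")
    return wide.rank(axis=1, method="average", ascending=True)


def rank_frequency(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of each rank per species across configurations.

    Rows (species) sum to the number of configurations; average-tie ranks
    appear as their own (possibly half-integer) columns.
    """
    long = rank_table.stack().rename("rank").reset_index()
    freq = pd.crosstab(long["species"], long["rank"])
    freq.columns.name = "rank"
    return freq
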