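"""Published-style reference tables used as worked-example inputs.

``IGG_CAPTURE_RECAPTURE`` is a capture-recapture summary of an IgG
heavy-chain repertoire from one adult donor sampled at five weekly visits:
clusters observed in a 100,000-sequence sample at each visit (total and
abundant, i.e. >= 10 sequences), Chapman size estimates of the effective
cluster repertoire from biological replicates, and the printed
percent-sampled columns.  The percent columns and their summary statistics
are re-derivable from the first four columns with ``bcrep.depth``; the
package's validation suite does exactly that.
"""

from __future__ import annotations

import pandas as pd

from bcrep.depth import percent_sampled, round_half_up

IGG_CAPTURE_RECAPTURE = pd.DataFrame(
    {
        "day": [0, 7, 14, 21, 28],
        "total_clusters": [12152, 13186, 16907, 17930, 15463],
        "abundant_clusters": [1919, 367, 1137, 861, 775],
        "total_size_estimate": [132841, 108253, 162868, 158311, 150605],
        "abundant_size_estimate": [10426, 1168, 5368, 3013, 3245],
        "total_pct_printed": [9.1, 12.2, 10.4, 11.3, 10.3],
        "abundant_pct_printed": [18.4, 31.4, 21.2, 28.6, 23.9],
    }
)

#: printed summary row of the same table (column means; percents are the
#: rounded means of the per-day percent columns)
IGG_CAPTURE_RECAPTURE_MEANS = {
    "total_clusters": 15128,
    "abundant_clusters": 1012,
    "total_size_estimate": 142576,
    "abundant_size_estimate": 4644,
    "total_pct": 10.7,
    "abundant_pct": 24.7,
}


def recompute_percent_sampled(table: pd.DataFrame = IGG_CAPTURE_RECAPTURE) -> pd.DataFrame:
    """Re-derive the percent-sampled columns from the cluster counts."""
    out = table.copy()
    out["total_pct"] = [
        percent_sampled(o, e)
        for o, e in zip(table["total_clusters"], table["total_size_estimate"])
    ]
    out["abundant_pct"] = [
        percent_sampled(o, e)
        for o, e in zip(table["abundant_clusters"], table["abundant_size_estimate"])
    ]
    return out


def summary_row(table: pd.DataFrame = IGG_CAPTURE_RECAPTURE) -> dict[str, float]:
    """Column means as printed: counts rounded to integers, per-day percents
    averaged and rounded to one decimal."""
    derived = recompute_percent_sampled(table)
    return {
        "total_clusters": round_half_up(table["total_clusters"].mean(), 0),
        "abundant_clusters": round_half_up(table["abundant_clusters"].mean(), 0),
        "total_size_estimate": round_half_up(table["total_size_estimate"].mean(), 0),
        "abundant_size_estimate": round_half_up(table["abundant_size_estimate"].mean(), 0),
        "total_pct": round_half_up(derived["total_pct"].mean(), 1),
        "abundant_pct": round_half_up(derived["abundant_pct"].mean(), 1),
    }


def size_estimate_ratios(table: pd.DataFrame = IGG_CAPTURE_RECAPTURE) -> dict[str, float]:
    """Max/min ratio of the day-to-day size estimates (repertoire-size
    fluctuation across visits), for the total and the abundant repertoire."""
    return {
        "total": table["total_size_estimate"].max() / table["total_size_estimate"].min(),
        "abundant": table["abundant_size_estimate"].max() / table["abundant_size_estimate"].min(),
    }
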