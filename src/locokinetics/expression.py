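"""RNAscope co-expression count summaries.

Summarizes per-animal cell counts (numerator marker positive among
denominator-marker positive cells, per region) into percentages under two
explicit aggregation methods: the mean of per-animal percentages
(``per_animal_mean``, the default) and the percentage of summed counts
(``pooled``).  Both are always available side by side because count data
aggregated across animals with very different denominators can diverge
between the two; the pooled value always lies within the per-animal range.
Display rounding is half-away-from-zero to one decimal; full precision is
kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ProportionSummary", "load_count_table", "load_example_counts",
    "validate_count_table", "proportions", "coexpression_matrix",
    "round_half_away",
]

COUNT_COLUMNS = ("animal", "region", "denom_marker", "num_marker",
                 "positive", "denominator")


@dataclass
class ProportionSummary:
    """Co-expression percentage for one (region, denominator, numerator)
    combination."""
    region: str
    denom_marker: str
    num_marker: str
    method: str
    percentage: float            # full precision
    per_animal: dict             # animal -> percentage
    n_animals: int

    @property
    def display(self) -> str:
        return f"{round_half_away(self.percentage, 1):.1f}%"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the printed values),
    unlike banker's rounding."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (table["denominator"] <= 0).any():
        bad = table.loc[table["denominator"] <= 0, "animal"].tolist()
        raise ValueError(f"zero denominator for animal(s): {bad}")
    if ((table["positive"] < 0)
            | (table["positive"] > table["denominator"])).any():
        raise ValueError("positive counts must lie in [0, denominator]")
    return table


def load_count_table(path) -> pd.DataFrame:
    return validate_count_table(pd.read_csv(path))


def load_example_counts() -> pd.DataFrame:
    """Bundled per-animal RNAscope counts for D1/D2 x Vglut2 co-expression
    in the CnF and PPN (transcribed published counts; one row per animal)."""
    ref = resources.files("locokinetics.data") / "rnascope_counts.csv"
    with resources.as_file(ref) as p:
        return load_count_table(p)


def proportions(table: pd.DataFrame, region: str, denom_marker: str,
                num_marker: str, method: str = "per_animal_mean") -> ProportionSummary:
    """Co-expression percentage for one region and marker pair.

    Rows are first aggregated per animal (summing slices); the per-animal
    percentage is 100 * positive / denominator.  ``per_animal_mean`` is the
    arithmetic mean of those percentages; ``pooled`` is 100 * sum(positive)
    / sum(denominator).
    """
    if method not in ("per_animal_mean", "pooled"):
        raise ValueError("method must be 'per_animal_mean' or 'pooled'")
    validate_count_table(table)
    sel = table[(table["region"] == region)
                & (table["denom_marker"] == denom_marker)
                & (table["num_marker"] == num_marker)]
    if sel.empty:
        raise ValueError(f"no rows for {region}/{denom_marker}/{num_marker}")
    per = sel.groupby("animal")[["positive", "denominator"]].sum()
    pct = 100.0 * per["positive"] / per["denominator"]
    if method == "per_animal_mean":
        value = float(pct.mean())
    else:
        value = float(100.0 * per["positive"].sum() / per["denominator"].sum())
    return ProportionSummary(region=region, denom_marker=denom_marker,
                             num_marker=num_marker, method=method,
                             percentage=value,
                             per_animal=pct.to_dict(), n_animals=len(per))


def coexpression_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulated summary over all (region, denominator, numerator)
    combinations with both aggregation methods side by side."""
    validate_count_table(table)
    rows = []
    combos = table[["region", "denom_marker", "num_marker"]].drop_duplicates()
    for region, dm, nm in combos.itertuples(index=False):
        a = proportions(table, region, dm, nm, "per_animal_mean")
        b = proportions(table, region, dm, nm, "pooled")
        vals = np.array(list(a.per_animal.values()))
        rows.append({
            "region": region, "denom_marker": dm, "num_marker": nm,
            "per_animal_mean_pct": a.percentage,
            "pooled_pct": b.percentage,
            "n_animals": a.n_animals,
            "min_animal_pct": float(vals.min()),
            "max_animal_pct": float(vals.max()),
        })
    return pd.DataFrame(rows)
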