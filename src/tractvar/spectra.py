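"""Normalized mutation statistics and positional spectra.

All statistics are simple count/denominator ratios where the denominator
comes from a genome-wide tract census:

* ``F SNV``      = SNV count / (N tracts x n)          per (class, n)
* positional %   = SNV count at position p / N x 100   per (class, n, p, type)
* ``F slip``     = (+1 and -1 slippage) / (N x n)      per (class, n)
* ``F Indel``    = indels / (N x n) along the tract, indels / N at the
                   flanking positions
* insertion %    = insertions at junction j / N x 100  per (class, n, j)

Flank-conditioned spectra (e.g. TA[n]T tracts) divide by the matching
flank-conditioned census stratum, never by the class total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracts import TractCensus
from .variants import TractVariantAssignment


@dataclass
class SpectrumTable:
    """A tidy statistic table plus its dataset label."""

    table: pd.DataFrame
    label: str = ""
    value_col: str = "percent"

    def total_percent(self, tract_class: str, n: int) -> float:
        t = self.table
        sel = (t["tract_class"] == tract_class) & (t["n"] == n)
        return float(t.loc[sel, self.value_col].sum())

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.insert(0, "dataset", self.label)
        out.to_csv(path, sep="\t", index=False)


def _frame(assignments: Iterable[TractVariantAssignment]) -> pd.DataFrame:
    from .variants import assignments_to_frame

    if isinstance(assignments, pd.DataFrame):
        return assignments
    return assignments_to_frame(assignments)


def f_snv_table(
    assignments: Iterable[TractVariantAssignment], census: TractCensus
) -> pd.DataFrame:
    """F SNV = tract-SNV count / (N tracts x n) per (class, n).

    Strata present in the census with no SNVs report 0; strata absent
    from the census are omitted.
    """
    df = _frame(assignments)
    df = df[df.category == "tract_SNV"]
    counts = df.groupby(["tract_class", "n"]).size().rename("count")
    out = census.marginal().rename(columns={"count": "denominator"})
    out = out.merge(counts, on=["tract_class", "n"], how="left").fillna({"count": 0})
    out = out[out.denominator > 0]
    out["f_snv"] = out["count"] / (out["denominator"] * out["n"])
    return out[["tract_class", "n", "count", "denominator", "f_snv"]]


def positional_spectrum(
    assignments: Iterable[TractVariantAssignment],
    census: TractCensus,
    flank5: str | None = None,
    flank3: str | None = None,
    per_tract: bool = False,
) -> SpectrumTable:
    """Percent SNVs per (class, n, position, substitution).

    percent = count / N x 100 with N the census count of the matching
    stratum; when flank filters are given both the numerator assignments
    and the denominator strata are restricted consistently.  Positions 0
    and n+1 are the flank rows (flank_SNV events).  ``per_tract`` counts
    tracts with at least one matching SNV instead of SNV events.
    """
    df = _frame(assignments)
    df = df[df.category.isin(["tract_SNV", "flank_SNV"])].copy()
    if flank5 is not None:
        df = df[df.flank5 == flank5]
    if flank3 is not None:
        df = df[df.flank3 == flank3]
    if per_tract:
        df = df.drop_duplicates(["chrom", "start", "end", "position", "substitution"])
    counts = (
        df.groupby(["tract_class", "n", "position", "substitution"])
        .size()
        .rename("count")
        .reset_index()
    )
    denom = {
        (c, n): census.count(c, n, flank5, flank3)
        for c, n in counts[["tract_class", "n"]].drop_duplicates().itertuples(index=False)
    }
    counts["denominator"] = [
        denom[(c, n)] for c, n in counts[["tract_class", "n"]].itertuples(index=False)
    ]
    counts = counts[counts.denominator > 0].copy()
    counts["percent"] = counts["count"] / counts["denominator"] * 100.0
    return SpectrumTable(counts)


def direction_bias(
    assignments: Iterable[TractVariantAssignment],
) -> pd.DataFrame:
    """Fraction of tract SNVs mutating toward a flanking base.

    Per (class, n, p): the fraction of tract-SNV alts equal to the 5'
    flank base, the 3' flank base, and either.  Tracts with an N flank
    are excluded.
    """
    df = _frame(assignments)
    df = df[(df.category == "tract_SNV") & (df.flank5 != "N") & (df.flank3 != "N")].copy()
    alt = df.substitution.str.split(">").str[1]
    df["to_flank5"] = alt == df.flank5
    df["to_flank3"] = alt == df.flank3
    df["to_either"] = df.to_flank5 | df.to_flank3
    g = df.groupby(["tract_class", "n", "position"])
    out = g[["to_flank5", "to_flank3", "to_either"]].mean().reset_index()
    out["count"] = g.size().values
    return out


def slippage_stats(
    assignments: Iterable[TractVariantAssignment], census: TractCensus
) -> pd.DataFrame:
    """F slip = slippage events / (N x n), and the +1/-1 event ratio.

    The ratio is NaN when no -1 events were observed in a stratum.
    """
    df = _frame(assignments)
    df = df[df.category.isin(["slippage_plus", "slippage_minus"])]
    counts = (
        df.groupby(["tract_class", "n", "category"]).size().unstack(fill_value=0)
    )
    for col in ("slippage_plus", "slippage_minus"):
        if col not in counts:
            counts[col] = 0
    counts = counts.reset_index()
    out = census.marginal().rename(columns={"count": "denominator"})
    out = out.merge(counts, on=["tract_class", "n"], how="left").fillna(0)
    out = out[out.denominator > 0].copy()
    out["f_slip"] = (out.slippage_plus + out.slippage_minus) / (out.denominator * out.n)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["plus_minus_ratio"] = np.where(
            out.slippage_minus > 0, out.slippage_plus / out.slippage_minus, np.nan
        )
    return out[
        ["tract_class", "n", "slippage_plus", "slippage_minus", "denominator",
         "f_slip", "plus_minus_ratio"]
    ]


def _indel_location(row) -> str:
    if row.category == "indel_del":
        return row.location
    # insertions: junction 0 abuts the 5' flank, junctions >= n the 3' side
    if row.position == 0:
        return "before_tract"
    if row.position >= row.n:
        return "after_tract"
    return "in_tract"


def indel_fractions(
    assignments: Iterable[TractVariantAssignment], census: TractCensus
) -> pd.DataFrame:
    """F Indel per (class, n, location).

    Along the tract ('in_tract') the denominator is N x n; at the
    flanking positions ('before_tract'/'after_tract') it is N alone.
    Slippage events are excluded by construction.
    """
    df = _frame(assignments)
    df = df[df.category.isin(["indel_ins", "indel_del"])].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["tract_class", "n", "location", "count", "denominator", "f_indel"]
        )
    df["loc_class"] = df.apply(_indel_location, axis=1)
    counts = (
        df.groupby(["tract_class", "n", "loc_class"]).size().rename("count").reset_index()
    )
    marg = census.marginal().rename(columns={"count": "N"})
    counts = counts.merge(marg, on=["tract_class", "n"], how="inner")
    counts["denominator"] = np.where(
        counts.loc_class == "in_tract", counts.N * counts.n, counts.N
    )
    counts["f_indel"] = counts["count"] / counts["denominator"]
    return counts.rename(columns={"loc_class": "location"})[
        ["tract_class", "n", "location", "count", "denominator", "f_indel"]
    ]


def insertion_position_matrix(
    assignments: Iterable[TractVariantAssignment],
    census: TractCensus,
    include: Sequence[str] = ("slippage_plus", "indel_ins"),
) -> SpectrumTable:
    """Percent insertions per junction j in 0..n+1 per (class, n).

    percent = insertions at j / N x 100; the row marginal over j equals
    the total insertion percent for the stratum.
    """
    df = _frame(assignments)
    df = df[df.category.isin(list(include))]
    counts = (
        df.groupby(["tract_class", "n", "position"]).size().rename("count").reset_index()
    )
    counts = counts.rename(columns={"position": "junction"})
    denom = {
        (c, n): census.count(c, n)
        for c, n in counts[["tract_class", "n"]].drop_duplicates().itertuples(index=False)
    }
    counts["denominator"] = [
        denom[(c, n)] for c, n in counts[["tract_class", "n"]].itertuples(index=False)
    ]
    counts = counts[counts.denominator > 0].copy()
    counts["percent"] = counts["count"] / counts["denominator"] * 100.0
    return SpectrumTable(counts)


def equalize_datasets(
    table_a: SpectrumTable,
    table_b: SpectrumTable,
    tract_class: str,
    anchor_n: int = 4,
) -> tuple[float, SpectrumTable]:
    """Rescale dataset B so its total percent at (class, anchor_n) matches A.

    Returns the multiplication factor and a rescaled copy of B.  Used to
    compare datasets of very different depth on a common scale.
    """
    a = table_a.total_percent(tract_class, anchor_n)
    b = table_b.total_percent(tract_class, anchor_n)
    if b == 0:
        raise ValueError("anchor stratum empty in table B")
    factor = a / b
    scaled = table_b.table.copy()
    scaled[table_b.value_col] = scaled[table_b.value_col] * factor
    return factor, SpectrumTable(scaled, label=table_b.label, value_col=table_b.value_col)
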