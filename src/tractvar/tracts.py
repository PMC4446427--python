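"""Maximal mononucleotide-tract scanning and censuses.

A-tracts are maximal runs of A:T base pairs and G-tracts maximal runs of
G:C base pairs, 4-13 bp long, named after the purine-rich strand.  Every
tract carries its two nearest-neighbour bases ("flanks"), expressed on the
purine strand: flank5 is the base 5' of the run (position 0) and flank3
the base 3' of it (position n+1).  Tract positions are numbered 1..n from
the 5' end of the purine strand; for a run of T or C on the forward
strand the purine strand is the reverse strand and coordinates/flanks are
reverse-complemented accordingly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

MIN_TRACT_LEN = 4
MAX_TRACT_LEN = 13

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

_RUN_RE = re.compile(r"(A+|C+|G+|T+)")
_NON_ACGT = re.compile(r"[^ACGT]")


def revcomp(seq: str) -> str:
    """Reverse complement; characters outside ACGT map to N."""
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


@dataclass(frozen=True, slots=True)
class Tract:
    """A maximal homopolymer run with purine-strand annotation.

    Coordinates are 0-based half-open on the forward strand of ``chrom``.
    ``tract_class`` is 'A' (A:T run) or 'G' (G:C run); ``purine_strand``
    is '+' when the forward strand carries the purine (A or G) and '-'
    otherwise.  ``flank5``/``flank3`` are the purine-strand neighbours at
    positions 0 and n+1.
    """

    chrom: str
    start: int
    end: int
    tract_class: str
    purine_strand: str
    flank5: str
    flank3: str

    @property
    def n(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Central base coordinate; even lengths use the left-of-center base."""
        return self.start + (self.n - 1) // 2

    def purine_position(self, coord: int) -> int:
        """Purine-strand position p of forward-strand coordinate ``coord``.

        p runs 0 (5' flank) .. n+1 (3' flank); interior bases are 1..n.
        """
        if self.purine_strand == "+":
            return coord - self.start + 1
        return self.end - coord


def _normalize_seq(seq: str) -> str:
    seq = seq.upper()
    return _NON_ACGT.sub("N", seq)


def scan_sequence(chrom_id: str, seq: str) -> list[Tract]:
    """Find all maximal A- and G-tracts of length 4-13 in ``seq``.

    Characters outside {A,C,G,T} are treated as N and never extend a run.
    Runs abutting either sequence end are excluded because their flank at
    position 0 or n+1 is undefined.  Flanks of N are retained (reported
    as 'N').
    """
    if not isinstance(chrom_id, str) or not chrom_id:
        raise ValueError("chrom_id must be a non-empty string")
    seq = _normalize_seq(seq)
    out: list[Tract] = []
    L = len(seq)
    for m in _RUN_RE.finditer(seq):
        start, end = m.start(), m.end()
        n = end - start
        if n < MIN_TRACT_LEN or n > MAX_TRACT_LEN:
            continue
        if start == 0 or end == L:
            continue  # no defined flank at a sequence edge
        base = seq[start]
        left, right = seq[start - 1], seq[end]
        if base in "AG":
            tract_class = "A" if base == "A" else "G"
            strand = "+"
            flank5, flank3 = left, right
        else:
            tract_class = "A" if base == "T" else "G"
            strand = "-"
            flank5 = COMPLEMENT.get(right, "N")
            flank3 = COMPLEMENT.get(left, "N")
        out.append(Tract(chrom_id, start, end, tract_class, strand, flank5, flank3))
    return out


def scan_fasta(path: str) -> list[Tract]:
    """Scan every record of a FASTA file (gzip allowed via pyfaidx)."""
    from pyfaidx import Fasta

    tracts: list[Tract] = []
    with Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
        for name in fa.keys():
            tracts.extend(scan_sequence(name, str(fa[name][:])))
    return tracts


# ---------------------------------------------------------------------------
# Census


class TractCensus:
    """Counts of tracts per (class, n, flank5, flank3) stratum.

    The marginal N(class, n) sums over all flank pairs and includes tracts
    with an N flank; flank-conditioned strata with an N flank are kept in
    the table but are expected to be excluded by flank-conditioned
    analyses.
    """

    def __init__(self, table: pd.DataFrame, region: str | None = None):
        expected = ["tract_class", "n", "flank5", "flank3", "count"]
        if list(table.columns) != expected:
            table = table[expected]
        self.table = table.reset_index(drop=True)
        self.region = region

    @classmethod
    def from_tracts(
        cls,
        tracts: Iterable[Tract],
        mask: Sequence[tuple[str, int, int]] | None = None,
        region: str | None = None,
    ) -> "TractCensus":
        return build_census(tracts, mask=mask, region=region)

    def count(self, tract_class: str, n: int,
              flank5: str | None = None, flank3: str | None = None) -> int:
        t = self.table
        sel = (t.tract_class == tract_class) & (t.n == n)
        if flank5 is not None:
            sel &= t.flank5 == flank5
        if flank3 is not None:
            sel &= t.flank3 == flank3
        return int(t.loc[sel, "count"].sum())

    def marginal(self) -> pd.DataFrame:
        """N(class, n) summed over flank pairs."""
        return (
            self.table.groupby(["tract_class", "n"], as_index=False)["count"]
            .sum()
        )

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "TractCensus":
        return cls(pd.read_csv(path, sep="\t"))

    def __add__(self, other: "TractCensus") -> "TractCensus":
        merged = (
            pd.concat([self.table, other.table])
            .groupby(["tract_class", "n", "flank5", "flank3"], as_index=False)["count"]
            .sum()
        )
        return TractCensus(merged)


class IntervalSet:
    """Half-open 0-based intervals per chromosome, supporting overlap math."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if e <= s:
                continue
            by_chrom.setdefault(chrom, []).append((s, e))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    @classmethod
    def read_bed(cls, path: str) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(ivs)

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bases of [start, end) covered by the interval set."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        bp = 0
        for i in range(lo, hi):
            bp += min(end, ends[i]) - max(start, starts[i])
        return bp

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """Whole containment of [start, end) within a single merged interval."""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        i = int(np.searchsorted(starts, start, side="right")) - 1
        return i >= 0 and ends[i] >= end


def build_census(
    tracts: Iterable[Tract],
    mask: Sequence[tuple[str, int, int]] | IntervalSet | None = None,
    region: str | None = None,
) -> TractCensus:
    """Count tracts per (class, n, flank5, flank3).

    With a ``mask``, only tracts wholly contained in a mask interval are
    counted: the tract is the unit of normalization, so partial overlap
    does not qualify.
    """
    if mask is not None and not isinstance(mask, IntervalSet):
        mask = IntervalSet(mask)
    counts: dict[tuple[str, int, str, str], int] = {}
    for t in tracts:
        if mask is not None and not mask.contains(t.chrom, t.start, t.end):
            continue
        key = (t.tract_class, t.n, t.flank5, t.flank3)
        counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(
        [(c, n, f5, f3, k) for (c, n, f5, f3), k in sorted(counts.items())],
        columns=["tract_class", "n", "flank5", "flank3", "count"],
    )
    if table.empty:
        table = pd.DataFrame(
            columns=["tract_class", "n", "flank5", "flank3", "count"]
        ).astype({"n": int, "count": int}, errors="ignore")
    return TractCensus(table, region=region)


def census_percent_difference(
    census_a: TractCensus, census_b: TractCensus, normalize: bool = True
) -> pd.DataFrame:
    """Percent difference in tract numbers between two censuses per (class, n).

    By default each census is first reduced to per-class proportions over
    n = 4-13, which removes overall scale differences between the two
    sequence sets (e.g. genomes differing ~2x in covered length); the
    value is (propA - propB) / propB * 100.  With ``normalize=False`` raw
    counts are compared directly.  Strata with a zero denominator are
    reported as NaN.
    """
    a = census_a.marginal().rename(columns={"count": "a"})
    b = census_b.marginal().rename(columns={"count": "b"})
    m = a.merge(b, on=["tract_class", "n"], how="outer").fillna(0)
    if normalize:
        for col in ("a", "b"):
            totals = m.groupby("tract_class")[col].transform("sum")
            m[col] = m[col] / totals.where(totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m["percent_difference"] = np.where(
            m["b"] > 0, (m["a"] - m["b"]) / m["b"] * 100.0, np.nan
        )
    return m[["tract_class", "n", "percent_difference"]]


def intersect_fraction(
    tracts: Iterable[Tract],
    intervals: Sequence[tuple[str, int, int]] | IntervalSet,
    unit: str = "tract",
) -> pd.DataFrame:
    """Percent of tracts (or tract base pairs) overlapping an interval set.

    ``unit='tract'`` counts tracts with >= 1 bp overlap; ``unit='bp'``
    counts overlapping tract base pairs.  Results are percent of the
    (class, n) stratum total.
    """
    if unit not in ("tract", "bp"):
        raise ValueError("unit must be 'tract' or 'bp'")
    if not isinstance(intervals, IntervalSet):
        intervals = IntervalSet(intervals)
    num: dict[tuple[str, int], float] = {}
    den: dict[tuple[str, int], float] = {}
    for t in tracts:
        key = (t.tract_class, t.n)
        ov = intervals.overlap_bp(t.chrom, t.start, t.end)
        if unit == "tract":
            den[key] = den.get(key, 0) + 1
            num[key] = num.get(key, 0) + (1 if ov > 0 else 0)
        else:
            den[key] = den.get(key, 0) + t.n
            num[key] = num.get(key, 0) + ov
    rows = [
        (c, n, num.get((c, n), 0) / den[(c, n)] * 100.0)
        for (c, n) in sorted(den)
    ]
    return pd.DataFrame(rows, columns=["tract_class", "n", "percent_overlapping"])


def tracts_to_bed(tracts: Iterable[Tract], path: str) -> None:
    """Write tracts as BED6+2 (name 'class:n', strand = purine strand)."""
    with open(path, "w") as fh:
        for t in tracts:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.tract_class}:{t.n}\t0\t"
                f"{t.purine_strand}\t{t.flank5}\t{t.flank3}\n"
            )


def tracts_to_frame(tracts: Iterable[Tract]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.chrom, t.start, t.end, t.n, t.tract_class, t.purine_strand,
             t.flank5, t.flank3)
            for t in tracts
        ],
        columns=["chrom", "start", "end", "n", "tract_class", "purine_strand",
                 "flank5", "flank3"],
    )
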